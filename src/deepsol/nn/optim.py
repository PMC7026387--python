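"""Gradient-descent optimizers over layer parameter dictionaries.

L2 regularization is applied as classic weight decay added to the gradient
of weight matrices/kernels only (keys named 'W'); biases and batch-norm
scale/shift are not decayed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]

_DECAYED_KEYS = {"W"}


class _Optimizer:
    def __init__(self, lr: float, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.weight_decay = weight_decay

    def _grad(self, layer, key):
        g = layer.grads[key]
        if self.weight_decay and key in _DECAYED_KEYS:
            g = g + self.weight_decay * layer.params[key]
        return g

    def step(self, layers) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr: float, weight_decay: float = 0.0, momentum: float = 0.0):
        super().__init__(lr, weight_decay)
        self.momentum = momentum
        self._velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers) -> None:
        for layer in layers:
            for key in layer.params:
                g = self._grad(layer, key)
                if self.momentum:
                    k = (id(layer), key)
                    v = self._velocity.get(k)
                    v = self.momentum * v + g if v is not None else g
                    self._velocity[k] = v
                    g = v
                layer.params[key] = layer.params[key] - self.lr * g


class Adam(_Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        super().__init__(lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}
        self._t = 0

    def step(self, layers) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for layer in layers:
            for key in layer.params:
                g = self._grad(layer, key)
                k = (id(layer), key)
                m = self._m.get(k)
                v = self._v.get(k)
                m = b1 * m + (1 - b1) * g if m is not None else (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g if v is not None else (1 - b2) * g * g
                self._m[k], self._v[k] = m, v
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                layer.params[key] = layer.params[key] - self.lr * update
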