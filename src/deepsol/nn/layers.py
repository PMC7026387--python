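"""Minimal NumPy layers with explicit forward/backward passes.

Convolutional activations use the (batch, channels, length) layout; dense
activations are (batch, features).  Each layer owns its parameters and the
gradients from the most recent backward pass; optimizers iterate over them.

Convolutions are computed by an im2col lowering to a single BLAS matmul;
their input gradient is accumulated tap-by-tap over the kernel (at most a
handful of taps), which avoids a scatter-based col2im.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "ChannelSoftmax",
    "Dropout",
    "GlobalAvgPool1d",
    "AddChannelDim",
    "uniform_fan_in",
]


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   scale: float, dtype) -> np.ndarray:
    """Fan-in-scaled uniform initialization: U(-a, a), a = scale*sqrt(3/fan_in).

    At scale 1 the weight variance is 1/fan_in.
    """
    a = scale * np.sqrt(3.0 / fan_in)
    return rng.uniform(-a, a, size=shape).astype(dtype)


class Layer:
    """Base layer: parameter-free unless a subclass populates ``params``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1d(Layer):
    """1D convolution, weight shape (out_channels, in_channels, kernel).

    Padding defaults to kernel//2 on both sides, so stride 1 preserves the
    sequence length and stride s yields floor((L + 2p - k)/s) + 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 init_scale: float = 1.0, dtype=np.float32, pad: int | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel
        self.params["W"] = uniform_fan_in(rng, (out_channels, in_channels, kernel), fan_in, init_scale, dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._cache = None

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        L_out = self.out_length(L)
        k, s = self.kernel, self.stride
        span = s * (L_out - 1) + 1
        # tap-wise accumulation: k batched matmuls, no im2col copy
        out = np.matmul(W[:, :, 0], xp[:, :, 0:span:s])
        for t in range(1, k):
            out += np.matmul(W[:, :, t], xp[:, :, t : t + span : s])
        out += b[None, :, None]
        self._cache = (xp, x.shape, L_out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, L_out = self._cache
        W = self.params["W"]
        B, C, L = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        span = s * (L_out - 1) + 1
        dW = np.empty_like(W)
        dout_t = dout.transpose(0, 2, 1)                       # (B, L_out, out)
        dxp = np.zeros((B, C, xp.shape[2]), dtype=dout.dtype)
        for t in range(k):
            sl = xp[:, :, t : t + span : s]                    # (B, C, L_out)
            dW[:, :, t] = np.matmul(sl, dout_t).sum(axis=0).T
            dxp[:, :, t : t + span : s] += np.matmul(W[:, :, t].T, dout)
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2)).astype(W.dtype)
        return dxp[:, :, p : p + L] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:
            m = x.shape[0] * x.shape[2]
            mean = np.einsum("bcl->c", x) / m
            var = np.einsum("bcl,bcl->c", x, x) / m - mean * mean
            np.maximum(var, 0.0, out=var)  # guard fp cancellation
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        # fused scale-shift: y = a*x + c with a = gamma*invstd
        a = (self.params["gamma"] * invstd).astype(x.dtype)
        c = (self.params["beta"] - a * mean).astype(x.dtype)
        self._cache = (x, mean.astype(x.dtype), invstd.astype(x.dtype), training)
        return a[None, :, None] * x + c[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # fused form: dx = A*dout + B*x + C per channel, derived from the
        # standard batch-norm backward with xhat re-expressed in x
        x, mean, invstd, training = self._cache
        g = self.params["gamma"]
        dbeta = np.einsum("bcl->c", dout)
        dx_sum = np.einsum("bcl,bcl->c", dout, x)
        dgamma = invstd * (dx_sum - mean * dbeta)
        self.grads["gamma"] = dgamma.astype(g.dtype)
        self.grads["beta"] = dbeta.astype(g.dtype)
        if not training:
            A = (g * invstd).astype(dout.dtype)
            return A[None, :, None] * dout
        m = dout.shape[0] * dout.shape[2]
        A = g * invstd
        Bc = -(g * invstd**3) * (dx_sum - mean * dbeta) / m
        Cc = -(g * invstd) * dbeta / m - Bc * mean
        return (
            A.astype(dout.dtype)[None, :, None] * dout
            + Bc.astype(dout.dtype)[None, :, None] * x
            + Cc.astype(dout.dtype)[None, :, None]
        )


class Dense(Layer):
    """Fully connected layer on (batch, features)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 init_scale: float = 1.0, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        self.params["W"] = uniform_fan_in(rng, (out_features, in_features), in_features, init_scale, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)
        self._x = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["W"] = (dout.T @ self._x).astype(W.dtype)
        self.grads["b"] = dout.sum(axis=0).astype(W.dtype)
        return dout @ W


class ReLU(Layer):
    def forward(self, x, training):
        y = np.maximum(x, 0)
        self._y = y
        return y

    def backward(self, dout):
        return dout * (self._y > 0)


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class ChannelSoftmax(Layer):
    """Softmax over the channel axis of (batch, channels, length)."""

    def forward(self, x, training):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, dout):
        y = self._y
        return y * (dout - (dout * y).sum(axis=1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool1d(Layer):
    """(batch, channels, length) -> (batch, channels) mean over length."""

    def forward(self, x, training):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    """(batch, channels, length) -> (batch, channels*length)."""

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class AddChannelDim(Layer):
    """(batch, features) -> (batch, 1, features) for the convolutional stem."""

    def forward(self, x, training):
        return x[:, None, :]

    def backward(self, dout):
        return dout[:, 0, :]
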