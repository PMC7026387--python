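"""Network containers: sequential stacks and residual blocks.

A residual block computes ``y = F(x) + shortcut(x)`` — the branch F holds
the parameterized layers and the shortcut is the identity when shapes match
or a 1x1 strided projection convolution when channels/length change.  No
activation follows the addition, so zeroing the branch parameters makes a
block return its shortcut output exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .layers import Conv1d, Dense, Layer

__all__ = ["Sequential", "ResidualBlock", "Network", "LayerAuditEntry"]


@dataclass(frozen=True)
class LayerAuditEntry:
    kind: str                 # 'conv1d' or 'dense'
    in_shape: tuple
    out_shape: tuple
    n_params: int
    is_shortcut: bool = False


class Sequential:
    def __init__(self, modules: list):
        self.modules = modules

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout

    def iter_layers(self):
        for m in self.modules:
            if isinstance(m, Layer):
                yield m
            else:
                yield from m.iter_layers()


class ResidualBlock:
    """y = branch(x) + shortcut(x); shortcut is identity or a projection conv."""

    def __init__(self, branch: Sequential, shortcut: Sequential | None = None):
        self.branch = branch
        self.shortcut = shortcut

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        fx = self.branch.forward(x, training)
        sx = self.shortcut.forward(x, training) if self.shortcut is not None else x
        return fx + sx

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.branch.backward(dout)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dout)
        else:
            dx = dx + dout
        return dx

    def shortcut_output(self, x: np.ndarray) -> np.ndarray:
        """The shortcut path alone, in evaluation mode."""
        return self.shortcut.forward(x, False) if self.shortcut is not None else x

    def zero_branch(self) -> None:
        """Zero every branch parameter so the block becomes its shortcut."""
        for layer in self.branch.iter_layers():
            for name in layer.params:
                layer.params[name] = np.zeros_like(layer.params[name])

    def iter_layers(self):
        yield from self.branch.iter_layers()
        if self.shortcut is not None:
            yield from self.shortcut.iter_layers()


class Network:
    """A trainable model: a module tree plus its layer audit."""

    def __init__(self, body: Sequential, layer_audit: list[LayerAuditEntry],
                 input_length: int, spec=None):
        self.body = body
        self.layer_audit = layer_audit
        self.input_length = input_length
        self.spec = spec
        # affine output calibration (location/scale of the training targets),
        # set at fit time so the head starts on the right scale
        self.output_loc = 0.0
        self.output_scale = 1.0

    # -- computation ------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (n, input_length) feature rows to (n,) predictions."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(f"expected input shape (n, {self.input_length}), got {X.shape}")
        out = self.body.forward(X.astype(self.dtype, copy=False), training)
        return out[:, 0] * self.output_scale + self.output_loc

    def backward(self, dpred: np.ndarray) -> None:
        d = (np.asarray(dpred) * self.output_scale).astype(self.dtype)
        self.body.backward(d[:, None])

    # -- introspection ----------------------------------------------------
    def iter_layers(self):
        yield from self.body.iter_layers()

    @property
    def dtype(self):
        for layer in self.iter_layers():
            for p in layer.params.values():
                return p.dtype
        return np.float32

    @property
    def blocks(self) -> list[ResidualBlock]:
        out = []

        def walk(node):
            if isinstance(node, ResidualBlock):
                out.append(node)
                walk(node.branch)
            elif isinstance(node, Sequential):
                for m in node.modules:
                    walk(m)

        walk(self.body)
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(layer.n_parameters for layer in self.iter_layers()))

    @property
    def param_layer_count(self) -> int:
        """Parameter layers (conv + dense) excluding shortcut projections."""
        return sum(1 for e in self.layer_audit if not e.is_shortcut)

    def zero_residual_branches(self) -> None:
        for block in self.blocks:
            block.zero_branch()

    # -- state ------------------------------------------------------------
    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self.iter_layers():
            entry = {k: v.copy() for k, v in layer.params.items()}
            if hasattr(layer, "running_mean"):
                entry["__running_mean"] = layer.running_mean.copy()
                entry["__running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        layers = list(self.iter_layers())
        if len(layers) != len(state):
            raise ValueError("state does not match network structure")
        for layer, entry in zip(layers, state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if hasattr(layer, "running_mean"):
                layer.running_mean = entry["__running_mean"].copy()
                layer.running_var = entry["__running_var"].copy()

    def copy_state(self):
        return copy.deepcopy(self.get_state())


def audit_entry_for(layer: Layer, in_shape: tuple, out_shape: tuple,
                    is_shortcut: bool = False) -> LayerAuditEntry:
    kind = "conv1d" if isinstance(layer, Conv1d) else "dense" if isinstance(layer, Dense) else type(layer).__name__
    return LayerAuditEntry(kind, tuple(in_shape), tuple(out_shape), layer.n_parameters, is_shortcut)
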