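"""Declarative model specs and builders for the solubility regressors.

Two families are covered:

* **ResNet-like 1D CNN** ("deeper-net"): the 881-bit fingerprint is treated
  as a one-channel sequence.  A stem convolution lifts it to the first
  channel stage; three stages of residual blocks follow, with the channel
  count stepping 9 -> 18 -> 36 by default and the sequence length halved at
  each stage transition by a strided convolution (the shortcut then becomes
  a 1x1 projection).  The final feature map is flattened into the single
  fully connected output layer producing the scalar logS (a global-average-
  pool head is available but discards bit position, and which substructure
  bit is set is the signal here — see docs/methods for the reasoning).  A
  model declared with N parameter layers has N-1 convolutions plus 1 fully
  connected layer; projection shortcuts carry parameters but are not
  counted toward N.

* **Plain DNN** ("shallow-net"): fully connected layers on the raw 881-bit
  vector with ReLU, dropout and L2 weight decay; the 4-hidden-layer
  512/1024/2048/4096 configuration is the reference baseline.

Builders return a :class:`~deepsol.nn.Network` whose ``layer_audit`` lists
every parameter layer with shapes and parameter counts, so depth claims are
checkable rather than asserted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.layers import (
    AddChannelDim,
    BatchNorm1d,
    ChannelSoftmax,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool1d,
    ReLU,
    Sigmoid,
)
from .nn.network import Network, ResidualBlock, Sequential, audit_entry_for

__all__ = ["ResNetSpec", "DNNSpec", "build_resnet", "build_dnn", "build_model",
           "save_checkpoint", "load_checkpoint"]

_ACTIVATIONS = {"relu": ReLU, "sigmoid": Sigmoid, "softmax": ChannelSoftmax}


@dataclass(frozen=True)
class ResNetSpec:
    """Residual 1D-CNN architecture description.

    ``n_param_layers`` is the headline depth N: N-1 convolutions plus the
    final fully connected layer.  After the stem convolution the remaining
    N-2 convolutions form two-convolution residual blocks, distributed
    equally over the channel stages, so (N-2)/2 must be a positive multiple
    of the number of stages.
    """

    n_param_layers: int = 20
    stage_channels: tuple[int, ...] = (9, 18, 36)
    stem_kernel: int = 7
    block_kernel: int = 3
    downsample_stride: int = 2
    activation: str = "relu"
    l2_lambda: float = 1e-4
    use_batch_norm: bool = True
    init_scale: float = 1.0
    head: str = "flatten"            # 'flatten' | 'gap'

    def __post_init__(self):
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}")
        n = self.n_param_layers
        n_stages = len(self.stage_channels)
        if n < 2:
            raise ValueError("need at least a stem convolution and the output layer (N >= 2)")
        rem = n - 2  # minus stem conv and FC head
        if rem <= 0 or rem % 2 != 0:
            raise ValueError(
                f"N={n}: after the stem conv and FC head, {rem} convolutions remain, "
                "which cannot form 2-convolution residual blocks"
            )
        n_blocks = rem // 2
        if n_blocks % n_stages != 0:
            raise ValueError(
                f"N={n} gives {n_blocks} residual blocks, not divisible across "
                f"{n_stages} channel stages"
            )
        if any(b <= a for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage_channels must be strictly increasing")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")

    @property
    def blocks_per_stage(self) -> int:
        return (self.n_param_layers - 2) // 2 // len(self.stage_channels)


@dataclass(frozen=True)
class DNNSpec:
    """Fully connected baseline description (hidden sizes exclude the output)."""

    hidden_sizes: tuple[int, ...] = (512, 1024, 2048, 4096)
    l2_lambda: float = 0.001
    dropout_rate: float = 0.5
    activation: str = "relu"
    init_scale: float = 1.0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("at least one hidden layer required")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def build_resnet(spec: ResNetSpec, input_length: int = 881,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> Network:
    """Construct an untrained residual CNN from its spec."""
    rng = rng or np.random.default_rng()
    act = _ACTIVATIONS[spec.activation]
    audit = []
    modules: list = [AddChannelDim()]

    def conv(in_ch, out_ch, k, stride, length, is_shortcut=False, pad=None):
        layer = Conv1d(in_ch, out_ch, k, stride=stride, rng=rng,
                       init_scale=spec.init_scale, dtype=dtype, pad=pad)
        out_len = layer.out_length(length)
        audit.append(audit_entry_for(layer, (in_ch, length), (out_ch, out_len), is_shortcut))
        return layer, out_len

    # stem
    length = input_length
    stem_conv, length = conv(1, spec.stage_channels[0], spec.stem_kernel, 1, length)
    stem: list = [stem_conv]
    if spec.use_batch_norm:
        stem.append(BatchNorm1d(spec.stage_channels[0], dtype=dtype))
    stem.append(act())
    modules.extend(stem)

    in_ch = spec.stage_channels[0]
    for stage_idx, out_ch in enumerate(spec.stage_channels):
        for block_idx in range(spec.blocks_per_stage):
            first = block_idx == 0
            stride = spec.downsample_stride if (first and stage_idx > 0) else 1
            branch_layers: list = []
            c1, blen = conv(in_ch, out_ch, spec.block_kernel, stride, length)
            branch_layers.append(c1)
            if spec.use_batch_norm:
                branch_layers.append(BatchNorm1d(out_ch, dtype=dtype))
            branch_layers.append(act())
            c2, blen = conv(out_ch, out_ch, spec.block_kernel, 1, blen)
            branch_layers.append(c2)
            if spec.use_batch_norm:
                branch_layers.append(BatchNorm1d(out_ch, dtype=dtype))
            shortcut = None
            if stride != 1 or in_ch != out_ch:
                proj, plen = conv(in_ch, out_ch, 1, stride, length, is_shortcut=True, pad=0)
                if plen != blen:  # pragma: no cover - guarded by construction
                    raise AssertionError("projection/branch length mismatch")
                shortcut = Sequential([proj])
            modules.append(ResidualBlock(Sequential(branch_layers), shortcut))
            length = blen
            in_ch = out_ch

    if spec.head == "gap":
        modules.append(GlobalAvgPool1d())
        head_in = in_ch
    else:
        modules.append(Flatten())
        head_in = in_ch * length
    head = Dense(head_in, 1, rng=rng, init_scale=spec.init_scale, dtype=dtype)
    audit.append(audit_entry_for(head, (head_in,), (1,)))
    modules.append(head)

    net = Network(Sequential(modules), audit, input_length, spec=spec)
    assert net.param_layer_count == spec.n_param_layers
    return net


def build_dnn(spec: DNNSpec, input_length: int = 881,
              rng: np.random.Generator | None = None,
              dtype=np.float32) -> Network:
    """Construct an untrained fully connected baseline from its spec."""
    rng = rng or np.random.default_rng()
    act = _ACTIVATIONS[spec.activation]
    audit = []
    modules: list = []
    in_f = input_length
    for h in spec.hidden_sizes:
        layer = Dense(in_f, h, rng=rng, init_scale=spec.init_scale, dtype=dtype)
        audit.append(audit_entry_for(layer, (in_f,), (h,)))
        modules.append(layer)
        modules.append(act())
        if spec.dropout_rate > 0:
            modules.append(Dropout(spec.dropout_rate, rng=rng))
        in_f = h
    head = Dense(in_f, 1, rng=rng, init_scale=spec.init_scale, dtype=dtype)
    audit.append(audit_entry_for(head, (in_f,), (1,)))
    modules.append(head)
    return Network(Sequential(modules), audit, input_length, spec=spec)


def build_model(spec, input_length: int = 881, rng=None, dtype=np.float32) -> Network:
    if isinstance(spec, ResNetSpec):
        return build_resnet(spec, input_length, rng, dtype)
    if isinstance(spec, DNNSpec):
        return build_dnn(spec, input_length, rng, dtype)
    raise TypeError(f"unknown spec type: {type(spec).__name__}")


def save_checkpoint(path: str | Path, net: Network) -> None:
    """Serialize a network (spec + weights + running stats) to one .npz file."""
    meta = {
        "spec_kind": type(net.spec).__name__,
        "spec": asdict(net.spec),
        "input_length": net.input_length,
        "output_loc": net.output_loc,
        "output_scale": net.output_scale,
    }
    arrays = {}
    for i, entry in enumerate(net.get_state()):
        for k, v in entry.items():
            arrays[f"{i}|{k}"] = v
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    spec_cls = {"ResNetSpec": ResNetSpec, "DNNSpec": DNNSpec}[meta["spec_kind"]]
    kwargs = meta["spec"]
    for key in ("stage_channels", "hidden_sizes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    spec = spec_cls(**kwargs)
    net = build_model(spec, input_length=int(meta["input_length"]))
    net.output_loc = float(meta.get("output_loc", 0.0))
    net.output_scale = float(meta.get("output_scale", 1.0))
    state: list[dict[str, np.ndarray]] = []
    for key in sorted(arrays, key=lambda s: (int(s.split("|")[0]), s)):
        idx, name = key.split("|", 1)
        while len(state) <= int(idx):
            state.append({})
        state[int(idx)][name] = arrays[key]
    net.set_state(state)
    return net
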