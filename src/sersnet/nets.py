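"""The three 1D lightweight CNN architectures for SERS mixture identification.

All three trade dense convolutions for cheaper structured ones:

* SqueezeNet-1D — a fire module: a 1x1 "squeeze" convolution feeding two
  parallel "expand" convolutions (kernel 1 and kernel 3) whose outputs are
  concatenated along channels; pooling is delayed so a larger feature map is
  convolved.
* MobileNet-1D — depthwise separable convolution (DSC): per-channel depthwise
  convolution then a pointwise 1x1 convolution, each followed by batch
  normalisation and ReLU.
* ShuffleNet-1D — shuffle units: 1x1 group convolution, channel shuffle,
  3-kernel depthwise convolution, 1x1 group convolution, and a residual
  addition with the unit input.

Spectra enter as single-channel vectors on the wavenumber axis ("3 x 1"
convolutions are kernel-3 along wavenumber); the head is flatten/dropout/
dense with a softmax over the four mixture classes.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm1D,
    ChannelShuffle,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool1D,
    Param,
    ReLU,
    Sequential,
    softmax,
)

__all__ = [
    "ARCHITECTURES",
    "NetworkConfig",
    "channel_shuffle",
    "FireBlock",
    "DSCBlock",
    "ShuffleUnit",
    "Network",
    "build_network",
    "plain_reference_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("squeezenet1d", "mobilenet1d", "shufflenet1d")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture selection plus the block hyperparameters.

    Exact layer tables for the original networks are not published for the 1D
    case; these defaults are the smallest widths consistent with the block
    inventory above and are all overridable.
    """

    architecture: str = "shufflenet1d"
    input_length: int = 751
    n_classes: int = 4
    dropout: float = 0.5
    seed: int = 0
    # squeezenet1d
    stem_filters: int = 16
    stem_kernel: int = 7
    stem_stride: int = 2
    squeeze_filters: int = 16
    expand_filters: int = 32
    # mobilenet1d
    mobile_stem_filters: int = 16
    dsc_filters: tuple[int, int] = (32, 64)
    dense_units: int = 64
    # shufflenet1d
    shuffle_channels: int = 24
    groups: int = 3

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_length < 8:
            raise ValueError("input_length smaller than the receptive field")
        if self.shuffle_channels % self.groups:
            raise ValueError(
                f"shuffle_channels ({self.shuffle_channels}) must be divisible by "
                f"groups ({self.groups})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "dsc_filters" in d:
            d["dsc_filters"] = tuple(d["dsc_filters"])
        return cls(**d)


def channel_shuffle(feature_map: np.ndarray, groups: int, channel_axis: int = -1) -> np.ndarray:
    """Functional channel shuffle on an arbitrary array.

    Output channel i is input channel (i mod g)*(C/g) + (i div g); all other
    axes are untouched. g=1 and g=C are identities.
    """
    C = feature_map.shape[channel_axis]
    if C % groups:
        raise ValueError(f"channels ({C}) not divisible by groups ({groups})")
    i = np.arange(C)
    perm = (i % groups) * (C // groups) + i // groups
    return np.take(feature_map, perm, axis=channel_axis)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class FireBlock(Layer):
    """Squeeze (1x1) then parallel expand (1x1 and kernel-3) convolutions,
    concatenated along channels: output channels = 2 * expand_filters."""

    def __init__(
        self,
        in_channels: int,
        squeeze_filters: int,
        expand_filters: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        if squeeze_filters < 1 or expand_filters < 1:
            raise ValueError("filter counts must be positive")
        self.squeeze = Conv1D(in_channels, squeeze_filters, 1, rng=rng)
        self.expand1 = Conv1D(squeeze_filters, expand_filters, 1, rng=rng)
        self.expand3 = Conv1D(squeeze_filters, expand_filters, 3, rng=rng)
        self.relu_s, self.relu_1, self.relu_3 = ReLU(), ReLU(), ReLU()
        self.expand_filters = expand_filters

    def params(self) -> list[Param]:
        return self.squeeze.params() + self.expand1.params() + self.expand3.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = self.relu_s.forward(self.squeeze.forward(x, training), training)
        a = self.relu_1.forward(self.expand1.forward(z, training), training)
        b = self.relu_3.forward(self.expand3.forward(z, training), training)
        return np.concatenate([a, b], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        e = self.expand_filters
        ga = self.expand1.backward(self.relu_1.backward(grad[:, :e]))
        gb = self.expand3.backward(self.relu_3.backward(grad[:, e:]))
        return self.squeeze.backward(self.relu_s.backward(ga + gb))

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        return 2 * self.expand_filters, spec[1]


class DSCBlock(Sequential):
    """Depthwise separable convolution: depthwise (kernel 3) -> BN -> ReLU ->
    pointwise (1x1) -> BN -> ReLU. Convolutions carry no bias (BN follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__(
            [
                Conv1D(in_channels, in_channels, kernel, groups=in_channels,
                       bias=False, rng=rng),
                BatchNorm1D(in_channels),
                ReLU(),
                Conv1D(in_channels, out_channels, 1, bias=False, rng=rng),
                BatchNorm1D(out_channels),
                ReLU(),
            ]
        )


class ShuffleUnit(Layer):
    """1x1 group conv -> ReLU -> channel shuffle -> kernel-3 depthwise conv ->
    1x1 group conv, added residually to the unit input (shape preserved)."""

    def __init__(
        self,
        channels: int,
        groups: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        if channels % groups:
            raise ValueError(f"channels ({channels}) must be divisible by groups ({groups})")
        self.branch = Sequential(
            [
                Conv1D(channels, channels, 1, groups=groups, rng=rng),
                ReLU(),
                ChannelShuffle(channels, groups),
                Conv1D(channels, channels, 3, groups=channels, rng=rng),
                Conv1D(channels, channels, 1, groups=groups, rng=rng),
            ]
        )

    def params(self) -> list[Param]:
        return self.branch.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x + self.branch.forward(x, training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.branch.backward(grad)


# ---------------------------------------------------------------------------
# Whole networks
# ---------------------------------------------------------------------------

class Network:
    """A built classifier: named blocks, a seeded generator for dropout, and
    the bookkeeping needed for audits and checkpoints."""

    def __init__(self, config: NetworkConfig, blocks: list[tuple[str, Layer]],
                 rng: np.random.Generator) -> None:
        self.config = config
        self.blocks = blocks
        self.rng = rng

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for _, layer in self.blocks:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.blocks):
            grad = layer.backward(grad)
        return grad

    def predict_logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """X is (n_spectra, input_length); returns (n_spectra, n_classes)."""
        outs = []
        for i in range(0, len(X), batch_size):
            xb = X[i : i + batch_size][:, None, :]
            outs.append(self.forward(xb, training=False))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return softmax(self.predict_logits(X, batch_size))

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_logits(X, batch_size).argmax(axis=1)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        return [p for _, layer in self.blocks for p in layer.params()]

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def weight_count(self) -> int:
        """Convolution/dense weights only (no biases, no batch-norm terms)."""
        return int(sum(p.value.size for p in self.params() if p.kind == "weight"))

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    # -- audit --------------------------------------------------------------
    def audit(self) -> list[dict]:
        """Predicted (channels, length) after each block plus its parameter
        count — the shape chain is pure arithmetic, checkable against a real
        forward pass."""
        spec = (1, self.config.input_length)
        rows = []
        for name, layer in self.blocks:
            spec = layer.out_spec(spec)
            rows.append(
                {
                    "block": name,
                    "out_channels": spec[0],
                    "out_length": spec[1],
                    "params": int(sum(p.value.size for p in layer.params())),
                }
            )
        return rows


def build_network(config: NetworkConfig) -> Network:
    """Assemble the selected architecture with seeded weight initialisation."""
    rng = np.random.default_rng(config.seed)
    c = config
    if c.architecture == "squeezenet1d":
        blocks: list[tuple[str, Layer]] = [
            ("conv", Conv1D(1, c.stem_filters, c.stem_kernel, stride=c.stem_stride, rng=rng)),
            ("relu", ReLU()),
            ("maxpool", MaxPool1D(2)),
            ("fire", FireBlock(c.stem_filters, c.squeeze_filters, c.expand_filters, rng=rng)),
            ("flatten", Flatten()),
            ("dropout", Dropout(c.dropout, rng=rng)),
            ("dense", None),  # placeholder, size filled below
        ]
    elif c.architecture == "mobilenet1d":
        blocks = [
            ("conv", Conv1D(1, c.mobile_stem_filters, 3, rng=rng)),
            ("relu", ReLU()),
            ("dsc1", DSCBlock(c.mobile_stem_filters, c.dsc_filters[0], rng=rng)),
            ("dsc2", DSCBlock(c.dsc_filters[0], c.dsc_filters[1], rng=rng)),
            ("maxpool", MaxPool1D(2)),
            ("flatten", Flatten()),
            ("dense1", None),
            ("relu2", ReLU()),
            ("dense2", None),
        ]
    else:  # shufflenet1d
        blocks = [
            ("conv", Conv1D(1, c.shuffle_channels, 3, rng=rng)),
            ("relu", ReLU()),
            ("maxpool", MaxPool1D(2)),
            ("shuffle1", ShuffleUnit(c.shuffle_channels, c.groups, rng=rng)),
            ("shuffle2", ShuffleUnit(c.shuffle_channels, c.groups, rng=rng)),
            ("flatten", Flatten()),
            ("dropout", Dropout(c.dropout, rng=rng)),
            ("dense1", None),
            ("relu2", ReLU()),
            ("dense2", None),
        ]

    # Fill dense-layer sizes from the shape chain up to each placeholder.
    spec = (1, c.input_length)
    for i, (name, layer) in enumerate(blocks):
        if layer is None:
            in_features = spec[0] if spec[1] == 1 else spec[0] * spec[1]
            is_head = name in ("dense", "dense2")
            out_features = c.n_classes if is_head else c.dense_units
            layer = Dense(in_features, out_features, rng=rng)
            blocks[i] = (name, layer)
        spec = layer.out_spec(spec)
    return Network(config=c, blocks=blocks, rng=rng)


def plain_reference_param_count(config: NetworkConfig) -> int:
    """Trainable parameters of the non-lightweight reference: same depth and
    channel widths, but every structured block replaced by a dense kernel-3
    convolution (with bias). Baseline for the parameter-saving claim."""
    c = config
    net = build_network(c)
    total = 0
    for name, layer in net.blocks:
        if name == "fire":
            cin, cout = c.stem_filters, 2 * c.expand_filters
            total += 3 * cin * cout + cout
        elif name.startswith("dsc"):
            cin = layer.layers[0].in_channels
            cout = layer.layers[3].out_channels
            total += 3 * cin * cout + cout
        elif name.startswith("shuffle"):
            ch = c.shuffle_channels
            total += 3 * ch * ch + ch
        else:
            total += int(sum(p.value.size for p in layer.params()))
    return total


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: Network, path: str | Path) -> None:
    """Weights as an .npz plus the config and a JSON architecture audit."""
    path = Path(path)
    arrays = {f"param_{i:03d}": w for i, w in enumerate(network.get_weights())}
    # Batch-norm running statistics are state, not Params; persist them too.
    bn_state = _bn_states(network)
    arrays.update({f"bn_{i:03d}": s for i, s in enumerate(bn_state)})
    np.savez(path, config=json.dumps(network.config.to_dict()), **arrays)
    audit_path = path.with_suffix(path.suffix + ".audit.json")
    audit_path.write_text(
        json.dumps(
            {
                "architecture": network.config.architecture,
                "parameter_count": network.parameter_count(),
                "weight_count": network.weight_count(),
                "blocks": network.audit(),
            },
            indent=2,
        )
        + "\n"
    )


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig.from_dict(json.loads(str(data["config"])))
        net = build_network(config)
        n = len(net.params())
        net.set_weights([data[f"param_{i:03d}"] for i in range(n)])
        bn = [data[k] for k in sorted(k for k in data.files if k.startswith("bn_"))]
    _set_bn_states(net, bn)
    return net


def _iter_layers(layer: Layer):
    yield layer
    for attr in ("layers", "branch"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Sequential):
            yield from _iter_layers(sub)
        elif isinstance(sub, list):
            for s in sub:
                yield from _iter_layers(s)
    if isinstance(layer, FireBlock):
        yield from (layer.squeeze, layer.expand1, layer.expand3)


def _bn_layers(network: Network) -> list[BatchNorm1D]:
    out = []
    for _, block in network.blocks:
        for layer in _iter_layers(block):
            if isinstance(layer, BatchNorm1D):
                out.append(layer)
    return out


def _bn_states(network: Network) -> list[np.ndarray]:
    out = []
    for bn in _bn_layers(network):
        out.append(bn.running_mean.copy())
        out.append(bn.running_var.copy())
    return out


def _set_bn_states(network: Network, states: list[np.ndarray]) -> None:
    bns = _bn_layers(network)
    if len(states) != 2 * len(bns):
        raise ValueError("batch-norm state count mismatch")
    for i, bn in enumerate(bns):
        bn.running_mean[...] = states[2 * i]
        bn.running_var[...] = states[2 * i + 1]


def clone_network(network: Network) -> Network:
    """Deep copy (used to retain best-validation weights during training)."""
    return copy.deepcopy(network)
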