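"""Declarative model construction.

Representation CNNs (CNN1-3) turn one mel-spectrogram slice into a feature
vector; temporal blocks (TCNN1-3 or LSTM/GRU/LMU stacks) combine the ordered
per-slide features; a fixed classification head (512-unit ReLU layer,
dropout 0.5, softmax output) produces class probabilities.  Stand-alone
baselines (VGG16, ResNet18/50, standard published configurations with the
final layer resized to the class count) consume the whole-clip 3x224x224
image instead.

Architectures are token lists (``32``/``"MP"``/``"AAvgPool"``) loaded from a
config mapping, so a different reading of the printed tables can be swapped
in without code changes (the three-column source table is flattened in print
and admits more than one reconstruction; the default below reproduces the
published parameter-count table for the small hybrids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _nn
from . import recurrent_cells as rc
from .synthetic_audio import ValidationError

# ---------------------------------------------------------------------------
# architecture configuration

#: canonical reconstruction of the representation-CNN table
REPRESENTATION_ARCHS: dict[str, list] = {
    "CNN1": [32, 64, "MP", 64, 64, "MP", 128, 128, 128, "MP",
             128, 128, 128, "AAvgPool"],
    "CNN2": [32, 64, "MP", 128, 128, "MP", 128, 128, 128, "MP",
             128, 128, 128, "MP", 256, 256, 256, "AAvgPool"],
    "CNN3": [64, "MP", 64, 64, 64, "MP", 256, 256, 256, "MP",
             256, 256, 256, "MP", 512, 512, 512, "AAvgPool"],
}

#: temporal-CNN table (unambiguous in print)
TEMPORAL_ARCHS: dict[str, list] = {
    "TCNN1": [64, 64, "MP", 128, 128, 128, "MP", 128, 128, 128, "MP",
              256, 256, 256],
    "TCNN2": [64, 64, "MP", 128, 128, 128, "MP", 256, 256, 256, "MP",
              256, 256, 256],
    "TCNN3": [64, 64, "MP", 128, 128, 128, "MP", 256, 256, 256, "MP",
              512, 512, 512],
}

#: published trainable-parameter counts (millions) — diagnostic reference
#: for :func:`report_table2`, never asserted.
TABLE2_REFERENCE = {
    "standalone": {"ResNet18": 14.0, "ResNet50": 24.0, "VGG16": 134.0},
    # (rep, size): {temporal: {layers: millions}}
    "hybrid": {
        ("CNN1", "S"): {"TCNN": 3.8, "LSTM": {1: 1.2, 3: 1.4},
                        "GRU": {1: 1.1, 3: 1.3}, "LMU": {1: 1.0, 3: 1.1}},
        ("CNN1", "L"): {"TCNN": 9.8, "LSTM": {1: 2.8, 3: 7.0},
                        "GRU": {1: 2.4, 3: 5.1}, "LMU": {1: 1.6, 3: 2.8}},
        ("CNN2", "S"): {"TCNN": 5.3, "LSTM": {1: 2.9, 3: 3.1},
                        "GRU": {1: 2.8, 3: 3.0}, "LMU": {1: 2.6, 3: 2.7}},
        ("CNN2", "L"): {"TCNN": 11.3, "LSTM": {1: 4.8, 3: 9.0},
                        "GRU": {1: 4.3, 3: 7.5}, "LMU": {1: 3.3, 3: 4.5}},
        ("CNN3", "S"): {"TCNN": 17.6, "LSTM": {1: 15.4, 3: 15.7},
                        "GRU": {1: 15.3, 3: 15.5}, "LMU": {1: 15.0, 3: 15.1}},
        ("CNN3", "L"): {"TCNN": 23.6, "LSTM": {1: 18.2, 3: 22.4},
                        "GRU": {1: 17.4, 3: 20.5}, "LMU": {1: 15.9, 3: 17.0}},
    },
}

HIDDEN_SIZES = {"S": 128, "L": 512}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer token list for a conv net: ints are 3x3 convs (+BN+ReLU),
    'MP' is 2x2 max pooling, 'AAvgPool' the final adaptive pool."""

    name: str
    layers: tuple
    in_channels: int = 1

    def __post_init__(self) -> None:
        for tok in self.layers:
            if isinstance(tok, int):
                if tok <= 0:
                    raise ValidationError(f"bad channel count token {tok!r}")
            elif tok not in ("MP", "AAvgPool"):
                raise ValidationError(f"unknown layer token {tok!r}")

    def conv_channels(self) -> list[int]:
        return [t for t in self.layers if isinstance(t, int)]


def load_architectures(path: str | Path | None = None) -> dict[str, ArchitectureSpec]:
    """Default architecture table, optionally overridden by a YAML mapping
    ``{name: [tokens...]}``."""
    table = {**REPRESENTATION_ARCHS, **TEMPORAL_ARCHS}
    if path is not None:
        with open(path) as fh:
            for name, tokens in (yaml.safe_load(fh) or {}).items():
                table[name] = tokens
    return {name: ArchitectureSpec(name=name, layers=tuple(tokens))
            for name, tokens in table.items()}


@dataclass(frozen=True)
class HybridSpec:
    representation: str = "CNN1"
    temporal: str = "GRU"  # TCNN|TCNN1..3|LSTM|GRU|LMU|GRU+LMU
    size: str = "S"        # S/L: hidden 128/512 for RNNs, TCNN1/TCNN3 for TCNN
    rnn_layers: int = 1
    n_classes: int = 100
    memory_size: int = 64
    theta: float = 26.0

    def __post_init__(self) -> None:
        if self.representation not in ("CNN1", "CNN2", "CNN3"):
            raise ValidationError(f"unknown representation {self.representation!r}")
        t = self.temporal.upper()
        if t not in ("TCNN", "TCNN1", "TCNN2", "TCNN3", "LSTM", "GRU", "LMU",
                     "GRU+LMU"):
            raise ValidationError(f"unknown temporal block {self.temporal!r}")
        if t == "GRU+LMU" and self.rnn_layers < 2:
            raise ValidationError("GRU+LMU requires at least 2 layers")
        if self.size not in HIDDEN_SIZES:
            raise ValidationError("size must be 'S' or 'L'")


# ---------------------------------------------------------------------------
# conv net assembly


def _conv_net(spec: ArchitectureSpec, aavg_out: tuple[int, int],
              rng: np.random.Generator, dtype=np.float32,
              batch_norm: bool = True) -> tuple[_nn.Sequential, int]:
    """Build a Sequential from tokens; returns (net, flat feature length)."""
    layers: list = []
    cin = spec.in_channels
    last_conv = cin
    for tok in spec.layers:
        if tok == "MP":
            layers.append(_nn.MaxPool2d(2))
        elif tok == "AAvgPool":
            layers.append(_nn.AdaptiveAvgPool2d(aavg_out))
        else:
            layers.append(_nn.Conv2d(cin, tok, kernel=3, rng=rng, dtype=dtype))
            if batch_norm:
                layers.append(_nn.BatchNorm2d(tok, dtype=dtype))
            layers.append(_nn.ReLU())
            cin = last_conv = tok
    layers.append(_nn.Flatten())
    feat = last_conv * aavg_out[0] * aavg_out[1]
    return _nn.Sequential(layers), feat


def build_representation(name: str = "CNN1", rng=None, dtype=np.float32,
                         archs: dict | None = None
                         ) -> tuple[_nn.Sequential, int]:
    """Representation CNN over a (1, n_mels, n_frames) slice; adaptive
    (2, 1) pooling makes the feature length input-size independent:
    CNN1 -> 256, CNN2 -> 512, CNN3 -> 1024."""
    archs = archs or load_architectures()
    if name not in ("CNN1", "CNN2", "CNN3"):
        raise ValidationError(f"unknown representation CNN {name!r}")
    rng = rng or np.random.default_rng(0)
    return _conv_net(archs[name], (2, 1), rng, dtype)


def build_temporal_cnn(name: str = "TCNN1", rng=None, dtype=np.float32,
                       archs: dict | None = None
                       ) -> tuple[_nn.Sequential, int]:
    """Temporal CNN over the (1, feature_dim, n_slides) concatenated map; a
    final adaptive (1, 1) average pool keeps the head input equal to the last
    conv width."""
    archs = archs or load_architectures()
    if name not in ("TCNN1", "TCNN2", "TCNN3"):
        raise ValidationError(f"unknown temporal CNN {name!r}")
    rng = rng or np.random.default_rng(1)
    spec = archs[name]
    spec = ArchitectureSpec(name=spec.name,
                            layers=tuple(spec.layers) + ("AAvgPool",))
    return _conv_net(spec, (1, 1), rng, dtype)


def build_head(in_features: int, n_classes: int, rng=None,
               dtype=np.float32) -> _nn.Sequential:
    """Classification block: 512 ReLU units, dropout 0.5, n_classes output."""
    rng = rng or np.random.default_rng(2)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    return _nn.Sequential([
        _nn.Linear(in_features, 512, rng=rng, dtype=dtype),
        _nn.ReLU(),
        _nn.Dropout(0.5, rng=drop_rng),
        _nn.Linear(512, n_classes, rng=rng, dtype=dtype),
    ])


# input slices are dB in [-80, 0]; map to [-1, 1] for conditioning
_INPUT_SCALE = 1.0 / 40.0
_INPUT_SHIFT = 1.0


class HybridModel:
    """Shared-weight representation CNN per slide -> temporal block ->
    classification head (see Fig-style pipeline).  Forward consumes a batch
    of slide stacks shaped (batch, n_slides, n_mels, n_frames)."""

    def __init__(self, spec: HybridSpec, seed: int = 0, dtype=np.float32,
                 archs: dict | None = None):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.input_norm = _nn.ScaleShift(_INPUT_SCALE, _INPUT_SHIFT)
        self.representation, self.feature_dim = build_representation(
            spec.representation, rng=rng, dtype=dtype, archs=archs)
        t = spec.temporal.upper()
        self.temporal_kind = "tcnn" if t.startswith("TCNN") else "rnn"
        if self.temporal_kind == "tcnn":
            name = t if t != "TCNN" else {"S": "TCNN1", "L": "TCNN3"}[spec.size]
            self.temporal, head_in = build_temporal_cnn(
                name, rng=rng, dtype=dtype, archs=archs)
            self.temporal_name = name
            self.rnn_layers = []
        else:
            hidden = HIDDEN_SIZES[spec.size]
            stack = rc.make_stack(t.lower(), self.feature_dim, hidden,
                                  spec.rnn_layers,
                                  memory_size=spec.memory_size,
                                  theta=spec.theta,
                                  seed=int(rng.integers(2**20)), dtype=dtype)
            self.stack = stack
            self.rnn_layers = [self._wrap(c) for c in stack.cells]
            self.temporal = None
            self.temporal_name = t
            head_in = hidden
        self.head = build_head(head_in, spec.n_classes,
                               rng=np.random.default_rng(rng.integers(2**31)),
                               dtype=dtype)

    @staticmethod
    def _wrap(cell):
        if isinstance(cell, rc.GRUCell):
            return _nn.GRULayer(cell)
        if isinstance(cell, rc.LSTMCell):
            return _nn.LSTMLayer(cell)
        if isinstance(cell, rc.LMUCellParams):
            return _nn.LMULayer(cell)
        raise ValidationError(f"unknown cell {type(cell)}")

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, stacks: np.ndarray, train: bool = False
                       ) -> np.ndarray:
        x = np.asarray(stacks, self.dtype)
        if x.ndim == 3:
            x = x[None]
        B, T, H, W = x.shape
        if T < 1:
            raise ValidationError("need at least one slide")
        self._bt = (B, T)
        flat = x.reshape(B * T, 1, H, W)
        flat = self.input_norm.forward(flat, train)
        feats = self.representation.forward(flat, train)  # (B*T, F)
        self.last_features = feats.reshape(B, T, -1)
        if self.temporal_kind == "rnn":
            out = self.last_features
            for layer in self.rnn_layers:
                out = layer.forward(out, train)
            summed = out.sum(axis=1)  # outputs summed over all time-steps
        else:
            fmap = self.last_features.transpose(0, 2, 1)[:, None]  # (B,1,F,T)
            summed = self.temporal.forward(fmap, train)
        self.last_penultimate = None  # filled below via head split
        # run head, capturing the penultimate activation (input to final layer)
        h = summed
        for layer in self.head.layers[:-1]:
            h = layer.forward(h, train)
        self.last_penultimate = h
        return self.head.layers[-1].forward(h, train)

    def forward(self, stacks: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities, one row per sample, each summing to 1."""
        return _nn.softmax(self.forward_logits(stacks, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head.layers):
            d = layer.backward(d)
        B, T = self._bt
        if self.temporal_kind == "rnn":
            d = np.repeat(d[:, None, :], T, axis=1)  # grad of sum over time
            for layer in reversed(self.rnn_layers):
                d = layer.backward(d)
            dfeats = d.reshape(B * T, -1)
        else:
            d = self.temporal.backward(d)  # (B,1,F,T)
            dfeats = d[:, 0].transpose(0, 2, 1).reshape(B * T, -1)
        self.representation.backward(dfeats)

    # -- parameters ----------------------------------------------------------

    def param_items(self):
        items = [("rep." + k, v, g)
                 for k, v, g in self.representation.param_items()]
        if self.temporal_kind == "rnn":
            for i, layer in enumerate(self.rnn_layers):
                items += [(f"rnn{i}." + k, v, g)
                          for k, v, g in layer.param_items()]
        else:
            items += [("tcnn." + k, v, g)
                      for k, v, g in self.temporal.param_items()]
        items += [("head." + k, v, g) for k, v, g in self.head.param_items()]
        return items

    def zero_grad(self):
        for _, _, g in self.param_items():
            g[...] = 0

    def buffer_items(self):
        items = [("rep." + k, v)
                 for k, v in self.representation.buffer_items()]
        if self.temporal_kind == "tcnn":
            items += [("tcnn." + k, v) for k, v in self.temporal.buffer_items()]
        items += [("head." + k, v) for k, v in self.head.buffer_items()]
        return items

    def get_state(self) -> dict:
        state = {name: v.copy() for name, v, _ in self.param_items()}
        state.update({"buf." + name: v.copy()
                      for name, v in self.buffer_items()})
        return state

    def set_state(self, state: dict) -> None:
        for name, v, _ in self.param_items():
            v[...] = state[name]
        for name, v in self.buffer_items():
            v[...] = state["buf." + name]

    def lmu_layers(self):
        return [l for l in self.rnn_layers if isinstance(l, _nn.LMULayer)]


# ---------------------------------------------------------------------------
# stand-alone baselines (standard published configurations, opaque baselines)

VGG16_CONV = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"]


def _vgg16(n_classes: int, rng, dtype) -> _nn.Sequential:
    layers: list = []
    cin = 3
    for tok in VGG16_CONV:
        if tok == "M":
            layers.append(_nn.MaxPool2d(2))
        else:
            layers.append(_nn.Conv2d(cin, tok, kernel=3, rng=rng, dtype=dtype))
            layers.append(_nn.ReLU())
            cin = tok
    drng = np.random.default_rng(rng.integers(2**31))
    layers += [
        _nn.Flatten(),
        _nn.Linear(512 * 7 * 7, 4096, rng=rng, dtype=dtype),
        _nn.ReLU(), _nn.Dropout(0.5, rng=drng),
        _nn.Linear(4096, 4096, rng=rng, dtype=dtype),
        _nn.ReLU(), _nn.Dropout(0.5, rng=drng),
        _nn.Linear(4096, n_classes, rng=rng, dtype=dtype),
    ]
    return _nn.Sequential(layers)


def _conv_bn(cin, cout, kernel, stride, rng, dtype):
    return [_nn.Conv2d(cin, cout, kernel=kernel, stride=stride,
                       pad=kernel // 2, rng=rng, dtype=dtype, bias=False),
            _nn.BatchNorm2d(cout, dtype=dtype)]


def _basic_block(cin, cout, stride, rng, dtype):
    main = _nn.Sequential(
        _conv_bn(cin, cout, 3, stride, rng, dtype) + [_nn.ReLU()]
        + _conv_bn(cout, cout, 3, 1, rng, dtype))
    short = None
    if stride != 1 or cin != cout:
        short = _nn.Sequential(_conv_bn(cin, cout, 1, stride, rng, dtype))
    return _nn.ResidualBlock(main, short)


def _bottleneck(cin, mid, cout, stride, rng, dtype):
    main = _nn.Sequential(
        _conv_bn(cin, mid, 1, 1, rng, dtype) + [_nn.ReLU()]
        + _conv_bn(mid, mid, 3, stride, rng, dtype) + [_nn.ReLU()]
        + _conv_bn(mid, cout, 1, 1, rng, dtype))
    short = None
    if stride != 1 or cin != cout:
        short = _nn.Sequential(_conv_bn(cin, cout, 1, stride, rng, dtype))
    return _nn.ResidualBlock(main, short)


def _resnet(n_classes: int, rng, dtype, depth: int) -> _nn.Sequential:
    layers = _conv_bn(3, 64, 7, 2, rng, dtype) + [
        _nn.ReLU(), _nn.MaxPool2d(3, stride=2, pad=1)]
    if depth == 18:
        cfg = [(64, 2, 1), (128, 2, 2), (256, 2, 2), (512, 2, 2)]
        cin = 64
        for cout, blocks, stride in cfg:
            for b in range(blocks):
                layers.append(_basic_block(cin, cout, stride if b == 0 else 1,
                                           rng, dtype))
                cin = cout
        feat = 512
    elif depth == 50:
        cfg = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2),
               (512, 2048, 3, 2)]
        cin = 64
        for mid, cout, blocks, stride in cfg:
            for b in range(blocks):
                layers.append(_bottleneck(cin, mid, cout,
                                          stride if b == 0 else 1, rng, dtype))
                cin = cout
        feat = 2048
    else:
        raise ValidationError(f"unsupported ResNet depth {depth}")
    layers += [_nn.AdaptiveAvgPool2d((1, 1)), _nn.Flatten(),
               _nn.Linear(feat, n_classes, rng=rng, dtype=dtype)]
    return _nn.Sequential(layers)


class StandaloneModel:
    """ImageNet-style classifier over the whole-clip 3x224x224 image."""

    def __init__(self, name: str, n_classes: int = 100, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.name = name
        self.dtype = dtype
        if name == "VGG16":
            self.net = _vgg16(n_classes, rng, dtype)
        elif name == "ResNet18":
            self.net = _resnet(n_classes, rng, dtype, 18)
        elif name == "ResNet50":
            self.net = _resnet(n_classes, rng, dtype, 50)
        else:
            raise ValidationError(f"unknown stand-alone model {name!r}")
        self.n_classes = n_classes

    def forward_logits(self, images: np.ndarray, train: bool = False):
        x = np.asarray(images, self.dtype)
        if x.ndim == 3:
            x = x[None]
        x = x * _INPUT_SCALE + _INPUT_SHIFT  # same dB normalization
        return self.net.forward(x, train)

    def forward(self, images: np.ndarray, train: bool = False):
        return _nn.softmax(self.forward_logits(images, train))

    def param_items(self):
        return self.net.param_items()


def assemble_hybrid(spec: HybridSpec, seed: int = 0, dtype=np.float32,
                    archs: dict | None = None) -> HybridModel:
    """Build a hybrid model mapping SlideStack batches to class probabilities."""
    return HybridModel(spec, seed=seed, dtype=dtype, archs=archs)


def assemble_standalone(name: str, n_classes: int = 100,
                        seed: int = 0) -> StandaloneModel:
    return StandaloneModel(name, n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# parameter counting and the published-count comparison


def count_model_parameters(model) -> int:
    """Exact trainable-parameter count (fixed LMU system matrices and BN
    running statistics excluded)."""
    if model is None:
        return 0
    if hasattr(model, "param_items"):
        return int(sum(v.size for _, v, _ in model.param_items()))
    return rc.trainable_parameter_count(model)


def hybrid_count(rep: str, temporal: str, size: str, layers: int,
                 n_classes: int = 100) -> int:
    model = assemble_hybrid(HybridSpec(representation=rep, temporal=temporal,
                                       size=size, rnn_layers=layers,
                                       n_classes=n_classes))
    return count_model_parameters(model)


def report_table2(n_classes: int = 100, include_standalone: bool = True
                  ) -> "object":
    """Recompute every model's trainable-parameter count (in millions, one
    decimal) next to the published values, with deltas.

    This is a *diagnostic* report: the printed source table for the
    representation CNNs is ambiguous and the published stand-alone counts
    suggest undocumented head modifications, so deltas are reported, never
    asserted."""
    import pandas as pd

    rows = []
    if include_standalone:
        for name, ref in TABLE2_REFERENCE["standalone"].items():
            n = count_model_parameters(assemble_standalone(name, n_classes))
            rows.append({"model": name, "size": "-", "layers": "-",
                         "millions": round(n / 1e6, 1), "published": ref,
                         "delta": round(n / 1e6 - ref, 1)})
    for (rep, size), cols in TABLE2_REFERENCE["hybrid"].items():
        for temporal, ref in cols.items():
            if temporal == "TCNN":
                n = hybrid_count(rep, "TCNN", size, 1, n_classes)
                rows.append({"model": f"{rep}+TCNN", "size": size,
                             "layers": "-", "millions": round(n / 1e6, 1),
                             "published": ref,
                             "delta": round(n / 1e6 - ref, 1)})
            else:
                for layers, r in ref.items():
                    n = hybrid_count(rep, temporal, size, layers, n_classes)
                    rows.append({"model": f"{rep}+{temporal}", "size": size,
                                 "layers": layers,
                                 "millions": round(n / 1e6, 1),
                                 "published": r,
                                 "delta": round(n / 1e6 - r, 1)})
    return pd.DataFrame(rows)


def describe_model(model: HybridModel | StandaloneModel) -> str:
    """Human-readable layer/parameter summary."""
    lines = []
    if isinstance(model, HybridModel):
        lines.append(f"Hybrid {model.spec.representation}+"
                     f"{model.temporal_name} size={model.spec.size} "
                     f"layers={model.spec.rnn_layers} "
                     f"classes={model.spec.n_classes}")
        lines.append(f"  representation feature dim: {model.feature_dim}")
    else:
        lines.append(f"Stand-alone {model.name} classes={model.n_classes}")
    lines.append(f"  trainable parameters: {count_model_parameters(model):,}")
    return "\n".join(lines)
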