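"""Declarative convolutional-mixer architecture with analytic accounting.

The mixer stacks two standard 5x5 convolutions (16, 32 filters) and two
5x5 depthwise-separable convolutions (64, 128 filters), each followed by
2x2 average pooling, then dropout, flatten and a dense head over the
five dementia stages.  Every layer's output shape, trainable-parameter
count and multiply-accumulate count is derived in closed form:

* conv/pool spatial extent: ``floor((I - F + 2P) / S) + 1``
* conv parameters: ``(kh * kw * C_in + 1) * F``
* separable conv parameters: depthwise kernel ``kh * kw * C_in`` (no
  bias) + pointwise ``C_in * F`` + one bias vector ``F``
* dense parameters: ``(fan_in + 1) * units``

For a 224x224 3-channel input with valid padding the default mixer has
exactly 3,305,221 trainable parameters.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "build_default_arch",
    "build_small_arch",
    "layer_output_shape",
    "count_params",
    "count_flops",
    "summary_table",
]

_KINDS = {
    "conv",
    "separable_conv",
    "avg_pool",
    "max_pool",
    "dropout",
    "flatten",
    "dense",
    "softmax",
}

_INITIALIZERS = {"glorot_normal", "glorot_uniform", "he_normal", "he_uniform"}


@dataclasses.dataclass
class LayerSpec:
    kind: str
    kernel: tuple[int, int] | None = None
    filters: int | None = None
    padding: str = "valid"
    stride: int = 1
    rate: float | None = None
    units: int | None = None
    activation: str = "none"
    initializer: str = "glorot_normal"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; options: {sorted(_KINDS)}")
        if self.kernel is not None:
            self.kernel = (int(self.kernel[0]), int(self.kernel[1]))
            if min(self.kernel) < 1:
                raise ValueError(f"kernel dims must be >= 1, got {self.kernel}")
        if self.rate is not None and not 0.0 <= self.rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {self.rate}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {self.padding!r}")
        if self.initializer not in _INITIALIZERS:
            raise ValueError(
                f"unknown initializer {self.initializer!r}; options: {sorted(_INITIALIZERS)}"
            )


def _pad(pixels: int, kernel: int, padding: str) -> int:
    return (kernel - 1) // 2 if padding == "same" else 0


def layer_output_shape(layer: LayerSpec, in_shape: tuple) -> tuple:
    """Shape produced by one layer; raises if any spatial dim collapses."""
    if layer.kind in ("conv", "separable_conv"):
        h, w, c = in_shape
        kh, kw = layer.kernel
        oh = (h - kh + 2 * _pad(h, kh, layer.padding)) // layer.stride + 1
        ow = (w - kw + 2 * _pad(w, kw, layer.padding)) // layer.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"{layer.kind} {kh}x{kw} collapses spatial dims {h}x{w} -> {oh}x{ow}"
            )
        return (oh, ow, layer.filters)
    if layer.kind in ("avg_pool", "max_pool"):
        h, w, c = in_shape
        # pool defaults: 2x2 window, stride 2, floor semantics
        f = layer.kernel[0] if layer.kernel else 2
        s = 2 if (layer.kernel is None and layer.stride == 1) else layer.stride
        oh = (h - f) // s + 1
        ow = (w - f) // s + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"pool {f}x{f}/{s} collapses spatial dims {h}x{w}")
        return (oh, ow, c)
    if layer.kind == "dropout":
        return tuple(in_shape)
    if layer.kind == "flatten":
        n = 1
        for d in in_shape:
            n *= d
        return (n,)
    if layer.kind == "dense":
        if len(in_shape) != 1:
            raise ValueError(f"dense layer needs a flat input, got shape {in_shape}")
        return (layer.units,)
    if layer.kind == "softmax":
        return tuple(in_shape)
    raise AssertionError(layer.kind)


def _layer_params(layer: LayerSpec, in_shape: tuple) -> int:
    if layer.kind == "conv":
        kh, kw = layer.kernel
        c = in_shape[2]
        return (kh * kw * c + 1) * layer.filters
    if layer.kind == "separable_conv":
        kh, kw = layer.kernel
        c = in_shape[2]
        return kh * kw * c + c * layer.filters + layer.filters
    if layer.kind == "dense":
        return (in_shape[0] + 1) * layer.units
    return 0


def _layer_macs(layer: LayerSpec, in_shape: tuple, out_shape: tuple) -> int:
    if layer.kind == "conv":
        kh, kw = layer.kernel
        oh, ow, f = out_shape
        return oh * ow * f * (kh * kw * in_shape[2])
    if layer.kind == "separable_conv":
        kh, kw = layer.kernel
        oh, ow, f = out_shape
        c = in_shape[2]
        return oh * ow * (kh * kw * c) + oh * ow * c * f
    if layer.kind == "dense":
        return in_shape[0] * layer.units
    return 0


@dataclasses.dataclass
class ArchitectureSpec:
    """Ordered layers with derived shapes, parameter and MAC accounts."""

    input_shape: tuple[int, int, int]
    layers: list[LayerSpec]

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(d) for d in self.input_shape)
        self._resolve()

    def _resolve(self) -> None:
        shapes, params, macs = [], [], []
        shape = self.input_shape
        chain = [shape]
        for layer in self.layers:
            try:
                out = layer_output_shape(layer, shape)
            except ValueError as exc:
                raise ValueError(
                    f"shape chain {' -> '.join(map(str, chain))} failed at "
                    f"layer {layer.name or layer.kind}: {exc}"
                ) from exc
            shapes.append(out)
            params.append(_layer_params(layer, shape))
            macs.append(_layer_macs(layer, shape, out))
            shape = out
            chain.append(out)
        self.output_shapes = shapes
        self.param_counts = params
        self.mac_counts = macs

    @property
    def total_params(self) -> int:
        return sum(self.param_counts)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "input_shape": list(self.input_shape),
            "layers": [
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(layer).items()
                    if v is not None and v != ""
                }
                for layer in self.layers
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ArchitectureSpec":
        text = str(source)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except (OSError, ValueError):
            pass
        doc = yaml.safe_load(text)
        layers = [LayerSpec(**d) for d in doc["layers"]]
        return cls(tuple(doc["input_shape"]), layers)


def build_default_arch(
    input_shape: tuple[int, int, int] = (224, 224, 3),
    initializer: str = "glorot_normal",
    pooling: str = "avg",
    n_classes: int = 5,
) -> ArchitectureSpec:
    """The full-size mixer: conv16 -> conv32 -> sep64 -> sep128 head.

    Needs input extent >= 68 so all four valid 5x5 convolutions and 2x2
    pools survive (224 -> 220 -> 110 -> 106 -> 53 -> 49 -> 24 -> 20 -> 10).
    """
    h, w, _ = input_shape
    if min(h, w) < 68:
        chain = "I -> I-4 -> /2 -> -4 -> /2 -> -4 -> /2 -> -4 -> /2"
        raise ValueError(
            f"input {h}x{w} too small for four valid 5x5 convs + 2x2 pools "
            f"(chain {chain} needs >= 68 pixels per side)"
        )
    pool = "avg_pool" if pooling == "avg" else "max_pool"
    k = dict(kernel=(5, 5), padding="valid", stride=1, activation="relu", initializer=initializer)
    layers = [
        LayerSpec("conv", filters=16, name="conv1", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool1"),
        LayerSpec("conv", filters=32, name="conv2", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool2"),
        LayerSpec("separable_conv", filters=64, name="sep1", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool3"),
        LayerSpec("separable_conv", filters=128, name="sep2", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool4"),
        LayerSpec("dropout", rate=0.5, name="dropout"),
        LayerSpec("flatten", name="flatten"),
        LayerSpec("dense", units=256, activation="relu", initializer=initializer, name="dense1"),
        LayerSpec("dense", units=n_classes, activation="none", initializer=initializer, name="dense2"),
        LayerSpec("softmax", name="softmax"),
    ]
    return ArchitectureSpec(input_shape, layers)


def build_small_arch(
    input_shape: tuple[int, int, int] = (64, 64, 1),
    initializer: str = "glorot_normal",
    pooling: str = "avg",
    n_classes: int = 5,
) -> ArchitectureSpec:
    """Scaled mixer for small inputs: same conv-conv-sep-sep structure
    with 3x3 kernels, 8/16/32/64 filters and a 64-unit dense layer.

    Valid at 64x64 (64 -> 62 -> 31 -> 29 -> 14 -> 12 -> 6 -> 4 -> 2);
    used for desk-scale training experiments.
    """
    pool = "avg_pool" if pooling == "avg" else "max_pool"
    k = dict(kernel=(3, 3), padding="valid", stride=1, activation="relu", initializer=initializer)
    layers = [
        LayerSpec("conv", filters=8, name="conv1", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool1"),
        LayerSpec("conv", filters=16, name="conv2", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool2"),
        LayerSpec("separable_conv", filters=32, name="sep1", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool3"),
        LayerSpec("separable_conv", filters=64, name="sep2", **k),
        LayerSpec(pool, kernel=(2, 2), stride=2, name="pool4"),
        LayerSpec("dropout", rate=0.5, name="dropout"),
        LayerSpec("flatten", name="flatten"),
        LayerSpec("dense", units=64, activation="relu", initializer=initializer, name="dense1"),
        LayerSpec("dense", units=n_classes, activation="none", initializer=initializer, name="dense2"),
        LayerSpec("softmax", name="softmax"),
    ]
    return ArchitectureSpec(input_shape, layers)


def count_params(arch: ArchitectureSpec) -> tuple[list[int], int]:
    """Per-layer and total trainable parameter counts."""
    return list(arch.param_counts), arch.total_params


def count_flops(arch: ArchitectureSpec, convention: str = "macs") -> tuple[list[int], int]:
    """Per-layer and total compute; 'macs' counts multiply-accumulates,
    'flops2x' counts each MAC as two floating-point operations."""
    if convention not in ("macs", "flops2x"):
        raise ValueError("convention must be 'macs' or 'flops2x'")
    mult = 2 if convention == "flops2x" else 1
    per = [m * mult for m in arch.mac_counts]
    return per, sum(per)


def summary_table(arch: ArchitectureSpec) -> str:
    """Human-readable per-layer shape / parameter / MAC table."""
    lines = [
        f"{'layer':<10}{'kind':<16}{'output shape':<18}{'params':>12}{'MACs':>14}",
        "-" * 70,
        f"{'input':<10}{'':<16}{str(arch.input_shape):<18}{'':>12}{'':>14}",
    ]
    for layer, shape, p, m in zip(
        arch.layers, arch.output_shapes, arch.param_counts, arch.mac_counts
    ):
        lines.append(
            f"{layer.name or layer.kind:<10}{layer.kind:<16}{str(shape):<18}{p:>12,}{m:>14,}"
        )
    lines.append("-" * 70)
    _, total_macs = count_flops(arch, "macs")
    lines.append(f"{'total':<44}{arch.total_params:>12,}{total_macs:>14,}")
    return "\n".join(lines)
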