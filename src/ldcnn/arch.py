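"""Architecture descriptions as data, with symbolic shape propagation.

The two built-in networks are the published per-beat classifiers:

* ``mitbih5`` — five-class net for 1-second (360-sample) windows: five
  same-padded conv stages (filters 16→256, kernels 13→21), each followed by
  average pooling (pool 3, stride 2), then flatten → dropout 0.5 →
  dense 35 → dense 5 with softmax.
* ``ptb2`` — binary net for 187-sample windows: four valid-padded conv
  blocks ([16,16] k5, [32,32] k3, [32,32] k3, [256,256] k3) with max-pool 2
  and dropouts 0.1/0.1/0.1/0.2, global max-pool, dense 64 → 64 → 1 with
  sigmoid.  (The published table prints pooling stride 1, but its own
  output-shape column — 179→89, 85→42, 38→19 — requires stride = pool = 2;
  the shapes win.)

``propagate_shapes`` computes every intermediate (length, channels) pair
without building the network, and is the oracle the built network's runtime
activations are checked against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .errors import ArchitectureError

_KINDS = {
    "conv1d", "avgpool1d", "maxpool1d", "globalmaxpool1d",
    "flatten", "dropout", "dense",
}


@dataclass(frozen=True)
class LayerSpec:
    """One layer's hyperparameters; fields irrelevant to ``kind`` stay None."""

    kind: str
    filters: int | None = None          # conv filters / dense units
    kernel_size: int | None = None
    activation: str | None = None       # relu | softmax | sigmoid | None
    padding: str | None = None          # same | valid
    stride: int | None = None
    pool_size: int | None = None
    dropout_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ArchitectureError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d":
            if not self.filters or not self.kernel_size or self.kernel_size < 1:
                raise ArchitectureError("conv1d needs filters and kernel_size >= 1")
            if self.padding not in ("same", "valid"):
                raise ArchitectureError("conv1d padding must be 'same' or 'valid'")
        if self.kind in ("avgpool1d", "maxpool1d"):
            if not self.pool_size or (self.stride or 1) < 1:
                raise ArchitectureError("pooling needs pool_size and stride >= 1")
        if self.kind == "dense" and not self.filters:
            raise ArchitectureError("dense needs a unit count")
        if self.kind == "dropout" and not 0 <= (self.dropout_rate or 0) < 1:
            raise ArchitectureError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered layer stack with its input geometry."""

    name: str
    input_length: int
    layers: tuple[LayerSpec, ...]
    n_outputs: int
    input_channels: int = 1

    def __post_init__(self) -> None:
        propagate_shapes(self)  # validates every intermediate length

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "n_outputs": self.n_outputs,
            "layers": [
                {k: v for k, v in asdict(l).items() if v is not None}
                for l in self.layers
            ],
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def from_json(text: str) -> "ArchitectureSpec":
        raw = json.loads(text)
        return ArchitectureSpec(
            name=raw["name"],
            input_length=raw["input_length"],
            input_channels=raw.get("input_channels", 1),
            n_outputs=raw["n_outputs"],
            layers=tuple(LayerSpec(**l) for l in raw["layers"]),
        )


def _conv(filters: int, kernel: int, padding: str) -> LayerSpec:
    return LayerSpec(
        kind="conv1d", filters=filters, kernel_size=kernel,
        activation="relu", padding=padding, stride=1,
    )


def builtin_architecture(name: str) -> ArchitectureSpec:
    """Return one of the two published per-beat classifier architectures."""
    if name == "mitbih5":
        layers: list[LayerSpec] = []
        for filters, kernel in ((16, 13), (32, 15), (64, 17), (128, 19), (256, 21)):
            layers.append(_conv(filters, kernel, "same"))
            layers.append(LayerSpec(kind="avgpool1d", pool_size=3, stride=2))
        layers += [
            LayerSpec(kind="flatten"),
            LayerSpec(kind="dropout", dropout_rate=0.5),
            LayerSpec(kind="dense", filters=35, activation="relu"),
            LayerSpec(kind="dense", filters=5, activation="softmax"),
        ]
        return ArchitectureSpec(
            name=name, input_length=360, layers=tuple(layers), n_outputs=5
        )
    if name == "ptb2":
        layers = []
        for filters, kernel, rate in (
            (16, 5, 0.1), (32, 3, 0.1), (32, 3, 0.1),
        ):
            layers.append(_conv(filters, kernel, "valid"))
            layers.append(_conv(filters, kernel, "valid"))
            layers.append(LayerSpec(kind="maxpool1d", pool_size=2, stride=2))
            layers.append(LayerSpec(kind="dropout", dropout_rate=rate))
        layers.append(_conv(256, 3, "valid"))
        layers.append(_conv(256, 3, "valid"))
        layers += [
            LayerSpec(kind="globalmaxpool1d"),
            LayerSpec(kind="dropout", dropout_rate=0.2),
            LayerSpec(kind="dense", filters=64, activation="relu"),
            LayerSpec(kind="dense", filters=64, activation="relu"),
            LayerSpec(kind="dense", filters=1, activation="sigmoid"),
        ]
        return ArchitectureSpec(
            name=name, input_length=187, layers=tuple(layers), n_outputs=1
        )
    raise ArchitectureError(f"unknown architecture {name!r}")


@dataclass(frozen=True)
class Shape:
    """Activation geometry after a layer: (length, channels) or flat features."""

    length: int | None
    channels: int | None
    features: int | None = None

    @property
    def size(self) -> int:
        if self.features is not None:
            return self.features
        return self.length * self.channels  # type: ignore[operator]


def propagate_shapes(spec: ArchitectureSpec) -> list[Shape]:
    """Symbolically propagate the input shape through every layer.

    Rules: same-padded conv preserves length; valid conv gives
    L − kernel + 1; pooling gives floor((L − pool)/stride) + 1; flatten
    gives L×C features; global max-pool keeps one value per channel; dense
    gives its unit count.  Raises naming the first layer whose output
    length would be non-positive.
    """
    shapes: list[Shape] = []
    length: int | None = spec.input_length
    channels: int | None = spec.input_channels
    features: int | None = None
    for i, layer in enumerate(spec.layers):
        where = f"layer {i} ({layer.kind})"
        if layer.kind == "conv1d":
            if length is None:
                raise ArchitectureError(f"{where}: conv after flatten")
            if layer.padding == "valid":
                length = length - layer.kernel_size + 1
            channels = layer.filters
        elif layer.kind in ("avgpool1d", "maxpool1d"):
            if length is None:
                raise ArchitectureError(f"{where}: pooling after flatten")
            length = (length - layer.pool_size) // (layer.stride or 1) + 1
        elif layer.kind == "globalmaxpool1d":
            if length is None or length < 1:
                raise ArchitectureError(f"{where}: nothing to pool globally")
            features, length, channels = channels, None, None
        elif layer.kind == "flatten":
            if length is None:
                raise ArchitectureError(f"{where}: flatten after flatten")
            features, length, channels = length * channels, None, None
        elif layer.kind == "dense":
            if features is None:
                raise ArchitectureError(f"{where}: dense before flatten/global pool")
            features = layer.filters
        elif layer.kind == "dropout":
            pass
        if length is not None and length < 1:
            raise ArchitectureError(f"{where}: non-positive output length {length}")
        shapes.append(Shape(length=length, channels=channels, features=features))
    return shapes


def flat_feature_size(spec: ArchitectureSpec) -> int:
    """Size of the first flatten/global-pool output (the feature vector)."""
    for layer, shape in zip(spec.layers, propagate_shapes(spec)):
        if layer.kind in ("flatten", "globalmaxpool1d"):
            return shape.features  # type: ignore[return-value]
    raise ArchitectureError(f"architecture {spec.name!r} never flattens")
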