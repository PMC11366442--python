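"""Domain containers shared across the pipeline.

The pipeline's currency is the annotated single-lead record (:class:`EcgRecord`)
and the table of fixed-length, R-peak-anchored beat windows
(:class:`BeatDataset`).  Class vocabularies are carried explicitly by
:class:`ClassScheme` so that label integers are never ambiguous: index ``i``
always means ``scheme.classes[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import LabelError

#: Sentinel returned by symbol mapping for beats outside the scheme's vocabulary.
EXCLUDE = "EXCLUDE"


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: R-peak sample position plus its beat code.

    ``sample_index`` is 0-based into the record's signal array.  ``symbol`` is
    the single-character beat code used by PhysioNet annotators (N, L, R, A, V,
    ... for beats; '+', '~', ... for non-beat markers).
    """

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"negative sample_index {self.sample_index}")
        if not self.symbol:
            raise ValueError("empty annotation symbol")


@dataclass
class EcgRecord:
    """A sampled single-lead ECG waveform with beat annotations.

    signal
        Amplitudes in mV (or normalized units after preprocessing).
    sampling_rate
        Hz.
    annotations
        Beat annotations sorted by sample index, indices within the signal.
    """

    signal: np.ndarray
    sampling_rate: float
    record_id: str = "record"
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.signal.size
        prev = -1
        for ann in self.annotations:
            if not prev < ann.sample_index < n:
                raise ValueError(
                    "annotation indices must be strictly increasing and inside "
                    f"the signal (got {ann.sample_index} after {prev}, n={n})"
                )
            prev = ann.sample_index

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate


@dataclass(frozen=True)
class ClassScheme:
    """A class vocabulary plus the beat-symbol → class mapping.

    ``classes`` fixes the integer encoding: label index i ⇔ classes[i].
    ``symbol_map`` sends annotation symbols to class labels; symbols absent
    from the map are excluded (see :data:`EXCLUDE`).
    """

    name: str
    classes: tuple[str, ...]
    symbol_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")
        for sym, label in self.symbol_map.items():
            if label not in self.classes:
                raise ValueError(f"symbol {sym!r} maps to unknown class {label!r}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise LabelError(f"unknown class label {label!r} for scheme {self.name}")


@dataclass
class BeatDataset:
    """Fixed-length beat windows with integer class labels.

    windows
        (n_beats, window_length) float array.
    labels
        (n_beats,) integer array; ``labels[i]`` indexes ``scheme.classes``.
    provenance
        Per-beat (record_id, sample_index) pairs; duplicated rows produced by
        resampling share a provenance key, which is how split disjointness is
        defined (and audited).
    meta
        Free-form counters from the producing stage (dropped beats etc.).
    """

    windows: np.ndarray
    labels: np.ndarray
    scheme: ClassScheme
    provenance: list[tuple[str, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 2:
            raise ValueError("windows must be 2-D (n_beats, window_length)")
        if self.windows.shape[0] != self.labels.shape[0]:
            raise ValueError("windows row count must equal labels length")
        if not self.provenance:
            self.provenance = [("", -1)] * len(self.labels)
        if len(self.provenance) != len(self.labels):
            raise ValueError("provenance length must equal labels length")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.scheme.n_classes
        ):
            raise LabelError("label index outside [0, n_classes)")
        if not np.isfinite(self.windows).all():
            raise ValueError("windows contain non-finite values")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=self.scheme.n_classes)
        return {c: int(k) for c, k in zip(self.scheme.classes, counts)}

    def subset(self, indices: Sequence[int] | np.ndarray) -> "BeatDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return BeatDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            scheme=self.scheme,
            provenance=[self.provenance[i] for i in idx],
        )


@dataclass
class SplitDataset:
    """A train/test partition of a BeatDataset."""

    train: BeatDataset
    test: BeatDataset
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class EncodedLabels:
    """One-hot label matrix: row i is the unit vector of sample i's class."""

    matrix: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.class_order):
            raise ValueError("matrix must be n × n_classes")
        if not (self.matrix.sum(axis=1) == 1).all():
            raise ValueError("each one-hot row must sum to 1")


def make_dataset(
    windows: np.ndarray,
    labels: np.ndarray,
    scheme: ClassScheme,
    record_id: str = "",
    sample_indices: Sequence[int] | None = None,
    **meta,
) -> BeatDataset:
    """Convenience constructor attaching provenance from one record."""
    if sample_indices is None:
        prov = [(record_id, i) for i in range(len(labels))]
    else:
        prov = [(record_id, int(s)) for s in sample_indices]
    return BeatDataset(windows, labels, scheme, provenance=prov, meta=dict(meta))


__all__ = [
    "EXCLUDE",
    "BeatAnnotation",
    "EcgRecord",
    "ClassScheme",
    "BeatDataset",
    "SplitDataset",
    "EncodedLabels",
    "make_dataset",
    "replace",
]
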