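"""Class balancing, train/test splitting, label encoding and reshaping.

The balancing step resamples every class to one common size: minority
classes are upsampled with replacement, majority classes downsampled
without replacement (the real archive's 2,546-beat ventricular class rises
to 5,000 while the 75,011-beat normal class falls to 5,000).

The pipeline's stated stage order balances *before* splitting, which lets
upsampled duplicates of one original beat land on both sides of the split;
see :func:`ldcnn.evaluation.run_pipeline` for the ``split_before_balance``
escape hatch and ``audit_leakage`` for measuring the effect.  The test set
holds ``ceil(test_fraction × n)`` samples — the rounding that makes a
14,552-beat table split into 11,641 train / 2,911 test at 20%.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split as _sk_split

from .containers import BeatDataset, EncodedLabels, SplitDataset
from .errors import InputShapeError, LabelError, MissingClassError, StratificationError


def balance_classes(
    data: BeatDataset, target_per_class: int, seed: int
) -> BeatDataset:
    """Resample every class to exactly ``target_per_class`` samples.

    Classes already at target are kept unchanged; resampled output is
    shuffled so classes interleave.  Deterministic given ``seed``.
    """
    if target_per_class < 1:
        raise MissingClassError("target_per_class must be at least 1")
    counts = data.class_counts()
    absent = [c for c, k in counts.items() if k == 0]
    if absent:
        raise MissingClassError(f"class(es) {absent} have no samples")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for ci in range(data.scheme.n_classes):
        idx = np.flatnonzero(data.labels == ci)
        if len(idx) == target_per_class:
            pick = idx
        elif len(idx) > target_per_class:
            pick = rng.choice(idx, size=target_per_class, replace=False)
        else:
            pick = rng.choice(idx, size=target_per_class, replace=True)
        chosen.append(pick)
    order = np.concatenate(chosen)
    order = order[rng.permutation(len(order))]
    out = data.subset(order)
    out.meta = {
        "before": counts,
        "after": out.class_counts(),
        "target_per_class": target_per_class,
        "seed": seed,
    }
    return out


def split_train_test(
    data: BeatDataset,
    test_fraction: float,
    seed: int,
    stratify: bool = True,
) -> SplitDataset:
    """Hold-out split with ``|test| = ceil(test_fraction × n)``.

    With ``stratify`` on, per-class test counts are within one sample of
    the requested fraction.  Split is by row; duplicated rows created by
    upsampling share a provenance key (see :func:`audit_leakage`).
    """
    n = len(data)
    if n < 2:
        raise StratificationError("need at least 2 samples to split")
    if not 0 < test_fraction < 1:
        raise StratificationError("test_fraction must lie in (0, 1)")
    strat = data.labels if stratify else None
    try:
        train_idx, test_idx = _sk_split(
            np.arange(n),
            test_size=test_fraction,
            random_state=seed,
            stratify=strat,
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    return SplitDataset(
        train=data.subset(train_idx),
        test=data.subset(test_idx),
        test_fraction=test_fraction,
        seed=seed,
    )


def audit_leakage(split: SplitDataset) -> int:
    """Count test rows whose provenance key also occurs in the training set."""
    train_keys = set(split.train.provenance)
    return sum(1 for key in split.test.provenance if key in train_keys)


def one_hot_encode(
    labels: np.ndarray, class_order: tuple[str, ...]
) -> EncodedLabels:
    """Encode integer class indices as unit indicator rows.

    ``class_order`` fixes the column order; column j is 1 exactly for rows
    whose label index is j.
    """
    y = np.asarray(labels, dtype=np.int64)
    k = len(class_order)
    if len(y) and (y.min() < 0 or y.max() >= k):
        raise LabelError(
            f"label index out of range for {k} classes: "
            f"[{y.min()}, {y.max()}]"
        )
    matrix = np.zeros((len(y), k), dtype=np.int64)
    matrix[np.arange(len(y)), y] = 1
    return EncodedLabels(matrix=matrix, class_order=tuple(class_order))


def binary_column(labels: np.ndarray) -> np.ndarray:
    """(n, 1) float 0/1 column for a two-class sigmoid head."""
    y = np.asarray(labels, dtype=np.int64)
    if len(y) and (y.min() < 0 or y.max() > 1):
        raise LabelError("binary_column requires labels in {0, 1}")
    return y.astype(np.float64)[:, None]


def reshape_for_network(windows: np.ndarray) -> np.ndarray:
    """Append the trailing channel axis of size one: (n, L) → (n, L, 1).

    Values are untouched; :func:`flatten_windows` is the exact inverse.
    """
    w = np.asarray(windows)
    if w.ndim != 2:
        raise InputShapeError(f"expected a 2-D window matrix, got ndim={w.ndim}")
    return w[:, :, None]


def flatten_windows(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_for_network`."""
    a = np.asarray(arr)
    if a.ndim != 3 or a.shape[2] != 1:
        raise InputShapeError(f"expected (n, L, 1), got {a.shape}")
    return a[:, :, 0]
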