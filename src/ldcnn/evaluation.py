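"""Confusion matrices, classification metrics, the end-to-end pipeline, and
classical-ML baselines.

Per-class metrics come from one-vs-rest marginalization of the multi-class
confusion matrix: for class c, TP = counts[c,c], FP = column − TP,
FN = row − TP, TN = the rest.  With those counts,

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

all reported as percentages.  One-vs-rest is the only reading under which a
"per-class accuracy" differs from recall, which is how the published
per-class tables are structured.  Aggregate accuracy is the overall correct
fraction; other aggregates are macro (unweighted class means) by default,
configurable to micro.  Zero-denominator cells are reported as 0 and
flagged rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import dataset as dsops
from . import network as net
from .arch import ArchitectureSpec, builtin_architecture
from .containers import BeatDataset, ClassScheme, EcgRecord, SplitDataset
from .errors import LabelError, ParameterError
from .preprocess import PreprocessConfig, segment_beats


@dataclass
class ConfusionMatrix:
    """Row = true class, column = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ParameterError("counts must be n_classes × n_classes")
        if (self.counts < 0).any():
            raise ParameterError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against all others."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum()) - tp
        fn = int(c[class_index, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Per-class and aggregate accuracy/precision/recall/F1, in percent."""

    per_class: dict[str, dict[str, float]]
    aggregate: dict[str, float]
    zero_division_flags: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        head = "| Class | Accuracy (%) | Precision (%) | Recall (%) | F1 (%) |"
        sep = "|---|---|---|---|---|"
        rows = [head, sep]
        for cls, m in self.per_class.items():
            rows.append(
                f"| {cls} | {m['accuracy']:.2f} | {m['precision']:.2f} "
                f"| {m['recall']:.2f} | {m['f1']:.2f} |"
            )
        a = self.aggregate
        rows.append(
            f"| **overall** | {a['accuracy']:.2f} | {a['precision']:.2f} "
            f"| {a['recall']:.2f} | {a['f1']:.2f} |"
        )
        return "\n".join(rows)


def confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    class_order: tuple[str, ...],
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a matrix over ``class_order``."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ParameterError("true and predicted labels must be equal-length 1-D")
    if t.size == 0:
        raise ParameterError("cannot build a confusion matrix from no samples")
    k = len(class_order)
    if (t.min() < 0 or t.max() >= k) or (p.min() < 0 or p.max() >= k):
        raise LabelError(f"labels outside [0, {k})")
    counts = _sk_confusion(t, p, labels=np.arange(k))
    return ConfusionMatrix(counts=counts, class_order=class_order)


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def metrics_from_confusion(
    cm: ConfusionMatrix, average: str = "macro"
) -> MetricsReport:
    """Accuracy/precision/recall/F1 per class (one-vs-rest) and aggregated."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    if average not in ("macro", "micro"):
        raise ParameterError("average must be 'macro' or 'micro'")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.class_order):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        precision = _safe_div(tp, tp + fp, flags, f"{cls}:precision")
        recall = _safe_div(tp, tp + fn, flags, f"{cls}:recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, flags, f"{cls}:f1")
        per_class[cls] = {
            "accuracy": 100.0 * (tp + tn) / cm.total,
            "precision": 100.0 * precision,
            "recall": 100.0 * recall,
            "f1": 100.0 * f1,
        }
    overall_acc = 100.0 * np.trace(cm.counts) / cm.total
    if average == "macro":
        agg = {
            m: float(np.mean([per_class[c][m] for c in cm.class_order]))
            for m in ("precision", "recall", "f1")
        }
    else:
        tps = sum(cm.one_vs_rest(i)[0] for i in range(len(cm.class_order)))
        fps = sum(cm.one_vs_rest(i)[1] for i in range(len(cm.class_order)))
        fns = sum(cm.one_vs_rest(i)[2] for i in range(len(cm.class_order)))
        precision = 100.0 * _safe_div(tps, tps + fps, flags, "micro:precision")
        recall = 100.0 * _safe_div(tps, tps + fns, flags, "micro:recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, flags, "micro:f1")
        agg = {"precision": precision, "recall": recall, "f1": f1}
    agg["accuracy"] = float(overall_acc)
    return MetricsReport(per_class=per_class, aggregate=agg, zero_division_flags=flags)


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One bundle of settings for the full read→train→evaluate pipeline.

    ``source`` is either an annotated :class:`EcgRecord` (raw mode — it will
    be denoised/normalized/segmented per ``preprocess``) or an already
    segmented :class:`BeatDataset`.  ``balance_target`` of None skips
    resampling.  The published stage order balances before splitting;
    ``split_before_balance=True`` gives the leakage-free variant (test set
    is held out first and never resampled).
    """

    scheme: ClassScheme
    architecture: str | ArchitectureSpec = "mitbih5"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    balance_target: int | None = 5000
    test_fraction: float = 0.2
    split_before_balance: bool = False
    stratify: bool = True
    seed: int = 0
    train: net.TrainConfig = field(default_factory=net.TrainConfig)


@dataclass
class PipelineResult:
    metrics: MetricsReport
    history: net.TrainHistory
    confusion: ConfusionMatrix
    manifest: dict
    model: net.Model
    split: SplitDataset


def _encode(labels: np.ndarray, scheme: ClassScheme, n_outputs: int) -> np.ndarray:
    if n_outputs == 1:
        return dsops.binary_column(labels)
    return dsops.one_hot_encode(labels, scheme.classes).matrix.astype(np.float64)


def run_pipeline(config: PipelineConfig, source: EcgRecord | BeatDataset) -> PipelineResult:
    """Execute segment → balance → split → encode → train → predict → metrics.

    Every stage's counts land in the manifest; the whole run is reproducible
    from ``config.seed`` and ``config.train.seed``.
    """
    manifest: dict = {"seed": config.seed}
    if isinstance(source, EcgRecord):
        data = segment_beats(source, config.scheme, config.preprocess)
        manifest["segmentation"] = dict(data.meta)
    else:
        data = source
        manifest["segmentation"] = {"segmented": len(data), "pre_segmented": True}
    manifest["class_counts_input"] = data.class_counts()

    if config.split_before_balance and config.balance_target is not None:
        split = dsops.split_train_test(
            data, config.test_fraction, config.seed, config.stratify
        )
        train_part = dsops.balance_classes(
            split.train, config.balance_target, config.seed
        )
        manifest["balance"] = train_part.meta
        split = SplitDataset(
            train=train_part,
            test=split.test,
            test_fraction=config.test_fraction,
            seed=config.seed,
        )
    else:
        if config.balance_target is not None:
            data = dsops.balance_classes(data, config.balance_target, config.seed)
            manifest["balance"] = data.meta
        split = dsops.split_train_test(
            data, config.test_fraction, config.seed, config.stratify
        )
    manifest["split"] = {
        "total": len(split.train) + len(split.test),
        "train": len(split.train),
        "test": len(split.test),
        "test_fraction": config.test_fraction,
        "duplicate_provenance_in_test": dsops.audit_leakage(split),
    }

    spec = (
        builtin_architecture(config.architecture)
        if isinstance(config.architecture, str)
        else config.architecture
    )
    model = net.build_network(spec, seed=config.seed)
    x_train = dsops.reshape_for_network(split.train.windows)
    x_test = dsops.reshape_for_network(split.test.windows)
    y_train = _encode(split.train.labels, config.scheme, spec.n_outputs)
    y_test = _encode(split.test.labels, config.scheme, spec.n_outputs)
    history = net.train(model, (x_train, y_train), (x_test, y_test), config.train)
    manifest["training"] = {
        "epochs_run": history.epochs_run,
        "parameters": model.parameter_count(),
    }
    _, predicted = net.predict(model, x_test)
    cm = confusion(split.test.labels, predicted, config.scheme.classes)
    report = metrics_from_confusion(cm)
    return PipelineResult(
        metrics=report, history=history, confusion=cm,
        manifest=manifest, model=model, split=split,
    )


# --------------------------------------------------------------------------
# classical baselines
# --------------------------------------------------------------------------

BASELINE_NAMES = (
    "naive-bayes",
    "logistic-regression",
    "decision-tree",
    "linear-svm",
    "svm",
    "knn",
    "random-forest",
)


def _make_baseline(name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC, LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    if name == "naive-bayes":
        return GaussianNB()
    if name == "logistic-regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "linear-svm":
        return LinearSVC(random_state=seed)
    if name == "svm":
        return SVC(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "random-forest":
        return RandomForestClassifier(random_state=seed)
    raise ParameterError(f"unknown baseline classifier {name!r}")


def run_baselines(
    split: SplitDataset,
    classifier_set: Sequence[str] = BASELINE_NAMES,
    seed: int = 0,
) -> list[tuple[str, MetricsReport]]:
    """Train/evaluate classical classifiers on the flattened windows.

    Returns (name, report) pairs sorted ascending by aggregate accuracy —
    the layout of the published comparison tables.  Training data with a
    single class raises :class:`MissingClassError`.
    """
    from .errors import MissingClassError

    if len(np.unique(split.train.labels)) < 2:
        raise MissingClassError("baselines need at least two classes in training data")
    scheme = split.train.scheme
    results = []
    for name in classifier_set:
        clf = _make_baseline(name, seed)
        clf.fit(split.train.windows, split.train.labels)
        pred = clf.predict(split.test.windows)
        cm = confusion(split.test.labels, pred, scheme.classes)
        results.append((name, metrics_from_confusion(cm)))
    results.sort(key=lambda item: item[1].aggregate["accuracy"])
    return results
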