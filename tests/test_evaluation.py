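"""Confusion matrices, one-vs-rest metrics, pipeline, baselines."""

import numpy as np
import pytest

from ldcnn import (
    MITBIH5,
    PTB2,
    ConfusionMatrix,
    PipelineConfig,
    PreprocessConfig,
    SyntheticConfig,
    TrainConfig,
    confusion,
    default_templates,
    generate_segment_table,
    metrics_from_confusion,
    run_baselines,
    run_pipeline,
    split_train_test,
)
from ldcnn.errors import MissingClassError, ParameterError


def brute_force_metrics(true, pred, n_classes):
    """Independent recount of Eq-style metrics straight from label pairs."""
    out = {}
    true, pred = np.asarray(true), np.asarray(pred)
    total = len(true)
    for c in range(n_classes):
        tp = int(np.sum((true == c) & (pred == c)))
        fp = int(np.sum((true != c) & (pred == c)))
        fn = int(np.sum((true == c) & (pred != c)))
        tn = total - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out[c] = {
            "accuracy": 100.0 * (tp + tn) / total,
            "precision": 100.0 * precision,
            "recall": 100.0 * recall,
            "f1": 100.0 * f1,
        }
    return out


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 1, 2, 2], [0, 1, 2, 2], ("a", "b", "c"))
        np.testing.assert_array_equal(cm.counts, np.diag([1, 1, 2]))

    def test_hand_enumerated_two_class_case(self):
        cm = confusion([1, 0, 1, 1], [1, 0, 0, 1], PTB2.classes)
        np.testing.assert_array_equal(cm.counts, [[1, 0], [1, 2]])

    def test_empty_input_is_error(self):
        with pytest.raises(ParameterError):
            confusion([], [], PTB2.classes)

    def test_one_vs_rest_marginals_sum_to_total(self, rng):
        t = rng.integers(0, 5, 200)
        p = rng.integers(0, 5, 200)
        cm = confusion(t, p, MITBIH5.classes)
        for i in range(5):
            assert sum(cm.one_vs_rest(i)) == 200


class TestMetrics:
    def test_perfect_two_sample_case(self):
        cm = ConfusionMatrix(np.array([[1, 0], [0, 1]]), PTB2.classes)
        report = metrics_from_confusion(cm)
        for m in report.per_class.values():
            assert m == {"accuracy": 100.0, "precision": 100.0,
                         "recall": 100.0, "f1": 100.0}

    def test_ninety_percent_everywhere_case(self):
        # TP=9, FP=1, FN=1, TN=9 in a binary matrix
        cm = ConfusionMatrix(np.array([[9, 1], [1, 9]]), PTB2.classes)
        report = metrics_from_confusion(cm)
        m = report.per_class["Normal"]
        assert m["precision"] == m["recall"] == m["f1"] == m["accuracy"] == 90.0
        assert report.aggregate["accuracy"] == 90.0

    def test_agrees_with_brute_force_recount(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            t = rng.integers(0, 3, n)
            p = rng.integers(0, 3, n)
            cm = confusion(t, p, ("x", "y", "z"))
            report = metrics_from_confusion(cm)
            want = brute_force_metrics(t, p, 3)
            for i, cls in enumerate(("x", "y", "z")):
                for key, val in want[i].items():
                    assert report.per_class[cls][key] == pytest.approx(val, abs=1e-9)

    def test_macro_f1_bounded_by_per_class_f1(self, rng):
        for _ in range(20):
            t = rng.integers(0, 4, 100)
            p = rng.integers(0, 4, 100)
            report = metrics_from_confusion(confusion(t, p, ("a", "b", "c", "d")))
            f1s = [m["f1"] for m in report.per_class.values()]
            assert min(f1s) - 1e-9 <= report.aggregate["f1"] <= max(f1s) + 1e-9

    def test_zero_denominator_reported_as_zero_with_flag(self):
        # class b never predicted and never true → precision/recall undefined
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]), ("a", "b"))
        report = metrics_from_confusion(cm)
        assert report.per_class["b"]["precision"] == 0.0
        assert any(flag.startswith("b:") for flag in report.zero_division_flags)

    def test_f1_consistent_with_own_precision_recall(self, rng):
        t = rng.integers(0, 5, 300)
        p = np.where(rng.random(300) < 0.8, t, rng.integers(0, 5, 300))
        report = metrics_from_confusion(confusion(t, p, MITBIH5.classes))
        for m in report.per_class.values():
            if m["precision"] + m["recall"] > 0:
                want = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
                assert m["f1"] == pytest.approx(want, abs=0.01)


@pytest.fixture(scope="module")
def mit_split(templates5):
    cfg = SyntheticConfig(
        n_beats=400,
        class_proportions={c: 0.2 for c in MITBIH5.classes},
        noise_sd=0.02,
        baseline_wander_amplitude=0.0,
        powerline_amplitude=0.0,
        seed=17,
    )
    table = generate_segment_table(cfg, templates5, 360, MITBIH5)
    return split_train_test(table, 0.25, seed=0)


class TestBaselines:
    def test_separable_data_every_baseline_strong(self, mit_split):
        names = ("naive-bayes", "decision-tree", "knn", "logistic-regression")
        results = run_baselines(mit_split, names, seed=0)
        for name, report in results:
            assert report.aggregate["accuracy"] >= 95.0, name

    def test_output_ranked_ascending_by_accuracy(self, mit_split):
        results = run_baselines(mit_split, ("naive-bayes", "knn"), seed=0)
        accs = [r.aggregate["accuracy"] for _, r in results]
        assert accs == sorted(accs)

    def test_single_class_training_data_rejected(self, mit_split):
        degenerate = mit_split.train.subset(
            np.flatnonzero(mit_split.train.labels == 0)
        )
        from ldcnn.containers import SplitDataset

        broken = SplitDataset(degenerate, mit_split.test, 0.25, 0)
        with pytest.raises(MissingClassError):
            run_baselines(broken, ("knn",))


class TestPipeline:
    @pytest.fixture(scope="class")
    def result(self, clean_record):
        config = PipelineConfig(
            scheme=MITBIH5,
            architecture="mitbih5",
            preprocess=PreprocessConfig(denoise=False),
            balance_target=40,
            test_fraction=0.2,
            seed=0,
            train=TrainConfig(epochs=4, batch_size=16, seed=0,
                              stop_at_accuracy=0.995),
        )
        return config, run_pipeline(config, clean_record)

    def test_zero_noise_pipeline_reaches_high_accuracy(self, result):
        _, res = result
        assert res.metrics.aggregate["accuracy"] >= 99.0

    def test_manifest_counts_are_conserved(self, result):
        _, res = result
        m = res.manifest
        assert sum(m["balance"]["after"].values()) == 200  # 5 classes × 40
        assert m["split"]["train"] + m["split"]["test"] == m["split"]["total"]
        assert m["split"]["test"] == 40  # ceil(0.2 × 200)

    def test_pipeline_deterministic(self, clean_record, result):
        config, res = result
        res2 = run_pipeline(config, clean_record)
        assert res2.metrics.aggregate == res.metrics.aggregate
        np.testing.assert_array_equal(res2.confusion.counts, res.confusion.counts)

    def test_split_before_balance_has_no_test_leakage(self, clean_record):
        config = PipelineConfig(
            scheme=MITBIH5,
            preprocess=PreprocessConfig(denoise=False),
            balance_target=40,
            split_before_balance=True,
            seed=1,
            train=TrainConfig(epochs=1, batch_size=16, seed=1),
        )
        res = run_pipeline(config, clean_record)
        assert res.manifest["split"]["duplicate_provenance_in_test"] == 0
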