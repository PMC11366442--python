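"""Balancing, splitting, encoding, reshaping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldcnn import (
    MITBIH5,
    PTB2,
    BeatDataset,
    audit_leakage,
    balance_classes,
    binary_column,
    flatten_windows,
    one_hot_encode,
    reshape_for_network,
    split_train_test,
)
from ldcnn.errors import (
    InputShapeError,
    LabelError,
    MissingClassError,
    StratificationError,
)


def labels_only_dataset(counts, scheme=MITBIH5, width=4):
    """Tiny-window dataset with the given per-class sizes (order = scheme)."""
    labels = np.concatenate(
        [np.full(k, i, dtype=np.int64) for i, k in enumerate(counts)]
    )
    rng = np.random.default_rng(0)
    windows = rng.normal(size=(len(labels), width))
    prov = [("fixture", i) for i in range(len(labels))]
    return BeatDataset(windows, labels, scheme, provenance=prov)


class TestBalance:
    def test_up_and_down_sampling_to_target(self):
        data = labels_only_dataset([60, 10, 25, 25, 5])
        out = balance_classes(data, 25, seed=3)
        assert out.class_counts() == {c: 25 for c in MITBIH5.classes}
        assert len(out) == 125

    def test_downsampled_rows_are_unique(self):
        data = labels_only_dataset([60, 30, 30, 30, 30])
        out = balance_classes(data, 25, seed=3)
        keys = [p for p, l in zip(out.provenance, out.labels) if l == 0]
        assert len(keys) == len(set(keys)) == 25

    def test_class_at_target_kept_identically(self):
        data = labels_only_dataset([25, 30, 30, 30, 30])
        out = balance_classes(data, 25, seed=3)
        kept = {p for p, l in zip(out.provenance, out.labels) if l == 0}
        original = {p for p, l in zip(data.provenance, data.labels) if l == 0}
        assert kept == original

    def test_deterministic_given_seed(self):
        data = labels_only_dataset([60, 10, 25, 25, 5])
        a = balance_classes(data, 25, seed=9)
        b = balance_classes(data, 25, seed=9)
        assert np.array_equal(a.windows, b.windows)
        assert a.provenance == b.provenance

    def test_absent_class_is_error(self):
        data = labels_only_dataset([10, 10, 10, 10, 0])
        with pytest.raises(MissingClassError, match="V"):
            balance_classes(data, 5, seed=0)


class TestSplit:
    def test_minimal_half_split(self):
        data = labels_only_dataset([1, 1], scheme=PTB2)
        split = split_train_test(data, 0.5, seed=0, stratify=False)
        assert len(split.train) == 1 and len(split.test) == 1

    def test_ceil_rounding_of_test_size(self):
        data = labels_only_dataset([7, 6], scheme=PTB2)
        split = split_train_test(data, 0.2, seed=0, stratify=False)
        assert len(split.test) == 3  # ceil(0.2 × 13)
        assert len(split.train) == 10

    def test_stratified_proportions_within_one_sample(self):
        data = labels_only_dataset([50, 20, 20, 20, 10])
        split = split_train_test(data, 0.2, seed=1, stratify=True)
        test_counts = split.test.class_counts()
        for cls, total in data.class_counts().items():
            assert abs(test_counts[cls] - 0.2 * total) <= 1

    def test_disjoint_by_row_and_deterministic(self):
        data = labels_only_dataset([40, 20, 20, 20, 20])
        a = split_train_test(data, 0.25, seed=5)
        b = split_train_test(data, 0.25, seed=5)
        assert set(a.train.provenance).isdisjoint(a.test.provenance)
        assert audit_leakage(a) == 0
        assert a.test.provenance == b.test.provenance

    def test_upsampled_duplicates_can_cross_split(self):
        data = labels_only_dataset([40, 3, 20, 20, 20])
        balanced = balance_classes(data, 20, seed=0)
        split = split_train_test(balanced, 0.2, seed=0)
        assert audit_leakage(split) > 0  # the published stage order leaks

    def test_singleton_class_fails_stratification(self):
        data = labels_only_dataset([10, 10, 10, 10, 1])
        with pytest.raises(StratificationError):
            split_train_test(data, 0.2, seed=0, stratify=True)


class TestEncoding:
    def test_identity_for_full_vocabulary(self):
        enc = one_hot_encode(np.arange(5), MITBIH5.classes)
        np.testing.assert_array_equal(enc.matrix, np.eye(5, dtype=int))

    def test_rows_are_unit_vectors_of_their_class(self, rng):
        labels = rng.integers(0, 5, size=100)
        enc = one_hot_encode(labels, MITBIH5.classes)
        assert (enc.matrix.sum(axis=1) == 1).all()
        np.testing.assert_array_equal(enc.matrix.argmax(axis=1), labels)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=200))
    def test_encoding_is_a_bijection(self, labels):
        """Unit rows decode back to exactly the labels that produced them."""
        enc = one_hot_encode(np.array(labels), MITBIH5.classes)
        assert (enc.matrix.sum(axis=1) == 1).all()
        np.testing.assert_array_equal(enc.matrix.argmax(axis=1), labels)
        for j in range(5):
            np.testing.assert_array_equal(
                enc.matrix[:, j] == 1, np.array(labels) == j
            )

    def test_out_of_range_label_rejected(self):
        with pytest.raises(LabelError):
            one_hot_encode(np.array([0, 5]), MITBIH5.classes)

    def test_binary_column_for_sigmoid_head(self):
        col = binary_column(np.array([0, 1, 1, 0]))
        assert col.shape == (4, 1)
        np.testing.assert_array_equal(col[:, 0], [0, 1, 1, 0])
        with pytest.raises(LabelError):
            binary_column(np.array([0, 2]))


class TestReshape:
    def test_round_trip_preserves_values(self, rng):
        w = rng.normal(size=(10, 360))
        arr = reshape_for_network(w)
        assert arr.shape == (10, 360, 1)
        assert np.shares_memory(arr, w) or np.array_equal(arr[:, :, 0], w)
        np.testing.assert_array_equal(flatten_windows(arr), w)

    def test_single_row(self, rng):
        assert reshape_for_network(rng.normal(size=(1, 187))).shape == (1, 187, 1)

    def test_ragged_input_rejected(self):
        with pytest.raises((InputShapeError, ValueError)):
            reshape_for_network([[1.0, 2.0], [1.0]])
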