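"""Confusion-matrix metrics, reported-table arithmetic, relabel protocol."""

import numpy as np
import pytest

from ecgbeats.evaluation import (
    BUNDLE_BRANCH_NORMAL_RECORDS,
    ConfusionMatrix,
    binary_metrics,
    confusion,
    misclassification_error,
    overall_accuracy,
    patient_specific_relabel,
    round_half_up,
)
from ecgbeats.io import CLASS_ORDER, ClassLabel
from ecgbeats.published_matrices import (
    BASIC_5CLASS,
    COMPARISON_CNN,
    COMPARISON_DAE,
    COMPARISON_EXPANDED,
    EXPANDED_5CLASS,
    THREE_CLASS_ORDER,
)

N, L, R, A, V = CLASS_ORDER


class TestConfusion:
    def test_identical_sequences_are_diagonal(self):
        labels = [N, L, R, A, V, N, V]
        m = confusion(labels, labels, CLASS_ORDER)
        assert np.array_equal(m.counts, np.diag([2, 1, 1, 1, 2]))

    def test_hand_placed_counts(self):
        m = confusion([N, V, A], [N, A, A], CLASS_ORDER)
        expected = np.zeros((5, 5), int)
        expected[0, 0] = 1  # N -> N
        expected[4, 3] = 1  # V -> A
        expected[3, 3] = 1  # A -> A
        assert np.array_equal(m.counts, expected)

    def test_random_sequences_match_brute_force(self):
        rng = np.random.default_rng(0)
        truth = [CLASS_ORDER[i] for i in rng.integers(0, 5, 1000)]
        pred = [CLASS_ORDER[i] for i in rng.integers(0, 5, 1000)]
        m = confusion(truth, pred, CLASS_ORDER)
        for i, ci in enumerate(CLASS_ORDER):
            for j, cj in enumerate(CLASS_ORDER):
                tally = sum(1 for t, p in zip(truth, pred) if t is ci and p is cj)
                assert m.counts[i, j] == tally

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([N], ["bogus"], CLASS_ORDER)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([N, N], [N], CLASS_ORDER)


class TestReportedTables:
    """The printed result tables must be reproduced from their raw counts."""

    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (BASIC_5CLASS, [1.87, 3.05, 3.45, 13.99, 5.5]),
            (EXPANDED_5CLASS, [2.68, 4.93, 3.61, 7.21, 7.21]),
        ],
    )
    def test_five_class_misclassification_rows(self, matrix, expected):
        got = [
            round_half_up(misclassification_error(matrix, c))
            for c in matrix.class_order
        ]
        assert got == expected

    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (COMPARISON_CNN, [1.43, 36.36, 9.38]),
            (COMPARISON_DAE, [6.18, 52.61, 32.98]),
            (COMPARISON_EXPANDED, [1.66, 6.32, 6.61]),
        ],
    )
    def test_three_class_misclassification_rows(self, matrix, expected):
        got = [
            round_half_up(misclassification_error(matrix, c))
            for c in THREE_CLASS_ORDER
        ]
        assert got == expected

    def test_expanded_overall_accuracy_and_error(self):
        acc = overall_accuracy(EXPANDED_5CLASS)
        assert round_half_up(acc) == 95.94
        assert round_half_up(100.0 - acc) == 4.06
        assert int(np.trace(EXPANDED_5CLASS.counts)) == 9786
        assert EXPANDED_5CLASS.total == 10200

    def test_basic_overall_accuracy_by_hand_summation(self):
        counts = BASIC_5CLASS.counts
        trace = sum(int(counts[i, i]) for i in range(5))
        total = int(counts.sum())
        assert overall_accuracy(BASIC_5CLASS) == pytest.approx(100 * trace / total)


class TestMisclassificationError:
    def test_diagonal_matrix_is_zero(self):
        m = ConfusionMatrix(CLASS_ORDER, np.diag([5, 4, 3, 2, 1]))
        assert all(misclassification_error(m, c) == 0.0 for c in CLASS_ORDER)

    def test_zero_column_is_not_applicable(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 10
        m = ConfusionMatrix(CLASS_ORDER, counts)
        assert misclassification_error(m, V) is None

    def test_complement_of_ppv(self):
        # column error + column PPV = 100 for every predicted class
        for m in (BASIC_5CLASS, EXPANDED_5CLASS):
            for j, c in enumerate(m.class_order):
                col = m.counts[:, j].sum()
                ppv = 100.0 * m.counts[j, j] / col
                assert misclassification_error(m, c) + ppv == pytest.approx(100.0)


class TestOverallAccuracy:
    def test_diagonal_is_perfect(self):
        m = ConfusionMatrix(CLASS_ORDER, np.diag([1, 2, 3, 4, 5]))
        assert overall_accuracy(m) == 100.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, (5, 5))
        m = ConfusionMatrix(CLASS_ORDER, counts)
        perm = rng.permutation(5)
        m2 = ConfusionMatrix(
            tuple(CLASS_ORDER[i] for i in perm), counts[np.ix_(perm, perm)]
        )
        assert overall_accuracy(m) == pytest.approx(overall_accuracy(m2))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(ConfusionMatrix(CLASS_ORDER, np.zeros((5, 5), int)))


class TestBinaryMetrics:
    def test_direct_formula_evaluation(self):
        # TP=9, FN=1, FP=2, TN=88
        m = ConfusionMatrix(
            ("abnormal", "normal"), np.array([[9, 1], [2, 88]])
        )
        report = binary_metrics(m, {"abnormal"})
        assert report.sensitivity == pytest.approx(90.0)
        assert round_half_up(report.specificity) == 97.78
        assert round_half_up(report.ppv) == 81.82
        assert report.accuracy == pytest.approx(97.0)

    def test_perfect_classifier(self):
        m = ConfusionMatrix(("abnormal", "normal"), np.array([[10, 0], [0, 30]]))
        r = binary_metrics(m, {"abnormal"})
        assert (r.accuracy, r.sensitivity, r.specificity, r.ppv) == (100.0,) * 4

    def test_all_negative_predictions(self):
        m = ConfusionMatrix(("abnormal", "normal"), np.array([[0, 5], [0, 20]]))
        r = binary_metrics(m, {"abnormal"})
        assert r.sensitivity == 0.0
        assert r.ppv is None  # nothing predicted positive

    def test_multiclass_collapse_matches_label_reconstruction(self):
        rng = np.random.default_rng(3)
        truth = [CLASS_ORDER[i] for i in rng.integers(0, 5, 500)]
        pred = [CLASS_ORDER[i] for i in rng.integers(0, 5, 500)]
        m = confusion(truth, pred, CLASS_ORDER)
        positives = {A, V}
        direct = binary_metrics(m, positives)
        collapse = lambda c: "abnormal" if c in positives else "normal"
        m2 = confusion(
            [collapse(t) for t in truth],
            [collapse(p) for p in pred],
            ("abnormal", "normal"),
        )
        via_labels = binary_metrics(m2, {"abnormal"})
        assert direct == via_labels

    def test_se_plus_fnr_is_100(self):
        m = ConfusionMatrix(("abnormal", "normal"), np.array([[37, 13], [5, 45]]))
        r = binary_metrics(m, {"abnormal"})
        fnr = 100.0 * 13 / 50
        assert r.sensitivity + fnr == pytest.approx(100.0)

    def test_positive_set_must_be_proper_subset(self):
        m = ConfusionMatrix(("abnormal", "normal"), np.eye(2, dtype=int))
        with pytest.raises(ValueError):
            binary_metrics(m, {"abnormal", "normal"})
        with pytest.raises(ValueError):
            binary_metrics(m, set())


class TestPatientSpecificRelabel:
    @pytest.mark.parametrize("record", sorted(BUNDLE_BRANCH_NORMAL_RECORDS))
    @pytest.mark.parametrize("label", [L, R])
    def test_bundle_branch_records_count_as_normal(self, record, label):
        assert patient_specific_relabel(record, label) == "normal"

    def test_bundle_branch_elsewhere_is_abnormal(self):
        assert patient_specific_relabel("100", L) == "abnormal"
        assert patient_specific_relabel("100", R) == "abnormal"

    @pytest.mark.parametrize("record", ["100", "109", "232"])
    def test_ectopic_beats_always_abnormal(self, record):
        assert patient_specific_relabel(record, A) == "abnormal"
        assert patient_specific_relabel(record, V) == "abnormal"

    @pytest.mark.parametrize("record", ["100", "109"])
    def test_nsr_always_normal(self, record):
        assert patient_specific_relabel(record, N) == "normal"


class TestCsvRoundTrip:
    def test_matrix_csv_roundtrip(self, tmp_path):
        path = tmp_path / "m.csv"
        BASIC_5CLASS.to_csv(path)
        back = ConfusionMatrix.from_csv(path)
        assert back.class_order == BASIC_5CLASS.class_order
        assert np.array_equal(back.counts, BASIC_5CLASS.counts)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(13.985, 13.99), (1.865, 1.87), (5.497, 5.5), (7.205, 7.21)]
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected
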