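"""Evaluation metrics against hand-worked examples and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from talsrx import metrics
from talsrx.metrics import (
    band_histogram,
    cohen_kappa,
    confusion,
    error_vector,
    evaluate_predictions,
    kappa_band,
    overall_accuracy,
    ovr_macro_auc,
    per_class_kappa,
    prf_macro,
)

# the worked binary confusion matrix used throughout: [[4, 1], [2, 3]]
CM2 = np.array([[4, 1], [2, 3]])


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 3, 7, 10])
        cm = confusion(y, y)
        assert cm.sum() == 4
        assert np.array_equal(np.diag(cm), np.bincount(y, minlength=11))

    def test_direct_counts(self):
        cm = confusion([0, 0, 1], [0, 1, 1], n_classes=2)
        assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[1, 1] == 1
        assert cm.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestPrfMacro:
    def test_diagonal_gives_all_ones(self):
        cm = np.diag([3, 0, 5, 2] + [0] * 7)
        macro = prf_macro(cm)["macro"]
        assert all(v == 1.0 for v in macro.values())

    def test_hand_worked_binary_example(self):
        res = prf_macro(CM2)
        pc = res["per_class"]
        assert pc["precision"][0] == pytest.approx(4 / 6)
        assert pc["recall"][0] == pytest.approx(4 / 5)
        f1 = 2 * (4 / 6 * 4 / 5) / (4 / 6 + 4 / 5)
        assert pc["f1"][0] == pytest.approx(f1)
        assert pc["f1"][0] == pytest.approx(0.7273, abs=1e-4)
        # the TP / (TP + FP + FN) ratio as printed
        assert pc["tp_over_tp_fp_fn"][0] == pytest.approx(4 / 7)

    def test_jaccard_ratio_bounded_by_precision_and_recall(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 4, 60)
            y_pred = rng.integers(0, 4, 60)
            res = prf_macro(confusion(y_true, y_pred, n_classes=4))
            pc = res["per_class"]
            assert (
                pc["tp_over_tp_fp_fn"]
                <= np.minimum(pc["precision"], pc["recall"]) + 1e-12
            ).all()

    def test_macro_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 100)
        y_pred = rng.integers(0, 5, 100)
        m1 = prf_macro(confusion(y_true, y_pred, n_classes=5))["macro"]
        perm = np.array([3, 0, 4, 1, 2])
        m2 = prf_macro(confusion(perm[y_true], perm[y_pred], n_classes=5))["macro"]
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prf_macro(np.zeros((11, 11), dtype=int))


class TestAccuracy:
    def test_values(self):
        assert overall_accuracy([1, 2, 3], [1, 2, 3]) == 1.0
        assert overall_accuracy([1, 2, 3, 4], [1, 2, 3, 0]) == 0.75

    def test_equals_trace_over_total(self, rng):
        y_true = rng.integers(0, 11, 80)
        y_pred = rng.integers(0, 11, 80)
        cm = confusion(y_true, y_pred)
        assert overall_accuracy(y_true, y_pred) == pytest.approx(
            np.trace(cm) / cm.sum()
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy([], [])


class TestKappa:
    def test_diagonal_is_one(self):
        assert cohen_kappa(np.diag([5, 3, 2])) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # p_o = 0.7, p_e = (5*6 + 5*4) / 100 = 0.5, kappa = 0.4
        assert cohen_kappa(CM2) == pytest.approx(0.4)

    def test_zero_when_observed_equals_expected(self):
        # independent margins: p_o = p_e exactly
        cm = np.array([[1, 1], [1, 1]])
        assert cohen_kappa(cm) == pytest.approx(0.0)

    def test_matches_sklearn(self, rng):
        y_true = rng.integers(0, 6, 200)
        y_pred = rng.integers(0, 6, 200)
        ours = cohen_kappa(confusion(y_true, y_pred, n_classes=6))
        assert ours == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_degenerate_single_cell_undefined(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 10
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(cm)

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.9, "almost perfect agreement"),
            (0.81, "almost perfect agreement"),
            (0.7, "significant agreement"),
            (0.5, "moderate agreement"),
            (0.3, "fair agreement"),
            (0.1, "very low agreement"),
            (-0.2, "no agreement"),
        ],
    )
    def test_band_edges(self, value, label):
        assert kappa_band(value) == label


class TestPerClassKappa:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 5, 5, 10])
        out = per_class_kappa(y, y)
        for c in (0, 5, 10):
            assert out[c] == pytest.approx(1.0)

    def test_absent_class_marked_none(self):
        out = per_class_kappa([0, 0, 1], [0, 0, 1], n_classes=11)
        assert out[7] is None

    def test_binary_collapse_matches_overall_binary(self):
        # truth/prediction realizing the matrix [[4, 1], [2, 3]] with class 0
        # as the positive label; the one-vs-rest collapse for class 0 swaps
        # positive/negative, which leaves kappa unchanged (it is symmetric)
        y_true = [0] * 5 + [1] * 5
        y_pred = [0, 0, 0, 0, 1, 0, 0, 1, 1, 1]
        out = per_class_kappa(y_true, y_pred, n_classes=2)
        assert out[0] == pytest.approx(0.4)
        assert out[1] == pytest.approx(0.4)


class TestAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        P = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert ovr_macro_auc(y, P) == 1.0

    def test_constant_scores_give_half(self):
        y = np.array([0, 0, 1, 1])
        P = np.full((4, 2), 0.5)
        assert ovr_macro_auc(y, P) == pytest.approx(0.5)

    def test_four_sample_pair_counting(self):
        y = np.array([1, 1, 0, 0])
        perfect = np.array([0.9, 0.8, 0.7, 0.6])
        P = np.column_stack([1 - perfect, perfect])
        assert ovr_macro_auc(y, P) == pytest.approx(1.0)
        # swap the middle two scores: 3 of 4 positive/negative pairs ordered
        swapped = np.array([0.9, 0.7, 0.8, 0.6])
        P2 = np.column_stack([1 - swapped, swapped])
        assert ovr_macro_auc(y, P2) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            ovr_macro_auc([1, 1], np.array([[0.5, 0.5], [0.5, 0.5]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 2), min_size=2, max_size=50),
        seed=st.integers(0, 10_000),
    )
    def test_rank_statistic_equals_exhaustive_pair_counting(self, labels, seed):
        y = np.array(labels)
        if np.unique(y).size < 2:
            return
        rng = np.random.default_rng(seed)
        P = rng.random((len(y), 3))
        P /= P.sum(axis=1, keepdims=True)

        def pair_count_auc(y_bin, s):
            pos = s[y_bin == 1]
            neg = s[y_bin == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            return wins / (len(pos) * len(neg))

        expected = np.mean(
            [pair_count_auc((y == c).astype(int), P[:, c]) for c in np.unique(y)]
        )
        assert ovr_macro_auc(y, P) == pytest.approx(float(expected))

    def test_matches_sklearn_ovr_macro(self, rng):
        y = rng.integers(0, 4, 120)
        P = rng.random((120, 4))
        P /= P.sum(axis=1, keepdims=True)
        ours = ovr_macro_auc(y, P)
        theirs = roc_auc_score(y, P, multi_class="ovr", average="macro")
        assert ours == pytest.approx(theirs)


class TestErrorsAndHistograms:
    def test_simple_error(self):
        assert error_vector([100], [90])[0] == 10

    def test_perfect_predictions_zero_errors_same_histograms(self):
        scores = [0, 10, 50, 100, 50]
        assert (error_vector(scores, scores) == 0).all()
        assert band_histogram(scores) == band_histogram(list(scores))

    def test_histogram_counts_conserve_n(self, rng):
        scores = rng.choice(np.arange(0, 101, 10), 57)
        hist = band_histogram(scores)
        assert sum(hist.values()) == 57
        assert set(hist) == set(range(0, 101, 10))

    def test_invalid_score_rejected(self):
        with pytest.raises(Exception):
            error_vector([55], [50])


class TestEvalReport:
    def test_assembles_consistent_report(self, rng):
        y_true = rng.integers(0, 11, 100)
        y_pred = np.where(rng.random(100) < 0.8, y_true, rng.integers(0, 11, 100))
        P = np.full((100, 11), 0.01)
        P[np.arange(100), y_pred] = 0.9
        P /= P.sum(axis=1, keepdims=True)
        rep = evaluate_predictions(y_true, y_pred, P)
        assert 0 <= rep.accuracy <= 1
        assert -1 <= rep.kappa <= 1
        assert rep.kappa_label == kappa_band(rep.kappa)
        assert rep.errors.shape == (100,)
        assert (rep.errors % 10 == 0).all()
        assert sum(rep.true_histogram.values()) == 100
        summary = rep.summary()
        assert set(summary) == {
            "accuracy", "macro_precision", "macro_recall", "macro_f1",
            "kappa", "macro_auc",
        }
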