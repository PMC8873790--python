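"""Metric implementations against brute-force and library oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support, roc_auc_score

from migcn.metrics import (
    cohens_kappa,
    confusion_and_gaa,
    evaluate_predictions,
    macro_prf1,
    multiclass_roc_auc,
    summary_stats,
)


def random_labels(rng, n=60):
    y_true = rng.integers(0, 4, n)
    y_pred = rng.integers(0, 4, n)
    return y_true, y_pred


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.repeat(np.arange(4), 5)
        C, gaa, per_class = confusion_and_gaa(y, y)
        assert np.all(C == np.diag([5, 5, 5, 5]))
        assert gaa == 1.0
        assert np.all(per_class == 1.0)

    def test_constant_prediction_on_balanced_labels(self):
        y = np.repeat(np.arange(4), 10)
        C, gaa, _ = confusion_and_gaa(y, np.zeros_like(y))
        assert gaa == 0.25

    def test_gaa_is_count_weighted_mean_of_per_class_accuracy(self, rng):
        for _ in range(50):
            y_true, y_pred = random_labels(rng)
            C, gaa, per_class = confusion_and_gaa(y_true, y_pred)
            row = C.sum(axis=1)
            assert gaa == pytest.approx((per_class * row).sum() / row.sum())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_gaa([], [])


class TestKappa:
    def test_diagonal_table_gives_one(self):
        assert cohens_kappa(np.diag([3, 4, 5, 6])) == pytest.approx(1.0)

    def test_independent_table_gives_zero(self):
        rows = np.array([10, 20, 30, 40], float)
        cols = np.array([25, 25, 25, 25], float)
        C = np.outer(rows, cols) / cols.sum()
        assert cohens_kappa(C) == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle_and_sklearn(self, rng):
        for _ in range(50):
            y_true, y_pred = random_labels(rng)
            C, _, _ = confusion_and_gaa(y_true, y_pred)
            n = C.sum()
            p_o = np.trace(C) / n
            p_e = (C.sum(1) * C.sum(0)).sum() / n**2
            assert cohens_kappa(C) == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
            assert cohens_kappa(C) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )

    def test_degenerate_single_cell_table(self):
        C = np.zeros((4, 4))
        C[2, 2] = 10
        assert cohens_kappa(C) == 0.0


class TestMacroPRF1:
    def test_perfect_prediction(self):
        p, r, f = macro_prf1(np.diag([2, 3, 4, 5]))
        assert p == r == f == 1.0

    def test_never_predicted_class_contributes_zero_precision(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 0, 0])
        C, _, _ = confusion_and_gaa(y_true, y_pred, n_classes=2)
        p, r, f = macro_prf1(C)
        assert p == pytest.approx((2 / 4 + 0) / 2)

    def test_matches_per_class_hand_computation_and_sklearn(self, rng):
        for _ in range(50):
            y_true, y_pred = random_labels(rng)
            C, _, _ = confusion_and_gaa(y_true, y_pred)
            p, r, f = macro_prf1(C)
            ps, rs, fs = [], [], []
            for c in range(4):
                tp = C[c, c]
                fp = C[:, c].sum() - tp
                fn = C[c, :].sum() - tp
                pc = tp / (tp + fp) if tp + fp else 0.0
                rc = tp / (tp + fn) if tp + fn else 0.0
                fc = 2 * pc * rc / (pc + rc) if pc + rc else 0.0
                ps.append(pc), rs.append(rc), fs.append(fc)
            assert p == pytest.approx(np.mean(ps), abs=1e-12)
            assert r == pytest.approx(np.mean(rs), abs=1e-12)
            assert f == pytest.approx(np.mean(fs), abs=1e-12)
            sp, sr, sf, _ = precision_recall_fscore_support(
                y_true, y_pred, average="macro", zero_division=0, labels=range(4)
            )
            assert (p, r, f) == pytest.approx((sp, sr, sf), abs=1e-12)


class TestRocAuc:
    def test_one_hot_truth_gives_auc_one(self):
        y = np.array([0, 1, 2, 3, 1])
        P = np.eye(4)[y]
        _, auc = multiclass_roc_auc(y, P)
        assert auc == pytest.approx(1.0)

    def test_uniform_scores_give_half(self):
        y = np.array([0, 1, 2, 3])
        P = np.full((4, 4), 0.25)
        _, auc = multiclass_roc_auc(y, P)
        assert auc == pytest.approx(0.5)

    def test_small_instance_matches_threshold_sweep_oracle(self, rng):
        for _ in range(30):
            y = rng.integers(0, 4, 6)
            if len(np.unique(y)) < 2:
                continue
            P = rng.random((6, 4))
            P /= P.sum(axis=1, keepdims=True)
            _, auc = multiclass_roc_auc(y, P)
            # exhaustive threshold sweep over pooled (sample, class) pairs
            truth = np.zeros((6, 4), bool)
            truth[np.arange(6), y] = True
            s, t = P.ravel(), truth.ravel()
            pts = [(0.0, 0.0)]
            for thr in sorted(set(s), reverse=True):
                sel = s >= thr
                pts.append(((sel & ~t).sum() / (~t).sum(), (sel & t).sum() / t.sum()))
            pts = np.array(pts)
            ref = np.trapezoid(pts[:, 1], pts[:, 0])
            assert auc == pytest.approx(ref, abs=1e-12)
            # sklearn micro average as independent library check
            assert auc == pytest.approx(
                roc_auc_score(truth.ravel(), P.ravel()), abs=1e-9
            )

    def test_invariant_under_monotone_score_transform(self, rng):
        y = rng.integers(0, 4, 40)
        P = rng.random((40, 4))
        P /= P.sum(axis=1, keepdims=True)
        roc1, auc1 = multiclass_roc_auc(y, P)
        # global affine map with matching renormalization keeps rows summing
        # to one and is strictly increasing on the pooled scores
        c = 0.7
        Q = (P + c) / (1 + 4 * c)
        roc2, auc2 = multiclass_roc_auc(y, Q)
        assert auc2 == pytest.approx(auc1, abs=1e-12)
        assert np.allclose(roc1, roc2)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            multiclass_roc_auc(np.zeros(5, int), np.full((5, 4), 0.25))

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            multiclass_roc_auc(np.array([0, 1]), np.ones((2, 4)))


class TestReportAndSummary:
    def test_kappa_is_one_iff_confusion_diagonal(self, rng):
        y_true, y_pred = random_labels(rng)
        rep = evaluate_predictions(y_true, y_pred)
        diagonal = np.all(rep.confusion == np.diag(np.diag(rep.confusion)))
        assert (rep.kappa == pytest.approx(1.0)) == diagonal

    def test_summary_median_matches_direct_sort(self):
        vals = [0.9, 0.7, 0.95, 0.8, 0.85]
        s = summary_stats(vals)
        assert s["median"] == np.median(vals)
        assert s["q1"] <= s["median"] <= s["q3"]
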