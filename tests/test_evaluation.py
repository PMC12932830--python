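"""Metrics, statistical tests, decision curves, feature selection and
the classical-classifier bench."""

import numpy as np
import pytest
from scipy import stats as _stats

from arlnet.evaluation import (ConfusionCounts, bootstrap_auc_ci, cfs_merit,
                               cfs_select, confusion_matrix, decision_curve,
                               delong_test, forest_select, paired_model_tests,
                               rfe_select, roc_pr_brier, run_classifier_bench,
                               threshold_metrics)


def pairwise_auc(labels, scores):
    """Independent oracle: exhaustive positive-negative pair counting
    (ties count one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_count(self):
        c = confusion_matrix([1, 1, 0, 0], [1, 0, 0, 0])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 2, 0)

    def test_perfect_predictions(self):
        c = confusion_matrix([1, 0, 1], [0.9, 0.1, 0.8])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_on_negatives(self):
        c = confusion_matrix([0] * 5, [1] * 5)
        assert c.fp == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestThresholdMetrics:
    def test_reference_final_model_counts(self):
        # the printed confusion matrix: 449 TP, 7 FN, 456 TN, 0 FP
        m = threshold_metrics(ConfusionCounts(tp=449, tn=456, fp=0, fn=7))
        assert m["recall"] == pytest.approx(449 / 456)
        assert m["recall"] >= 0.984
        assert m["precision"] == 1.0
        assert m["accuracy"] == pytest.approx(905 / 912)

    def test_symmetric_unit_case(self):
        m = threshold_metrics(ConfusionCounts(1, 1, 1, 1))
        assert m["accuracy"] == 0.5 and m["f1"] == 0.5

    def test_zero_over_zero_resolves_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            m = threshold_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocPrBrier:
    def test_perfect_separation(self):
        roc, pr, brier = roc_pr_brier([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc == 1.0 and pr == 1.0 and brier < 0.25

    def test_exact_probabilities_zero_brier(self):
        _, _, brier = roc_pr_brier([0, 1], [0.0, 1.0])
        assert brier == 0.0

    def test_hand_case_three_quarters(self):
        roc, _, _ = roc_pr_brier([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert roc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_brier([1, 1], [0.5, 0.6])

    @pytest.mark.parametrize("seed", range(8))
    def test_rank_formulation_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        roc, _, _ = roc_pr_brier(labels, scores)
        assert roc == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = bootstrap_auc_ci([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9],
                                  B=50, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_contains_point_estimate_and_deterministic(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        p = np.clip(0.5 * y + rng.normal(0.25, 0.2, 80), 0, 1)
        point, _, _ = roc_pr_brier(y, p)
        a = bootstrap_auc_ci(y, p, B=200, seed=1)
        b = bootstrap_auc_ci(y, p, B=200, seed=1)
        assert a == b
        assert a[0] <= point <= a[1]

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (50, 200, 800):
            y = np.tile([0, 1], n // 2)
            p = np.clip(0.5 * y + rng.normal(0.25, 0.25, n), 0, 1)
            lo, hi = bootstrap_auc_ci(y, p, B=300, seed=3)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_ci([0, 1], [0.1, 0.9], B=5)


class TestDeLong:
    def test_identical_models(self):
        y = [1, 1, 0, 0, 1, 0]
        s = [0.9, 0.8, 0.3, 0.2, 0.7, 0.1]
        diff, z, p = delong_test(y, s, s)
        assert diff == 0.0 and p == 1.0

    def test_auc_components_match_pair_counting(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        a = np.array([0.9, 0.6, 0.4, 0.5, 0.3, 0.1])
        b = np.array([0.8, 0.5, 0.2, 0.6, 0.4, 0.3])
        diff, _, _ = delong_test(y, a, b)
        assert diff == pytest.approx(pairwise_auc(y, a) - pairwise_auc(y, b))

    def test_swap_negates_difference_same_p(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 20)
        a = np.clip(0.5 * y + rng.normal(0.25, 0.2, 40), 0, 1)
        b = np.clip(0.5 * y + rng.normal(0.25, 0.3, 40), 0, 1)
        d1, z1, p1 = delong_test(y, a, b)
        d2, z2, p2 = delong_test(y, b, a)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)


class TestPairedTests:
    def test_identical_series_p_one(self):
        a = np.array([0.8, 0.9, 0.85, 0.8, 0.9, 0.88])
        t_p, w_p = paired_model_tests(a, a)
        assert t_p == 1.0 and w_p == 1.0

    def test_constant_shift_significant_and_monotone_in_n(self):
        rng = np.random.default_rng(0)
        ps = []
        for n in (8, 32):
            b = rng.normal(0.8, 0.01, n)
            shift = 0.03 + rng.normal(0, 0.02, n)  # noisy positive shift
            t_p, _ = paired_model_tests(b + shift, b)
            ps.append(t_p)
        assert ps[0] < 0.05 and ps[1] <= ps[0]

    def test_t_statistic_matches_closed_form(self):
        a = np.array([0.90, 0.85, 0.88, 0.92, 0.87, 0.91])
        b = np.array([0.80, 0.82, 0.85, 0.84, 0.83, 0.86])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected_p = 2 * _stats.t.sf(abs(t), len(d) - 1)
        t_p, _ = paired_model_tests(a, b)
        assert t_p == pytest.approx(expected_p)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            paired_model_tests([1, 2], [2, 3])


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self):
        y = [1, 0, 1, 0]
        curve = decision_curve(y, [0.9, 0.1, 0.8, 0.2], np.linspace(0.1, 0.9, 9))
        assert (curve["nb_none"] == 0).all()

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        p = y.astype(float)
        curve = decision_curve(y, p, np.array([0.1, 0.5, 0.9]))
        assert np.allclose(curve["nb_model"], 0.2)

    def test_hand_substitution(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.5, 0.3, 0.25, 0.1, 0.1, 0.1, 0.1, 0.1])
        curve = decision_curve(y, p, np.array([0.2]))
        assert curve["nb_model"].iloc[0] == pytest.approx(0.3 - 0.2 * 0.25)

    def test_boundary_thresholds_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0, 1], [0.2, 0.8], np.array([0.0, 0.5]))


class TestFeatureSelection:
    def _informative(self, seed=0, n=120, p=10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = (X[:, 0] + 0.2 * rng.normal(size=n) > 0).astype(int)
        return X, y

    def test_cfs_single_feature_merit_is_abs_correlation(self):
        X, y = self._informative()
        merit = cfs_merit(X, y, [0])
        assert merit == pytest.approx(abs(np.corrcoef(X[:, 0], y)[0, 1]))

    def test_cfs_duplicate_feature_never_helps(self):
        X, y = self._informative()
        X_dup = np.column_stack([X, X[:, 0]])
        base = cfs_merit(X_dup, y, [0])
        with_dup = cfs_merit(X_dup, y, [0, X.shape[1]])
        assert with_dup <= base + 1e-12

    def test_cfs_picks_informative_feature_first(self):
        X, y = self._informative(seed=3)
        assert cfs_select(X, y, k=1) == [0]

    def test_forest_ranks_label_copy_first(self):
        X, y = self._informative(seed=1)
        X2 = np.column_stack([X, y.astype(float)])
        idx, imp = forest_select(X2, y, k=3, seed=0)
        assert idx[0] == X.shape[1]
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0)

    def test_forest_k_all_is_identity_by_importance(self):
        X, y = self._informative(seed=2, p=5)
        idx, imp = forest_select(X, y, k=5, seed=0)
        assert sorted(idx) == list(range(5))
        assert list(imp[idx]) == sorted(imp, reverse=True)

    def test_rfe_k_all_identity(self):
        X, y = self._informative(p=6)
        assert rfe_select(X, y, k=6) == list(range(6))

    def test_rfe_keeps_label_copy_over_noise(self):
        X, y = self._informative(seed=5, p=4)
        X2 = np.column_stack([X, y.astype(float)])
        kept = rfe_select(X2, y, k=2, seed=0)
        assert X.shape[1] in kept

    def test_invalid_k_rejected(self):
        X, y = self._informative(p=4)
        with pytest.raises(ValueError):
            rfe_select(X, y, k=0)
        with pytest.raises(ValueError):
            cfs_select(X, y, k=99)


class TestClassifierBench:
    def test_cartesian_rows_and_metric_ranges(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 12))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        bench = run_classifier_bench(X[:60], y[:60], X[60:], y[60:],
                                     selectors=("all", "ff"),
                                     classifiers=("dt", "nb"),
                                     k_features=5, seed=0)
        assert len(bench) == 4
        metric_cols = [c for c in bench.columns
                       if c.startswith(("train_acc", "test_"))
                       or c in ("roc_auc", "pr_auc", "brier")]
        values = bench[metric_cols].to_numpy(dtype=float)
        assert np.nanmin(values) >= 0.0 and np.nanmax(values) <= 1.0

    def test_unpruned_tree_overfits_noisy_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 10))
        y = (X[:, 0] + 1.5 * rng.normal(size=120) > 0).astype(int)
        bench = run_classifier_bench(X[:90], y[:90], X[90:], y[90:],
                                     selectors=("all",), classifiers=("dt",),
                                     seed=0)
        row = bench.iloc[0]
        assert row["train_accuracy"] >= row["test_accuracy"]
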