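"""Cohort diagnostics: ROC/AUC, Youden cutoff, confusion metrics, group tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from conftest import make_cohort

from elasto_bcp import (
    ConfusionTable,
    classify_at,
    compare_groups,
    count_below,
    diagnostic_metrics,
    feature_performance,
    roc_curve,
    youden_cutoff,
)


def brute_force_auc(pos, neg):
    """Exhaustive pair counting: concordant pairs + half the ties."""
    wins = sum(p > n for p, n in itertools.product(pos, neg))
    ties = sum(p == n for p, n in itertools.product(pos, neg))
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(pos, neg):
    """Best (lowest) threshold by direct counting over every midpoint."""
    v = sorted(set(pos) | set(neg))
    candidates = [v[0] - 1] + [(a + b) / 2 for a, b in zip(v, v[1:])] + [v[-1] + 1]
    best_t, best_j = None, -2.0
    for t in candidates:
        sens = sum(p > t for p in pos) / len(pos)
        spec = sum(n <= t for n in neg) / len(neg)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return best_t, best_j


score_lists = st.lists(
    st.floats(0, 100, allow_nan=False).map(lambda x: round(x, 1)),
    min_size=2,
    max_size=15,
)


class TestRocCurve:
    def test_four_node_example(self, small_cohort):
        # benign {10, 35}, malignant {30, 80}: 3 concordant of 4 pairs
        roc = roc_curve(small_cohort, n_boot=50, seed=0)
        assert roc.auc == pytest.approx(brute_force_auc([30.0, 80.0], [10.0, 35.0]))
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self, cohort_factory):
        cohort = cohort_factory([5.0, 10.0, 20.0], [50.0, 60.0, 70.0])
        roc = roc_curve(cohort, n_boot=50, seed=0)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.youden_cutoff == pytest.approx(35.0)  # midpoint of the gap

    def test_null_scores_give_chance_auc(self, cohort_factory):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(200):
            scores = rng.uniform(0, 100, 20)
            cohort = cohort_factory(scores[:10], scores[10:])
            aucs.append(roc_curve(cohort, n_boot=1, seed=0).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_monotone_sweep(self, cohort_factory):
        cohort = cohort_factory([10, 20, 20, 35], [30, 30, 55, 80])
        roc = roc_curve(cohort, n_boot=10, seed=0)
        assert (np.diff(roc.sens) <= 0).all()
        assert (np.diff(roc.spec) >= 0).all()

    def test_single_class_rejected(self, cohort_factory):
        with pytest.raises(ValueError, match="both"):
            roc_curve(cohort_factory([10, 20], []))

    @settings(max_examples=60, deadline=None)
    @given(neg=score_lists, pos=score_lists)
    def test_auc_equals_pairwise_concordance(self, neg, pos):
        cohort = make_cohort(neg, pos)
        roc = roc_curve(cohort, n_boot=1, seed=0)
        assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-9)
        y = [0] * len(neg) + [1] * len(pos)
        assert roc.auc == pytest.approx(roc_auc_score(y, neg + pos), abs=1e-9)

    def test_bootstrap_ci_reproducible_and_covers_point(self, cohort_factory):
        rng = np.random.default_rng(11)
        cohort = cohort_factory(rng.uniform(0, 60, 20), rng.uniform(30, 100, 20))
        a = roc_curve(cohort, n_boot=500, seed=7)
        b = roc_curve(cohort, n_boot=500, seed=7)
        assert (a.auc_ci_low, a.auc_ci_high) == (b.auc_ci_low, b.auc_ci_high)
        assert a.auc_ci_low <= a.auc <= a.auc_ci_high


class TestYoudenCutoff:
    def test_four_node_example_by_enumeration(self, small_cohort):
        roc = roc_curve(small_cohort, n_boot=10, seed=0)
        cut, j = youden_cutoff(roc)
        oracle_cut, oracle_j = brute_force_youden([30.0, 80.0], [10.0, 35.0])
        assert j == pytest.approx(oracle_j) == pytest.approx(0.5)
        assert cut == pytest.approx(oracle_cut)
        # J = 0.5 is attained at thresholds 20 and 57.5; the lowest-threshold
        # tie rule (preserving sensitivity) selects 20
        assert cut == pytest.approx(20.0)

    def test_identical_scores_give_zero_j(self, cohort_factory):
        roc = roc_curve(cohort_factory([40, 40], [40, 40]), n_boot=10, seed=0)
        assert youden_cutoff(roc)[1] == 0.0

    @settings(max_examples=60, deadline=None)
    @given(neg=score_lists, pos=score_lists)
    def test_agrees_with_brute_force(self, neg, pos):
        roc = roc_curve(make_cohort(neg, pos), n_boot=1, seed=0)
        cut, j = youden_cutoff(roc)
        oracle_cut, oracle_j = brute_force_youden(pos, neg)
        assert j == pytest.approx(oracle_j, abs=1e-9)
        assert cut == pytest.approx(oracle_cut, abs=1e-9)


class TestClassifyAt:
    def test_extreme_cutoffs(self, cohort_factory):
        cohort = cohort_factory([10, 20], [60, 70, 80])
        low = classify_at(cohort, -1.0)
        assert (low.tp, low.fp, low.fn, low.tn) == (3, 2, 0, 0)
        high = classify_at(cohort, 101.0)
        assert (high.tp, high.fp, high.fn, high.tn) == (0, 0, 3, 2)

    def test_score_equal_to_cutoff_is_predicted_benign(self, cohort_factory):
        cohort = cohort_factory([36.7], [36.7, 50.0])
        t = classify_at(cohort, 36.7)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 1, 1)


class TestDiagnosticMetrics:
    def test_reference_confusion_counts(self):
        m = diagnostic_metrics(ConfusionTable(tp=36, fp=14, fn=3, tn=26))
        assert m["sensitivity"] == 92.3
        assert m["accuracy"] == 78.5
        assert m["specificity"] == 65.0
        assert m["ppv"] == 72.0
        assert m["npv"] == 89.7

    def test_undefined_metric_flagged_not_zero(self):
        m = diagnostic_metrics(ConfusionTable(tp=0, fp=3, fn=0, tn=5))
        assert m["sensitivity"] is None
        assert m["specificity"] == 62.5

    def test_count_conservation(self):
        t = ConfusionTable(tp=36, fp=14, fn=3, tn=26)
        m = diagnostic_metrics(t)
        correct = m["sensitivity"] / 100 * (t.tp + t.fn) + m["specificity"] / 100 * (
            t.tn + t.fp
        )
        assert correct + t.fp + t.fn == pytest.approx(t.total, abs=0.1)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=0, fp=0, fn=0, tn=0)


class TestFeaturePerformance:
    def test_constant_negative_feature(self, cohort_factory):
        cohort = cohort_factory([10, 20], [60, 70], round_shape=[0, 0, 0, 0])
        perf = feature_performance(cohort, "round_shape")
        assert perf == {"sensitivity": 0.0, "specificity": 100.0}

    def test_suv_unmeasured_records_excluded(self, cohort_factory):
        cohort = cohort_factory(
            [10, 20, 30], [60, 70, 80],
            suv_gt_2_5=[0.0, np.nan, np.nan, 1.0, 1.0, np.nan],
        )
        perf = feature_performance(cohort, "suv_gt_2_5")
        assert perf == {"sensitivity": 100.0, "specificity": 100.0}

    def test_all_undefined_rejected(self, cohort_factory):
        cohort = cohort_factory([10], [60], suv_gt_2_5=[np.nan, np.nan])
        with pytest.raises(ValueError):
            feature_performance(cohort, "suv_gt_2_5")


class TestCompareGroups:
    def test_identical_groups(self, cohort_factory):
        cohort = cohort_factory([10, 20, 30], [10, 20, 30])
        out = compare_groups(cohort)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["malignant"]["mean"] == out["benign"]["mean"]

    def test_well_separated_groups(self, cohort_factory):
        cohort = cohort_factory([0.0, 1.0, 0.0], [99.0, 100.0, 100.0])
        out = compare_groups(cohort)
        assert out["p_value"] < 1e-6
        assert out["benign"]["mean"] < 1 < 99 < out["malignant"]["mean"]
        assert out["malignant"]["sd"] > 0  # n-1 denominator, not population SD

    def test_requires_two_per_group(self, cohort_factory):
        with pytest.raises(ValueError):
            compare_groups(cohort_factory([10], [60, 70]))


def test_count_below_floor(cohort_factory):
    cohort = cohort_factory([10, 20, 50], [30, 60])
    out = count_below(cohort, 27.9)
    assert out["n_below"] == 2 and out["all_benign"]
    out2 = count_below(cohort, 35.0)
    assert out2["n_below"] == 3 and not out2["all_benign"]
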