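"""Cohort statistics: formula oracles, enumeration oracles, and invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighrep.diagnostics import (
    Unclassifiable,
    binary_metrics_at_threshold,
    classify_rejection,
    fit_exponential_trend,
    mann_whitney_one_sided,
    pearson_with_fisher_ci,
    roc_c_statistic,
    wilson_cc_interval,
)


class TestClassifyRejection:
    def test_clean_sample_is_none(self):
        assert classify_rejection("0", 0.3) == frozenset({"none"})

    def test_biopsy_and_cfddna_labels_overlap(self):
        assert classify_rejection("2R", 2.5) == frozenset(
            {"mod_severe_ACR", "elevated_cfdDNA"}
        )

    def test_cfddna_only(self):
        assert classify_rejection("NA", 1.5) == frozenset({"elevated_cfdDNA"})

    def test_mild_and_grade3(self):
        assert classify_rejection("1R", 0.2) == frozenset({"mild_ACR"})
        assert classify_rejection("3R", None) == frozenset({"mod_severe_ACR"})

    def test_threshold_is_open_bound(self):
        assert classify_rejection("NA", 1.0) == frozenset({"none"})

    def test_unclassifiable_without_any_field(self):
        with pytest.raises(Unclassifiable):
            classify_rejection(None, None)

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            classify_rejection("4X", 0.5)


class TestPearsonFisher:
    def test_textbook_formula_agreement(self):
        """Seeded bivariate draws: CI matches a direct recomputation to 1e-12."""
        rng = np.random.default_rng(10)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=100)
        r, lo, hi = pearson_with_fisher_ci(xy[:, 0], xy[:, 1])
        n = 100
        r_direct = float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
        z = 1.959963984540054
        assert abs(r - r_direct) < 1e-12
        assert abs(lo - math.tanh(math.atanh(r_direct) - z / math.sqrt(n - 3))) < 1e-12
        assert abs(hi - math.tanh(math.atanh(r_direct) + z / math.sqrt(n - 3))) < 1e-12

    def test_perfect_correlation_degenerates(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_with_fisher_ci(x, 2 * x + 1)
        assert r == lo == hi == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_fisher_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_null_coverage_near_nominal(self):
        """~95% of Fisher CIs cover rho=0 on 1,000 null datasets of n=10."""
        rng = np.random.default_rng(2)
        cover = 0
        n_sim = 1000
        for _ in range(n_sim):
            x, y = rng.normal(size=10), rng.normal(size=10)
            _, lo, hi = pearson_with_fisher_ci(x, y)
            cover += lo <= 0.0 <= hi
        se = math.sqrt(0.95 * 0.05 / n_sim)
        assert abs(cover / n_sim - 0.95) < 3 * se + 0.005


def _mwu_enumeration_p(a, b):
    """Exact one-sided p by full permutation enumeration (no ties)."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        grp = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        u = sum(1 for x in grp for y in rest if x > y) + 0.5 * sum(
            1 for x in grp for y in rest if x == y
        )
        count += u >= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney_one_sided([5, 6, 7], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(1 / 20)

    def test_identical_groups_p_at_least_half(self):
        _, p = mann_whitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_exact_branch_equals_full_enumeration(self):
        rng = np.random.default_rng(3)
        for na, nb in [(3, 4), (5, 5), (6, 4), (8, 8)]:
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 0.5
            _, p = mann_whitney_one_sided(a, b)
            assert p == pytest.approx(_mwu_enumeration_p(a, b), abs=1e-12)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        _, p_exact = mann_whitney_one_sided(a, b)  # 225 <= 400 -> exact
        big_a = np.concatenate([a, rng.normal(size=10)])
        # force the asymptotic branch via a tie on values that do not change order much
        from scipy import stats

        p_asym = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


def _auc_bruteforce(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1 for p in pos for n in neg if p > n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocCStatistic:
    def test_perfect_separation(self):
        auc, lo, hi, pts = roc_c_statistic([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=200)
        assert auc == 1.0
        assert {"threshold", "fpr", "tpr"} <= set(pts.columns)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        auc, *_ = roc_c_statistic(scores, labels, n_boot=10)
        assert abs(auc - 0.5) < 0.04

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_c_statistic([1, 2, 3], [1, 1, 1], n_boot=10)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_pair_count(self, data):
        n = data.draw(st.integers(min_value=4, max_value=50))
        scores = data.draw(
            st.lists(st.integers(min_value=0, max_value=9), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        auc, *_ = roc_c_statistic(scores, labels, n_boot=2)
        assert auc == pytest.approx(_auc_bruteforce(scores, labels))

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 60)])
        labels = np.array([True] * 40 + [False] * 60)
        auc, lo, hi, _ = roc_c_statistic(scores, labels, n_boot=500, seed=1)
        assert lo <= auc <= hi


def _wilson_cc_independent(k, n, alpha=0.05):
    """Newcombe's continuity-corrected formulation, written out separately."""
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    p = k / n
    lo = (
        (2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)))
        / (2 * (n + z * z))
        if k > 0
        else 0.0
    )
    hi = (
        (2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)))
        / (2 * (n + z * z))
        if k < n
        else 1.0
    )
    return max(0.0, lo), min(1.0, hi)


class TestWilsonCC:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = wilson_cc_interval(0, 10)
        assert lo == 0.0 and hi > 0.0

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = wilson_cc_interval(10, 10)
        assert hi == 1.0 and lo < 1.0

    def test_matches_independent_formula(self):
        for k, n in [(17, 20), (1, 8), (5, 7), (50, 100), (3, 3)]:
            got = wilson_cc_interval(k, n)
            want = _wilson_cc_independent(k, n)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_interval_contains_point_estimate(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = wilson_cc_interval(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_width_shrinks_with_n_at_fixed_ratio(self):
        widths = []
        for n in (10, 20, 40, 80, 160):
            k = (3 * n) // 10
            lo, hi = wilson_cc_interval(k, n)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_cc_interval(5, 4)
        with pytest.raises(ValueError):
            wilson_cc_interval(-1, 4)


class TestBinaryMetrics:
    def test_five_of_seven_positives_called(self):
        scores = [0.05, 0.04, 0.03, 0.03, 0.025, 0.01, 0.02] + [0.01] * 10
        labels = [True] * 7 + [False] * 10
        m = binary_metrics_at_threshold(scores, labels, threshold=0.023)
        assert m.tp == 5 and m.fn == 2
        assert m.sensitivity == pytest.approx(5 / 7)
        assert round(m.sensitivity * 100, 1) == 71.4

    def test_threshold_below_all_scores(self):
        m = binary_metrics_at_threshold([1, 2, 3, 4], [True, False, True, False], 0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.npv is None

    def test_threshold_above_all_scores(self):
        m = binary_metrics_at_threshold([1, 2, 3, 4], [True, False, True, False], 99.0)
        assert m.sensitivity == 0.0 and m.specificity == 1.0
        assert m.ppv is None

    def test_ci_bounds_bracket_estimates(self):
        rng = np.random.default_rng(8)
        scores = rng.random(200)
        labels = scores + rng.normal(0, 0.3, 200) > 0.5
        m = binary_metrics_at_threshold(scores, labels, 0.5)
        assert m.sensitivity_ci[0] <= m.sensitivity <= m.sensitivity_ci[1]
        assert m.specificity_ci[0] <= m.specificity <= m.specificity_ci[1]


class TestExponentialFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 301, 30, dtype=float)
        y = 0.03 * np.exp(0.005 * t)
        fit = fit_exponential_trend(t, y)
        assert fit.a == pytest.approx(0.03, abs=1e-8)
        assert fit.b == pytest.approx(0.005, abs=1e-8)

    def test_constant_series(self):
        fit = fit_exponential_trend([0, 10, 20, 30], [0.02] * 4)
        assert fit.a == pytest.approx(0.02, abs=1e-10)
        assert fit.b == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        rng = np.random.default_rng(9)
        t = np.arange(0, 241, 20, dtype=float)
        y = 0.04 * np.exp(0.004 * t) * np.exp(rng.normal(0, 0.1, t.size))
        fit = fit_exponential_trend(t, y)
        a_grid = np.linspace(0.02, 0.08, 121)
        b_grid = np.linspace(0.0, 0.01, 201)
        rss = np.array(
            [
                [((y - a * np.exp(b * t)) ** 2).sum() for b in b_grid]
                for a in a_grid
            ]
        )
        ia, ib = np.unravel_index(np.argmin(rss), rss.shape)
        assert fit.a == pytest.approx(a_grid[ia], abs=(a_grid[1] - a_grid[0]))
        assert fit.b == pytest.approx(b_grid[ib], abs=(b_grid[1] - b_grid[0]))
        assert fit.rss <= rss[ia, ib] + 1e-12

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_trend([0, 1, 2], [0.1, 0.0, 0.2])
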