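"""Statistical primitives, cross-checked against scipy/statsmodels/lifelines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from deltap import exact_stats as es

# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisher:
    def test_small_symmetric_table_full_mass(self):
        # margins 3/3; hypergeometric masses .05,.45,.45,.05 are all <= .45
        res = es.fisher_exact(es.ContingencyTable(2, 1, 1, 2))
        assert res.p_two_sided == pytest.approx(1.0)

    def test_identical_rows(self):
        assert es.fisher_exact(es.ContingencyTable(5, 5, 5, 5)).p_two_sided == 1.0

    def test_published_sex_table(self):
        # 28/44 vs 26/43 female: printed P = 0.82
        res = es.fisher_exact(es.ContingencyTable(28, 16, 26, 17))
        assert res.p_two_sided == pytest.approx(0.82, abs=0.01)

    def test_degenerate_margin_raises(self):
        with pytest.raises(es.DegenerateTableError, match="degenerate"):
            es.fisher_exact(es.ContingencyTable(0, 0, 3, 4))

    def test_zero_cell_haldane_correction_flagged(self):
        res = es.fisher_exact(es.ContingencyTable(0, 10, 5, 5))
        assert res.zero_cell_corrected
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_odds_ratio_is_cross_product(self):
        res = es.fisher_exact(es.ContingencyTable(29, 15, 7, 36))
        assert res.odds_ratio == pytest.approx(29 * 36 / (15 * 7))

    @given(st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_scipy_and_transpose_invariant(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = es.fisher_exact(es.ContingencyTable(a, b, c, d)).p_two_sided
        assert p == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-10)
        # swapping rows with columns leaves the two-sided p unchanged
        pt = es.fisher_exact(es.ContingencyTable(a, c, b, d)).p_two_sided
        assert p == pytest.approx(pt, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples(self):
        res = es.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u == 9 / 2
        assert res.p_two_sided == 1.0

    def test_complete_separation_small(self):
        # one of C(6,3)=20 labelings is this extreme per side
        res = es.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_all_values_identical(self):
        res = es.mann_whitney([5.0] * 30, [5.0] * 30)
        assert res.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            es.mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_branch_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 9)
        mine = es.mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.method == "exact"
        assert mine.u == pytest.approx(ref.statistic)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_branch_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 25).astype(float)
        y = rng.integers(1, 7, 30).astype(float)
        mine = es.mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert mine.method == "normal"
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_close_to_normal_approximation(self):
        # the two branches agree within 0.02 at n = 10 + 10
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.4, 1, 10)
            exact = es.mann_whitney(x, y)
            mean_u, var_u = 50.0, 100 * 21 / 12.0
            z = max((abs(exact.u - mean_u) - 0.5) / math.sqrt(var_u), 0.0)
            approx = min(1.0, 2 * stats.norm.sf(z))
            assert abs(exact.p_two_sided - approx) < 0.02

    def test_titre_comparison_power(self):
        # log-normal titres, medians 448 vs 209 pM, sigma 1, n=40/group:
        # the group difference is detected in >= 90% of seeds
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.normal(np.log(448.0), 1.0, 40))
            y = np.exp(rng.normal(np.log(209.0), 1.0, 40))
            hits += es.mann_whitney(x, y).p_two_sided < 0.05
        assert hits / 200 >= 0.90


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def _expand_table(a, b, c, d):
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return x[:, None], y


class TestLogistic:
    def test_intercept_only_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = np.empty((100, 0))
        fit = es.logistic_fit(X, y, names=())
        p_hat = 1 / (1 + np.exp(-fit.coefficients[0]))
        assert p_hat == pytest.approx(0.3, abs=1e-9)

    def test_single_covariate_or_is_cross_product_ratio(self):
        X, y = _expand_table(29, 15, 7, 36)
        fit = es.logistic_fit(X, y, names=("smoking",))
        assert fit.odds_ratios[1] == pytest.approx(1044 / 105, rel=1e-6)

    def test_matches_statsmodels(self, default_cohort):
        import statsmodels.api as sm

        from deltap.pipeline import _item_matrix

        _, X, y = _item_matrix(default_cohort)
        ok = ~np.isnan(X).any(axis=1)
        fit = es.logistic_fit(X[ok], y[ok])
        ref = sm.Logit(y[ok], sm.add_constant(X[ok])).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)

    def test_constant_covariate_raises_naming_it(self):
        X = np.column_stack([np.r_[np.ones(5), np.zeros(5)], np.ones(10)])
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(es.SeparationError, match="always_on"):
            es.logistic_fit(X, y, names=("fine", "always_on"))

    def test_complete_separation_detected(self):
        x = np.r_[np.ones(10), np.zeros(10)][:, None]
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(es.SeparationError):
            es.logistic_fit(x, y, names=("perfect",))

    def test_needs_both_outcomes(self):
        with pytest.raises(ValueError):
            es.logistic_fit(np.ones((5, 1)), np.ones(5))


# ---------------------------------------------------------------------------
# Median CI
# ---------------------------------------------------------------------------


class TestMedianCI:
    def test_small_sample_reports_range(self):
        res = es.median_with_ci([1, 2, 3, 4, 5])
        assert res["median"] == 3
        assert res["ci_95"] == (1.0, 5.0)
        assert res["warning"] is not None

    def test_constant_sample_collapses(self):
        res = es.median_with_ci([7.0] * 20)
        assert res["ci_95"] == (7.0, 7.0)

    def test_order_statistic_coverage_n100(self):
        # for n=100 the exact binomial ranks are (40, 61): coverage 0.9648
        res = es.median_with_ci(list(range(1, 101)))
        lo, hi = res["ci_95"]
        r = int(lo)
        assert 1.0 - 2 * stats.binom(100, 0.5).cdf(r - 1) >= 0.95
        assert 1.0 - 2 * stats.binom(100, 0.5).cdf(r) < 0.95
        assert hi == 100 - r + 1

    def test_simulated_coverage(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            v = rng.normal(0, 1, 51)
            lo, hi = es.median_with_ci(v)["ci_95"]
            hits += lo <= 0.0 <= hi
        assert hits / 200 >= 0.93


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


class TestSurvival:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 4, 5.0]
        e = [1, 1, 0, 1, 1]
        res = es.survival_compare(t, e, t, e)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == 1.0

    def test_exponential_median_closed_form(self):
        lam = 0.04
        rng = np.random.default_rng(5)
        t = rng.exponential(1 / lam, 5000)
        res = es.survival_compare(t, np.ones(5000, int), t[:10], np.ones(10, int))
        assert res.medians["A"] == pytest.approx(math.log(2) / lam, rel=0.05)

    def test_km_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        km = es.survival_compare(t, np.ones(200, int),
                                 t[:5], np.ones(5, int)).groups["A"]
        for q in [1.0, 5.0, 15.0]:
            assert km.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_median_none_when_curve_stays_high(self):
        t = [10.0] * 10
        e = [1] + [0] * 9  # one event, S drops to 0.9
        res = es.survival_compare(t, e, [1.0], [1])
        assert res.medians["A"] is None

    def test_no_events_raises(self):
        with pytest.raises(es.NoEventsError):
            es.survival_compare([1, 2], [0, 0], [3, 4], [0, 0])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(9)
        ta = rng.exponential(15.6 / math.log(2), 44)
        tb = rng.exponential(50 / math.log(2), 43)
        ea = np.ones(44, int)
        eb = (rng.random(43) < 0.8).astype(int)
        mine = es.survival_compare(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.logrank_chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.logrank_p == pytest.approx(ref.p_value, rel=1e-9)

    def test_group_difference_power_at_study_size(self):
        # exponential medians 15.6 vs 50 months at n=44/43: log-rank
        # p < 0.001 in >= 90% of seeds
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(15.6 / math.log(2), 44)
            tb = rng.exponential(50 / math.log(2), 43)
            res = es.survival_compare(ta, np.ones(44, int), tb, np.ones(43, int))
            hits += res.logrank_p < 0.001
        assert hits / 60 >= 0.90
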