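"""ROC curve, AUC/DeLong, and the analytic item-probability oracle."""

import numpy as np
import pytest
from scipy import stats

from deltap import roc

# ---------------------------------------------------------------------------
# ROC points
# ---------------------------------------------------------------------------


class TestROCPoints:
    def test_perfect_separation_hits_corner(self):
        curve = roc.roc_points([3, 4, 1, 2], [1, 1, 0, 0])
        pts = set(zip(curve.fpr.tolist(), curve.sensitivity.tolist()))
        assert (0.0, 1.0) in pts

    def test_uninformative_scores_give_diagonal(self):
        curve = roc.roc_points([2, 2, 2, 2], [1, 1, 0, 0])
        assert set(zip(curve.fpr.tolist(), curve.sensitivity.tolist())) == {
            (0.0, 0.0), (1.0, 1.0)}

    def test_hand_enumerated_operating_points(self):
        # cases {2,3}, controls {1,3}: thresholds inf,3,2,1
        curve = roc.roc_points([2, 3, 1, 3], [1, 1, 0, 0])
        assert curve.thresholds.tolist() == [np.inf, 3, 2, 1]
        assert curve.sensitivity.tolist() == [0.0, 0.5, 1.0, 1.0]
        assert curve.fpr.tolist() == [0.0, 0.5, 0.5, 1.0]
        assert curve.tp.tolist() == [0, 1, 2, 2]

    def test_single_class_rejected(self):
        with pytest.raises(roc.SingleClassError):
            roc.roc_points([1, 2], [1, 1])


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


class TestAUC:
    def test_tied_pair_counting(self):
        # (2 wins + 0.5 tie) / 4 pairs
        res = roc.auc_with_ci([2, 3, 1, 3], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.625)

    def test_perfect_discrimination(self):
        res = roc.auc_with_ci([5, 6, 1, 2], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.ci_95[1] <= 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_pairwise_equals_trapezoidal_area(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        scores = rng.integers(0, 7, n)
        labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        auc = roc.auc_with_ci(scores, labels).auc
        area = roc.roc_points(scores, labels).trapezoidal_area()
        assert auc == pytest.approx(area, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_negation_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 80)
        labels = (rng.random(80) < 0.4).astype(int)
        a = roc.auc_with_ci(scores, labels).auc
        b = roc.auc_with_ci(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.integers(0, 7, 87)
        labels = (rng.random(87) < 0.5).astype(int)
        assert roc.auc_with_ci(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_null_auc_concentrates_at_half(self):
        # shuffled labels, n=500: AUC within [0.42, 0.58] in >= 95% of seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.integers(0, 7, 500)
            labels = np.r_[np.ones(250, int), np.zeros(250, int)]
            rng.shuffle(labels)
            hits += 0.42 <= roc.auc_with_ci(scores, labels).auc <= 0.58
        assert hits >= 95

    def test_delong_variance_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = rng.integers(0, 7, 40)
            labels = np.r_[np.ones(20, int), np.zeros(20, int)]
            assert roc.auc_with_ci(scores, labels).se >= 0.0


# ---------------------------------------------------------------------------
# AUC comparisons
# ---------------------------------------------------------------------------


class TestComparisons:
    def test_paired_identical_scores(self):
        scores = [1, 4, 2, 0, 3, 5]
        labels = [1, 1, 1, 0, 0, 0]
        cmp = roc.compare_auc_paired(scores, scores, labels)
        assert cmp.z == 0.0 and cmp.p_two_sided == 1.0

    def test_paired_symmetric_in_order(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 7, 87)
        b = np.clip(a + rng.integers(-1, 2, 87), 0, 6)
        y = (rng.random(87) < 0.5).astype(int)
        c1 = roc.compare_auc_paired(a, b, y)
        c2 = roc.compare_auc_paired(b, a, y)
        assert c1.p_two_sided == pytest.approx(c2.p_two_sided)
        assert c1.z == pytest.approx(-c2.z)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            roc.compare_auc_paired([1, 2], [1, 2, 3], [1, 0])

    def test_independent_equal_inputs(self):
        r = roc.AUCResult(auc=0.8, se=0.05, ci_95=(0.7, 0.9),
                          n_cases=20, n_controls=20)
        cmp = roc.compare_auc_independent(r, r)
        assert cmp.p_two_sided == 1.0

    def test_independent_published_sex_contrast(self):
        # male AUC 85.3% vs female 82.01%, SEs back-computed from the
        # printed CI half-widths: z ≈ 0.37, p ≈ 0.71
        male = roc.AUCResult(auc=0.853, se=(0.989 - 0.716) / 2 / 1.96,
                             ci_95=(0.716, 0.989), n_cases=0, n_controls=0)
        female = roc.AUCResult(auc=0.8201, se=(0.931 - 0.709) / 2 / 1.96,
                               ci_95=(0.709, 0.931), n_cases=0, n_controls=0)
        cmp = roc.compare_auc_independent(male, female)
        assert cmp.p_two_sided == pytest.approx(0.714, abs=0.01)

    def test_paired_reduces_to_independent_without_covariance(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 7, 60)
        b = rng.integers(0, 7, 60)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        paired = roc.compare_auc_paired(a, b, y)
        ra, rb = roc.auc_with_ci(a, y), roc.auc_with_ci(b, y)
        # reconstruct the paired z with the covariance term removed
        var_sum = ra.se**2 + rb.se**2
        z_nocov = paired.delta_auc / np.sqrt(var_sum)
        ind = roc.compare_auc_independent(ra, rb)
        assert ind.z == pytest.approx(z_nocov)


# ---------------------------------------------------------------------------
# Analytic score-distribution AUC
# ---------------------------------------------------------------------------


class TestAnalyticAUC:
    def test_equal_distributions(self):
        p = [0.5, 0.2, 0.7, 0.1, 0.9, 0.3]
        assert roc.analytic_auc_from_item_probs(p, p) == pytest.approx(0.5)

    def test_degenerate_extremes(self):
        assert roc.analytic_auc_from_item_probs([1] * 6, [0] * 6) == 1.0

    def test_score_distribution_sums_to_one(self):
        d = roc.score_distribution([0.545, 0.205, 0.614, 0.659, 0.909, 0.523])
        assert d.size == 7
        assert d.sum() == pytest.approx(1.0)
        # matches the Poisson-binomial mean
        assert np.dot(np.arange(7), d) == pytest.approx(
            0.545 + 0.205 + 0.614 + 0.659 + 0.909 + 0.523)

    def test_matches_monte_carlo_sampling(self):
        p_case = np.array([0.545, 0.205, 0.614, 0.659, 0.909, 0.523])
        p_ctrl = np.array([0.256, 0.186, 0.186, 0.163, 0.698, 0.233])
        exact = roc.analytic_auc_from_item_probs(p_case, p_ctrl)
        rng = np.random.default_rng(1)
        n = 200_000
        s_case = (rng.random((n, 6)) < p_case).sum(axis=1)
        s_ctrl = (rng.random((n, 6)) < p_ctrl).sum(axis=1)
        mc = roc.auc_with_ci(np.r_[s_case, s_ctrl],
                             np.r_[np.ones(n, int), np.zeros(n, int)]).auc
        assert exact == pytest.approx(mc, abs=0.005)
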