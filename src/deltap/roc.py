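"""ROC discrimination analysis for ordinal risk scores.

The empirical AUC is the pairwise (Mann-Whitney) estimator — the
probability that a randomly chosen case outscores a randomly chosen
control, ties credited 0.5 — which for integer scores such as DELTA-P
(0-6) is the natural, tie-aware estimator.  Standard errors, confidence
intervals and the paired comparison of two scores on the same patients
use the DeLong placement-value method; disjoint-subgroup comparisons use
the independent-samples z-test on the two AUCs.

Also provided is an exact score-level AUC under item independence, by
convolving six Bernoulli items per group; it serves as an analytic oracle
for simulation-based checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "AUCResult",
    "AUCComparison",
    "roc_points",
    "auc_with_ci",
    "compare_auc_paired",
    "compare_auc_independent",
    "analytic_auc_from_item_probs",
    "score_distribution",
]

Z975 = stats.norm.ppf(0.975)


class SingleClassError(ValueError):
    """ROC requested but only one outcome class is present."""


@dataclass
class ROCCurve:
    """Empirical ROC step curve: one operating point per threshold
    '>= s positive', plus the trivial (0,0) and (1,1) endpoints."""

    thresholds: np.ndarray   # descending; +inf for the (0,0) point
    sensitivity: np.ndarray
    specificity: np.ndarray
    fpr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_cases: int
    n_controls: int

    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.fpr))

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        })


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci_95: tuple
    n_cases: int
    n_controls: int
    method: str = "empirical"

    @property
    def auc_pct(self) -> float:
        return 100.0 * self.auc

    @property
    def ci_95_pct(self) -> tuple:
        return (100.0 * self.ci_95[0], 100.0 * self.ci_95[1])


@dataclass(frozen=True)
class AUCComparison:
    delta_auc: float
    z: float
    p_two_sided: float
    mode: str  # "paired" or "independent"
    correlation_estimate: float | None = None


def _split(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise SingleClassError("both outcome classes must be present")
    return cases, controls


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Exact operating points at every distinct observed score."""
    cases, controls = _split(scores, labels)
    m, n = cases.size, controls.size
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([cases, controls]))[::-1]])
    tp = np.array([(cases >= t).sum() for t in thresholds])
    fp = np.array([(controls >= t).sum() for t in thresholds])
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=tp / m,
        specificity=(n - fp) / n,
        fpr=fp / n,
        tp=tp, fp=fp, tn=n - fp, fn=m - tp,
        n_cases=m, n_controls=n,
    )


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values: V10 per case, V01 per control.

    Rank-based (searchsorted) rather than the naive m x n pairwise matrix,
    so large simulated cohorts stay cheap; ties credited 0.5 exactly.
    """
    n, m = controls.size, cases.size
    sc = np.sort(controls)
    lo = np.searchsorted(sc, cases, side="left")
    hi = np.searchsorted(sc, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n
    sx = np.sort(cases)
    lo_c = np.searchsorted(sx, controls, side="left")
    hi_c = np.searchsorted(sx, controls, side="right")
    v01 = ((m - hi_c) + 0.5 * (hi_c - lo_c)) / m
    return v10, v01, float(v10.mean())


def auc_with_ci(scores: Sequence[float], labels: Sequence[int]) -> AUCResult:
    """Pairwise AUC with DeLong standard error and a 95% CI clipped to [0,1]."""
    cases, controls = _split(scores, labels)
    v10, v01, auc = _placements(cases, controls)
    m, n = cases.size, controls.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - Z975 * se)
    hi = min(1.0, auc + Z975 * se)
    return AUCResult(auc=auc, se=se, ci_95=(lo, hi), n_cases=m, n_controls=n)


def compare_auc_paired(scores_a, scores_b, labels) -> AUCComparison:
    """DeLong test for two correlated AUCs measured on the same patients.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with variances and
    covariance from the placement values; two-sided normal p.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired comparison requires equal-length inputs")
    ca, qa = sa[y == 1], sa[y == 0]
    cb, qb = sb[y == 1], sb[y == 0]
    if ca.size == 0 or qa.size == 0:
        raise SingleClassError("both outcome classes must be present")
    v10a, v01a, auc_a = _placements(ca, qa)
    v10b, v01b, auc_b = _placements(cb, qb)
    m, n = ca.size, qa.size
    var_a = np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
    var_b = np.var(v10b, ddof=1) / m + np.var(v01b, ddof=1) / n
    cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
           + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
    delta = auc_a - auc_b
    var_delta = var_a + var_b - 2.0 * cov
    if var_delta <= 0 or delta == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = float(delta / np.sqrt(var_delta))
        p = float(2.0 * stats.norm.sf(abs(z)))
    corr = float(cov / np.sqrt(var_a * var_b)) if var_a > 0 and var_b > 0 else 0.0
    return AUCComparison(delta_auc=float(delta), z=z, p_two_sided=p,
                         mode="paired", correlation_estimate=corr)


def compare_auc_independent(result_a: AUCResult, result_b: AUCResult) -> AUCComparison:
    """z-test on two AUCs estimated from disjoint patient samples."""
    delta = result_a.auc - result_b.auc
    denom = np.sqrt(result_a.se**2 + result_b.se**2)
    if denom == 0:
        z = 0.0
        p = 1.0
    else:
        z = float(delta / denom)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AUCComparison(delta_auc=float(delta), z=z, p_two_sided=p,
                         mode="independent")


def score_distribution(item_probs: Sequence[float]) -> np.ndarray:
    """Exact distribution of the sum of independent Bernoulli items
    (Poisson-binomial), by dynamic programming over score states."""
    probs = np.asarray(item_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("item probabilities must lie in [0, 1]")
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def analytic_auc_from_item_probs(p_case: Sequence[float],
                                 p_control: Sequence[float]) -> float:
    """Exact AUC of the item-sum score under within-group item independence.

    AUC = P(S_case > S_control) + 0.5 P(S_case = S_control) with the two
    score distributions obtained by Bernoulli convolution.
    """
    dc = score_distribution(p_case)
    dn = score_distribution(p_control)
    k = max(dc.size, dn.size)
    dc = np.pad(dc, (0, k - dc.size))
    dn = np.pad(dn, (0, k - dn.size))
    cdf_n = np.cumsum(dn)
    auc = 0.0
    for s in range(k):
        below = cdf_n[s - 1] if s > 0 else 0.0
        auc += dc[s] * (below + 0.5 * dn[s])
    return float(auc)
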