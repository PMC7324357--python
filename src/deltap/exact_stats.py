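"""Statistical primitives for small clinical cohorts.

Self-contained implementations of the tests used throughout the cohort
analysis: Fisher's exact test (two-sided, probability-mass convention),
the Mann-Whitney U test (exact permutation distribution for small
untied samples, tie- and continuity-corrected normal approximation
otherwise), binary logistic regression by Newton-Raphson with Wald
intervals, exact order-statistic confidence intervals for the median, and
Kaplan-Meier estimation with the two-group log-rank test.

These are deliberately transparent implementations of textbook methods,
sized for cohorts of tens to hundreds of patients; the test-suite
cross-checks them against scipy, statsmodels and lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "MannWhitneyResult",
    "LogisticFit",
    "SurvivalSummary",
    "DegenerateTableError",
    "SeparationError",
    "ConvergenceError",
    "NoEventsError",
    "fisher_exact",
    "mann_whitney",
    "logistic_fit",
    "median_with_ci",
    "survival_compare",
]

Z975 = stats.norm.ppf(0.975)

# relative slack when comparing hypergeometric masses to the observed mass;
# guards against float round-off excluding tables of equal probability
FISHER_RELATIVE_SLACK = 1e-7


class DegenerateTableError(ValueError):
    """A 2x2 table with an empty margin; the test is undefined."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the score-norm tolerance."""


class NoEventsError(ValueError):
    """Log-rank requested but no events occurred in either group."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: row 1 = cases (exposed a / unexposed b), row 2 = controls
    (exposed c / unexposed d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_binary(cls, exposure: Sequence[int], outcome: Sequence[int]) -> "ContingencyTable":
        """Collapse paired 0/1 vectors: outcome=1 rows are cases."""
        e = np.asarray(exposure, dtype=int)
        o = np.asarray(outcome, dtype=int)
        if e.shape != o.shape:
            raise ValueError("exposure and outcome lengths differ")
        return cls(
            a=int(np.sum((o == 1) & (e == 1))),
            b=int(np.sum((o == 1) & (e == 0))),
            c=int(np.sum((o == 0) & (e == 1))),
            d=int(np.sum((o == 0) & (e == 0))),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _lchoose(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float
    or_ci_95: tuple
    zero_cell_corrected: bool = False


def fisher_exact(table: ContingencyTable) -> FisherResult:
    """Two-sided Fisher's exact test with Woolf odds-ratio interval.

    The two-sided p-value sums the hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's probability (with a small relative slack for float
    round-off) — the convention used by mainstream clinical software.

    Zero cells get the Haldane-Anscombe 0.5 correction for the odds ratio
    and its interval, flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise DegenerateTableError(f"degenerate table {table}: empty margin")

    n = table.total
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    # hypergeometric log-pmf over the whole support via gammaln; cheaper
    # and just as accurate as per-point scipy pmf calls
    log_pmf = (_lchoose(row1, support) + _lchoose(row2, col1 - support)
               - _lchoose(n, col1))
    pmf = np.exp(log_pmf)
    p_obs = float(pmf[support == a][0])
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_RELATIVE_SLACK)].sum())
    p = min(1.0, p)

    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    oratio = (aa * dd) / (bb * cc)
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (oratio * math.exp(-Z975 * se_log), oratio * math.exp(Z975 * se_log))
    return FisherResult(p_two_sided=p, odds_ratio=oratio, or_ci_95=ci,
                        zero_cell_corrected=corrected)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_sided: float
    method: str  # "exact" or "normal"


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for untied samples: counts of subsets of
    ranks 1..n1+n2 of size n1 by rank-sum, via the standard recursion."""
    max_u = n1 * n2
    # f[j, u] = number of ways to pick j of the first i ranks with U-value u
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for j in range(min(i, n1), 0, -1):
            # adding rank i as the j-th chosen element contributes (i - j) to U
            shift = i - j
            if shift > max_u:
                continue
            f[j, shift:] += f[j - 1, : max_u + 1 - shift]
    counts = f[n1]
    return counts / counts.sum()


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation distribution when n_x + n_y <= 20 and there are no
    ties; otherwise a normal approximation with tie correction and a 0.5
    continuity correction.  U is reported for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n1 + n2 <= 20 and not has_ties:
        dist = _exact_u_cdf(n1, n2)
        u_int = int(round(u))
        u_low = min(u_int, n1 * n2 - u_int)
        if 2 * u_low >= n1 * n2:
            p = 1.0
        else:
            # null distribution symmetric about n1*n2/2
            p = min(1.0, 2.0 * float(dist[: u_low + 1].sum()))
        return MannWhitneyResult(u=float(u), p_two_sided=p, method="exact")

    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        # all pooled values identical: no evidence of any difference
        return MannWhitneyResult(u=float(u), p_two_sided=1.0, method="normal")
    mean_u = n1 * n2 / 2.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return MannWhitneyResult(u=float(u), p_two_sided=min(1.0, p), method="normal")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood binary logistic regression summary.

    Wald 95% intervals on the odds-ratio scale (LCL/UCL), matching the
    standard clinical presentation.
    """

    names: tuple
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    or_lcl: np.ndarray
    or_ucl: np.ndarray
    p_values: np.ndarray
    n_events: np.ndarray
    converged: bool
    n_iterations: int
    n_obs: int
    log_likelihood: float

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "lcl": self.or_lcl,
                "ucl": self.or_ucl,
                "p_value": self.p_values,
                "n_events": self.n_events,
            },
            index=list(self.names),
        )


SCORE_TOL = 1e-8
MAX_NEWTON_ITER = 50
SEPARATION_COEF_BOUND = 30.0


def logistic_fit(X, y, names: Optional[Sequence[str]] = None,
                 add_intercept: bool = True) -> LogisticFit:
    """Fit a binary logistic regression by Newton-Raphson (IRLS).

    Converges when the score (gradient) norm drops below 1e-8, at most 50
    iterations.  Complete/quasi-complete separation is detected when a
    coefficient diverges or the weight matrix degenerates, and raised as a
    structured :class:`SeparationError` naming the worst covariate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_obs, k = X.shape
    if y.shape != (n_obs,):
        raise ValueError("outcome length does not match covariate rows")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be 0/1")
    if y.sum() == 0 or y.sum() == n_obs:
        raise ValueError("need at least one event and one non-event")
    if np.isnan(X).any():
        raise ValueError("missing covariate values are not allowed")

    if names is None:
        names = tuple(f"x{i}" for i in range(k))
    names = tuple(names)
    if len(names) != k:
        raise ValueError("names length does not match covariates")

    for j in range(k):
        if np.ptp(X[:, j]) == 0:
            raise SeparationError(f"covariate '{names[j]}' is constant; fit is degenerate")

    if add_intercept:
        Xd = np.column_stack([np.ones(n_obs), X])
        full_names = ("intercept",) + names
    else:
        Xd = X
        full_names = names

    beta = np.zeros(Xd.shape[1])
    trace = []
    for it in range(1, MAX_NEWTON_ITER + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = Xd.T @ (y - mu)
        score_norm = float(np.linalg.norm(score))
        trace.append(score_norm)
        if score_norm < SCORE_TOL:
            break
        H = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            worst = full_names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"singular information matrix; separation suspected on '{worst}'"
            ) from None
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_COEF_BOUND:
            worst = full_names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficient for '{worst}' diverged (|beta| > {SEPARATION_COEF_BOUND}); "
                "complete or quasi-complete separation"
            )
    else:
        raise ConvergenceError(
            f"no convergence in {MAX_NEWTON_ITER} iterations; score-norm trace: "
            + ", ".join(f"{s:.3g}" for s in trace[-5:])
        )

    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    n_events = np.concatenate([[y.sum()], X.sum(axis=0)]) if add_intercept else X.sum(axis=0)

    with np.errstate(over="ignore"):
        or_lcl = np.exp(beta - Z975 * se)
        or_ucl = np.exp(beta + Z975 * se)
    return LogisticFit(
        names=full_names,
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        or_lcl=or_lcl,
        or_ucl=or_ucl,
        p_values=pvals,
        n_events=np.asarray(n_events, dtype=float),
        converged=True,
        n_iterations=it,
        n_obs=n_obs,
        log_likelihood=ll,
    )


def median_with_ci(values: Sequence[float], level: float = 0.95):
    """Sample median with an exact binomial order-statistic interval.

    The interval is (x_(r), x_(s)) with r chosen as the largest symmetric
    rank pair whose binomial(n, 1/2) coverage is at least ``level``.  For
    n < 6 no such nondegenerate pair exists, so the whole sample range is
    returned with a warning flag.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 1:
        raise ValueError("need at least one value")
    med = float(np.median(v))
    if n < 6:
        return {"median": med, "ci_95": (float(v[0]), float(v[-1])),
                "exact_coverage": False,
                "warning": f"n={n} too small for a {level:.0%} order-statistic interval"}
    binom = stats.binom(n, 0.5)
    # largest r with P(r <= X <= n - r - 1) ... equivalently coverage
    # 1 - 2 P(X <= r - 1) >= level
    r = 0
    for cand in range(1, n // 2 + 1):
        if 1.0 - 2.0 * binom.cdf(cand - 1) >= level:
            r = cand
        else:
            break
    if r == 0:
        return {"median": med, "ci_95": (float(v[0]), float(v[-1])),
                "exact_coverage": False,
                "warning": "no interior interval achieves requested coverage"}
    return {"median": med, "ci_95": (float(v[r - 1]), float(v[n - r])),
            "exact_coverage": True, "warning": None}


@dataclass
class KaplanMeier:
    """Product-limit estimate for one group."""

    times: np.ndarray       # distinct event times
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalSummary:
    groups: dict            # name -> KaplanMeier
    medians: dict           # name -> median or None
    logrank_chi2: float
    logrank_p: float


def _km_fit(times: np.ndarray, events: np.ndarray) -> KaplanMeier:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    s = 1.0
    surv, at_risk, n_ev = [], [], []
    for t in distinct:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    surv_arr = np.asarray(surv)
    median = None
    crossed = np.nonzero(surv_arr <= 0.5)[0]
    if crossed.size:
        median = float(distinct[crossed[0]])
    return KaplanMeier(times=distinct, survival=surv_arr,
                       n_at_risk=np.asarray(at_risk), n_events=np.asarray(n_ev),
                       median=median)


def survival_compare(times_a, events_a, times_b, events_b,
                     names: tuple = ("A", "B")) -> SurvivalSummary:
    """Kaplan-Meier per group plus the two-group log-rank test.

    Median survival is the first time the KM curve reaches 0.5 or below;
    ``None`` when the curve never crosses.  Raises :class:`NoEventsError`
    when no events occurred anywhere (the log-rank statistic is undefined).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if np.any(ta < 0) or np.any(tb < 0):
        raise ValueError("survival times must be non-negative")
    if ea.sum() + eb.sum() == 0:
        raise NoEventsError("no events in either group; log-rank undefined")

    km_a = _km_fit(ta, ea)
    km_b = _km_fit(tb, eb)

    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        d1 = np.sum((ta == t) & (ea == 1))
        d2 = np.sum((tb == t) & (eb == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return SurvivalSummary(
        groups={names[0]: km_a, names[1]: km_b},
        medians={names[0]: km_a.median, names[1]: km_b.median},
        logrank_chi2=float(chi2),
        logrank_p=p,
    )
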