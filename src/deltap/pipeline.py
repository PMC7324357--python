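"""Cohort-level analysis pipeline.

Orchestrates the full validation analysis of the DELTA-P score on a
cohort of LEMS patients with known tumour status:

* a univariable clinical/demographic comparison between SCLC-LEMS and
  NT-LEMS (Fisher's exact test for binary variables, Mann-Whitney for
  numeric ones, log-rank for survival);
* a multivariable logistic regression on the six score items;
* the per-score SCLC risk table with Wilson intervals — the headline
  output used to stratify tumour screening;
* per-item diagnostic performance (correct/incorrect classification
  counts) and an item-versus-rest contrast;
* discrimination (AUC) of the 6-point score against the 5-point variant.

Patients whose score (or the variable under analysis) is undefined due
to missing items are excluded listwise per analysis and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import exact_stats as es
from . import roc
from .scoring import (Group, ITEM_NAMES, ScoreVariant, Sex, compute_deltap,
                      compute_dltap_variant, derive_items)

__all__ = [
    "UnivariableRow",
    "RiskTable",
    "ItemPerformanceRow",
    "univariable_summary",
    "multivariable_summary",
    "risk_table",
    "item_performance",
    "compare_items",
    "compare_score_variants",
    "subgroup_aucs",
    "cohort_scores",
]


def cohort_scores(cohort: Sequence, variant: ScoreVariant = ScoreVariant.DELTAP6) -> dict:
    """patient_id -> defined score (undefined scores omitted)."""
    out = {}
    for r in cohort:
        items = derive_items(r)
        res = compute_deltap(items) if variant is ScoreVariant.DELTAP6 \
            else compute_dltap_variant(items)
        score = res.deltap if variant is ScoreVariant.DELTAP6 else res.dltap
        if score is not None:
            out[r.patient_id] = score
    return out


def _item_matrix(cohort: Sequence):
    """(ids, items array with NaN for missing, sclc outcome array)."""
    ids, rows, y = [], [], []
    for r in cohort:
        if r.group is Group.UNKNOWN:
            continue
        iv = derive_items(r)
        ids.append(r.patient_id)
        rows.append([np.nan if v is None else float(v) for v in iv.as_tuple()])
        y.append(1 if r.group is Group.SCLC else 0)
    return ids, np.asarray(rows, dtype=float), np.asarray(y, dtype=int)


# ---------------------------------------------------------------------------
# Univariable table
# ---------------------------------------------------------------------------

@dataclass
class UnivariableRow:
    name: str
    kind: str                       # "binary" | "numeric" | "survival"
    sclc: Optional[str] = None      # rendered summary, e.g. "24/44 (55%)"
    nt: Optional[str] = None
    p_value: Optional[float] = None
    test: Optional[str] = None
    detail: dict = field(default_factory=dict)
    available: bool = True


def _fmt_frac(k: int, n: int) -> str:
    pct = round(100.0 * k / n) if n else 0
    return f"{k}/{n} ({pct}%)"


def _binary_row(name, sclc_pairs, nt_pairs) -> UnivariableRow:
    """pairs: list of 0/1 values (missing already dropped)."""
    k1, n1 = int(sum(sclc_pairs)), len(sclc_pairs)
    k0, n0 = int(sum(nt_pairs)), len(nt_pairs)
    if n1 == 0 and n0 == 0:
        return UnivariableRow(name=name, kind="binary", available=False)
    row = UnivariableRow(name=name, kind="binary",
                         sclc=_fmt_frac(k1, n1), nt=_fmt_frac(k0, n0),
                         test="fisher",
                         detail=dict(a=k1, b=n1 - k1, c=k0, d=n0 - k0,
                                     pct_sclc=100.0 * k1 / n1 if n1 else None,
                                     pct_nt=100.0 * k0 / n0 if n0 else None))
    try:
        res = es.fisher_exact(es.ContingencyTable(k1, n1 - k1, k0, n0 - k0))
        row.p_value = res.p_two_sided
        row.detail["odds_ratio"] = res.odds_ratio
    except (es.DegenerateTableError, ValueError) as exc:
        row.detail["test_error"] = str(exc)
    return row


def _numeric_row(name, sclc_vals, nt_vals) -> UnivariableRow:
    if not sclc_vals and not nt_vals:
        return UnivariableRow(name=name, kind="numeric", available=False)
    row = UnivariableRow(name=name, kind="numeric", test="mann-whitney")
    med1 = float(np.median(sclc_vals)) if sclc_vals else None
    med0 = float(np.median(nt_vals)) if nt_vals else None
    row.sclc = f"median {med1:g} (n={len(sclc_vals)})" if sclc_vals else "unavailable"
    row.nt = f"median {med0:g} (n={len(nt_vals)})" if nt_vals else "unavailable"
    row.detail = dict(median_sclc=med1, median_nt=med0,
                      n_sclc=len(sclc_vals), n_nt=len(nt_vals))
    if sclc_vals and nt_vals:
        mw = es.mann_whitney(sclc_vals, nt_vals)
        row.p_value = mw.p_two_sided
        row.detail["u"] = mw.u
        if len(sclc_vals) >= 1:
            row.detail["median_ci_sclc"] = es.median_with_ci(sclc_vals)["ci_95"]
        if len(nt_vals) >= 1:
            row.detail["median_ci_nt"] = es.median_with_ci(nt_vals)["ci_95"]
    return row


def univariable_summary(cohort: Sequence) -> list[UnivariableRow]:
    """Per-variable SCLC vs NT comparison in the published table's layout.

    The impotence item is reported both over all patients (females counted
    as unaffected) and restricted to males, as in the source table.
    """
    sclc = [r for r in cohort if r.group is Group.SCLC]
    nt = [r for r in cohort if r.group is Group.NT]
    if not sclc or not nt:
        raise ValueError("univariable summary needs at least one patient per group")

    def items_for(rs):
        return [derive_items(r) for r in rs]

    it1, it0 = items_for(sclc), items_for(nt)

    def binary(name, getter, g1=sclc, g0=nt, i1=it1, i0=it0):
        v1 = [v for v in (getter(r, i) for r, i in zip(g1, i1)) if v is not None]
        v0 = [v for v in (getter(r, i) for r, i in zip(g0, i0)) if v is not None]
        return _binary_row(name, v1, v0)

    rows = [
        _numeric_row("age_years",
                     [r.age_years for r in sclc if r.age_years is not None],
                     [r.age_years for r in nt if r.age_years is not None]),
        binary("aged_ge50", lambda r, i: i.a),
        binary("female", lambda r, i: 1 if r.sex is Sex.F else 0),
        binary("bulbar_weakness", lambda r, i: i.d),
        binary("impotence_all", lambda r, i: i.e),
        _binary_row("impotence_males",
                    [i.e for r, i in zip(sclc, it1) if r.sex is Sex.M and i.e is not None],
                    [i.e for r, i in zip(nt, it0) if r.sex is Sex.M and i.e is not None]),
        binary("weight_loss_ge5pct", lambda r, i: i.l),
        binary("smoking_at_onset", lambda r, i: i.t),
        binary("karnofsky_lt70", lambda r, i: i.p),
        # positivity is encoded by a recorded titre; absent titre = negative
        binary("vgcc_positive", lambda r, i: 1 if r.vgcc_titre_pM is not None else 0),
        _numeric_row("vgcc_titre_pM",
                     [r.vgcc_titre_pM for r in sclc if r.vgcc_titre_pM is not None],
                     [r.vgcc_titre_pM for r in nt if r.vgcc_titre_pM is not None]),
    ]

    # DELTA-P score medians with order-statistic CIs
    s1 = [v for v in cohort_scores(sclc).values()]
    s0 = [v for v in cohort_scores(nt).values()]
    rows.append(_numeric_row("deltap_score", s1, s0))

    # survival row (log-rank), only when survival data present
    surv1 = [(r.survival_months, r.death_event) for r in sclc
             if r.survival_months is not None and r.death_event is not None]
    surv0 = [(r.survival_months, r.death_event) for r in nt
             if r.survival_months is not None and r.death_event is not None]
    if surv1 and surv0:
        try:
            summ = es.survival_compare(
                [t for t, _ in surv1], [e for _, e in surv1],
                [t for t, _ in surv0], [e for _, e in surv0],
                names=("SCLC", "NT"))
            rows.append(UnivariableRow(
                name="median_survival_months", kind="survival",
                sclc=f"{summ.medians['SCLC']}", nt=f"{summ.medians['NT']}",
                p_value=summ.logrank_p, test="log-rank",
                detail=dict(chi2=summ.logrank_chi2, medians=summ.medians)))
        except es.NoEventsError as exc:
            rows.append(UnivariableRow(name="median_survival_months",
                                       kind="survival", available=False,
                                       detail=dict(test_error=str(exc))))
    else:
        rows.append(UnivariableRow(name="median_survival_months",
                                   kind="survival", available=False))
    return rows


# ---------------------------------------------------------------------------
# Multivariable logistic regression on the six items
# ---------------------------------------------------------------------------

@dataclass
class MultivariableReport:
    fit: es.LogisticFit
    n_included: int
    n_excluded: int
    covariates: tuple = ITEM_NAMES


def multivariable_summary(cohort: Sequence) -> MultivariableReport:
    """Logistic regression of SCLC status on the six DELTA-P items.

    Rows with any missing item are excluded listwise and counted; the fit
    itself is the Newton/Wald fit from :mod:`deltap.exact_stats`, so
    separation and non-convergence surface as structured errors.
    """
    _, X, y = _item_matrix(cohort)
    complete = ~np.isnan(X).any(axis=1)
    n_excl = int((~complete).sum())
    Xc, yc = X[complete], y[complete]
    if Xc.shape[0] == 0:
        raise ValueError("no patients with complete items")
    fit = es.logistic_fit(Xc, yc, names=ITEM_NAMES)
    return MultivariableReport(fit=fit, n_included=int(complete.sum()),
                               n_excluded=n_excl)


# ---------------------------------------------------------------------------
# Per-score risk table
# ---------------------------------------------------------------------------

@dataclass
class RiskTable:
    variant: ScoreVariant
    scores: tuple
    n_total: tuple
    n_sclc: tuple
    risk: tuple                  # None for empty strata
    ci_95: tuple                 # Wilson; None for empty strata
    frac_score_0_1: float
    frac_score_3_up: float
    n_included: int
    n_excluded: int

    def risk_pct(self, s: int) -> Optional[float]:
        r = self.risk[s]
        return None if r is None else 100.0 * r


def risk_table(cohort: Sequence, variant: ScoreVariant = ScoreVariant.DELTAP6) -> RiskTable:
    """Per-score SCLC risk: events / total at each score, Wilson 95% CIs.

    Empty strata yield an undefined (None) risk, never 0.  Also reports
    the fraction of scoreable patients in the low (0-1) and high (>= 3)
    strata used by the screening protocol.
    """
    max_score = 6 if variant is ScoreVariant.DELTAP6 else 5
    totals = np.zeros(max_score + 1, dtype=int)
    events = np.zeros(max_score + 1, dtype=int)
    n_excluded = 0
    for r in cohort:
        if r.group is Group.UNKNOWN:
            continue
        iv = derive_items(r)
        res = compute_deltap(iv) if variant is ScoreVariant.DELTAP6 \
            else compute_dltap_variant(iv)
        s = res.deltap if variant is ScoreVariant.DELTAP6 else res.dltap
        if s is None:
            n_excluded += 1
            continue
        totals[s] += 1
        if r.group is Group.SCLC:
            events[s] += 1
    n = int(totals.sum())
    risk, cis = [], []
    for s in range(max_score + 1):
        if totals[s] == 0:
            risk.append(None)
            cis.append(None)
        else:
            risk.append(events[s] / totals[s])
            lo, hi = proportion_confint(events[s], totals[s], alpha=0.05,
                                        method="wilson")
            cis.append((float(lo), float(hi)))
    return RiskTable(
        variant=variant,
        scores=tuple(range(max_score + 1)),
        n_total=tuple(int(v) for v in totals),
        n_sclc=tuple(int(v) for v in events),
        risk=tuple(risk),
        ci_95=tuple(cis),
        frac_score_0_1=float(totals[:2].sum() / n) if n else float("nan"),
        frac_score_3_up=float(totals[3:].sum() / n) if n else float("nan"),
        n_included=n,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Item performance (diagnostic accuracy of each item alone)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemPerformanceRow:
    """Classification bookkeeping for one item used alone as the test.

    A score of 1 is "correct" in an SCLC patient and "incorrect" in a
    no-cancer patient; a score of 0 is correct in no-cancer and incorrect
    in SCLC.  Percentages are of the per-item scoreable cohort.
    """

    item: str
    correct1_sclc: int
    correct0_nocancer: int
    incorrect0_sclc: int
    incorrect1_nocancer: int
    n: int

    @classmethod
    def from_counts(cls, item: str, correct1_sclc: int, correct0_nocancer: int,
                    incorrect0_sclc: int, incorrect1_nocancer: int) -> "ItemPerformanceRow":
        n = correct1_sclc + correct0_nocancer + incorrect0_sclc + incorrect1_nocancer
        return cls(item, correct1_sclc, correct0_nocancer,
                   incorrect0_sclc, incorrect1_nocancer, n)

    @property
    def total_correct(self) -> int:
        return self.correct1_sclc + self.correct0_nocancer

    @property
    def total_incorrect(self) -> int:
        return self.incorrect0_sclc + self.incorrect1_nocancer

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n if self.n else float("nan")

    @property
    def accuracy_pct(self) -> float:
        return self.pct(self.total_correct)


def item_performance(cohort: Sequence) -> dict:
    """Per-item correct/incorrect classification counts (item -> row)."""
    _, X, y = _item_matrix(cohort)
    rows = {}
    for j, name in enumerate(ITEM_NAMES):
        col = X[:, j]
        ok = ~np.isnan(col)
        c, yy = col[ok].astype(int), y[ok]
        rows[name] = ItemPerformanceRow.from_counts(
            name,
            correct1_sclc=int(np.sum((yy == 1) & (c == 1))),
            correct0_nocancer=int(np.sum((yy == 0) & (c == 0))),
            incorrect0_sclc=int(np.sum((yy == 1) & (c == 0))),
            incorrect1_nocancer=int(np.sum((yy == 0) & (c == 1))),
        )
    return rows


@dataclass(frozen=True)
class ItemContrast:
    item: str
    correct: int
    incorrect: int
    p_vs_others: float
    odds_ratio: float


def compare_items(rows: dict) -> dict:
    """Contrast each item's correct/incorrect totals against the pooled
    totals of the other five items (two-sided Fisher); the lowest-accuracy
    item is flagged.

    The contrast method is an interpretation: it uses only the per-item
    classification totals, tested item-versus-rest.
    """
    names = sorted(rows, key=lambda k: ITEM_NAMES.index(k))
    contrasts = {}
    for name in names:
        r = rows[name]
        oc = sum(rows[o].total_correct for o in names if o != name)
        oi = sum(rows[o].total_incorrect for o in names if o != name)
        fis = es.fisher_exact(es.ContingencyTable(r.total_correct, r.total_incorrect,
                                                  oc, oi))
        contrasts[name] = ItemContrast(item=name, correct=r.total_correct,
                                       incorrect=r.total_incorrect,
                                       p_vs_others=fis.p_two_sided,
                                       odds_ratio=fis.odds_ratio)
    worst = min(names, key=lambda k: rows[k].accuracy_pct)
    return {"contrasts": contrasts, "lowest_accuracy_item": worst}


# ---------------------------------------------------------------------------
# Discrimination: 6-point vs 5-point score, and subgroup AUCs
# ---------------------------------------------------------------------------

@dataclass
class VariantComparison:
    auc_deltap: roc.AUCResult
    auc_dltap: roc.AUCResult
    paired: roc.AUCComparison
    n: int


def _paired_scores(cohort: Sequence):
    s6, s5, y = [], [], []
    for r in cohort:
        if r.group is Group.UNKNOWN:
            continue
        res = compute_deltap(derive_items(r))
        if res.deltap is None or res.dltap is None:
            continue
        s6.append(res.deltap)
        s5.append(res.dltap)
        y.append(1 if r.group is Group.SCLC else 0)
    return np.array(s6), np.array(s5), np.array(y)


def compare_score_variants(cohort: Sequence) -> VariantComparison:
    """AUC of the 6-point score vs the 5-point variant on the same patients
    (DeLong paired comparison)."""
    s6, s5, y = _paired_scores(cohort)
    return VariantComparison(
        auc_deltap=roc.auc_with_ci(s6, y),
        auc_dltap=roc.auc_with_ci(s5, y),
        paired=roc.compare_auc_paired(s6, s5, y),
        n=int(y.size),
    )


def subgroup_aucs(cohort: Sequence, by: str = "sex") -> dict:
    """AUC of the 6-point score within disjoint subgroups (``sex`` or
    ``site``) plus the independent-samples comparison of the first two."""
    def key(r):
        return r.sex.value if by == "sex" else getattr(r, by)

    groups: dict = {}
    for r in cohort:
        if r.group is Group.UNKNOWN or key(r) is None:
            continue
        res = compute_deltap(derive_items(r))
        if res.deltap is None:
            continue
        groups.setdefault(key(r), ([], []))
        groups[key(r)][0].append(res.deltap)
        groups[key(r)][1].append(1 if r.group is Group.SCLC else 0)

    out = {"by": by, "auc": {}, "comparison": None, "errors": {}}
    for k, (s, y) in sorted(groups.items()):
        try:
            out["auc"][k] = roc.auc_with_ci(np.array(s), np.array(y))
        except roc.SingleClassError as exc:
            out["errors"][k] = str(exc)
    keys = list(out["auc"])
    if len(keys) >= 2:
        out["comparison"] = roc.compare_auc_independent(out["auc"][keys[0]],
                                                        out["auc"][keys[1]])
    return out
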