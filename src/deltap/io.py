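"""Cohort CSV I/O, validation, and the full report bundle.

The cohort file is a UTF-8 comma-separated table, one row per patient,
missing token ``NA``.  Required columns::

    patient_id, group, sex, age_years, bulbar_weakness,
    erectile_dysfunction, weight_loss_ge5pct, smoking_at_onset,
    karnofsky, vgcc_titre_pM, followup_months, tumour_detection_months,
    survival_months, death_event

Extra columns are preserved (``site`` is recognised); unknown ones are
warned about.  The reader rejects exactly the inputs that violate the
patient-record invariants, reporting every offending cell with its row
and column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import pipeline, screening
from .scoring import Group, PatientRecord, ScoreVariant, Sex, TriState

logger = logging.getLogger("deltap")

__all__ = ["REQUIRED_COLUMNS", "CohortValidationError", "read_cohort",
           "write_cohort", "run_validate", "report_to_json", "report_to_text"]

REQUIRED_COLUMNS = [
    "patient_id", "group", "sex", "age_years", "bulbar_weakness",
    "erectile_dysfunction", "weight_loss_ge5pct", "smoking_at_onset",
    "karnofsky", "vgcc_titre_pM", "followup_months",
    "tumour_detection_months", "survival_months", "death_event",
]
OPTIONAL_COLUMNS = ["karnofsky_lt70", "site"]
MISSING_TOKEN = "NA"


class CohortValidationError(ValueError):
    """Carries every offending cell as (row, column, message)."""

    def __init__(self, problems: list):
        self.problems = problems
        lines = "\n".join(f"  row {r}, column {c}: {m}" for r, c, m in problems)
        super().__init__(f"{len(problems)} validation problem(s):\n{lines}")


def _opt_float(value, row, col, problems, minimum=None):
    if pd.isna(value):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        problems.append((row, col, f"not a number: {value!r}"))
        return None
    if minimum is not None and v < minimum:
        problems.append((row, col, f"must be >= {minimum}, got {v}"))
    return v


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; all problems are reported at once."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False,
                     dtype=str)
    if df.empty:
        raise CohortValidationError([(0, "-", "no records in file")])
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(
            [(0, c, "required column missing") for c in missing_cols])
    unknown = [c for c in df.columns
               if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", ", ".join(unknown))

    problems: list = []
    records: list[PatientRecord] = []
    seen_ids: dict = {}
    for idx, raw in df.iterrows():
        rownum = idx + 2  # header is line 1
        pid = raw["patient_id"]
        if pd.isna(pid) or str(pid).strip() == "":
            problems.append((rownum, "patient_id", "empty patient id"))
            continue
        pid = str(pid)
        if pid in seen_ids:
            problems.append((rownum, "patient_id",
                             f"duplicate of row {seen_ids[pid]}"))
        seen_ids.setdefault(pid, rownum)

        try:
            group = Group(str(raw["group"]).upper()) if not pd.isna(raw["group"]) \
                else Group.UNKNOWN
        except ValueError:
            problems.append((rownum, "group", f"invalid group {raw['group']!r}"))
            continue
        try:
            sex = Sex(str(raw["sex"]).upper())
        except ValueError:
            problems.append((rownum, "sex", f"invalid sex {raw['sex']!r}"))
            continue

        tri = {}
        ok = True
        for col in ("bulbar_weakness", "erectile_dysfunction",
                    "weight_loss_ge5pct", "smoking_at_onset"):
            try:
                tri[col] = TriState.coerce(None if pd.isna(raw[col]) else raw[col])
            except ValueError as exc:
                problems.append((rownum, col, str(exc)))
                ok = False
        k70 = TriState.MISSING
        if "karnofsky_lt70" in df.columns and not pd.isna(raw.get("karnofsky_lt70")):
            try:
                k70 = TriState.coerce(raw["karnofsky_lt70"])
            except ValueError as exc:
                problems.append((rownum, "karnofsky_lt70", str(exc)))
                ok = False
        if not ok:
            continue

        age = _opt_float(raw["age_years"], rownum, "age_years", problems, minimum=0)
        karnofsky = _opt_float(raw["karnofsky"], rownum, "karnofsky", problems)
        death = _opt_float(raw["death_event"], rownum, "death_event", problems)
        rec = PatientRecord(
            patient_id=pid, group=group, sex=sex, age_years=age,
            bulbar_weakness=tri["bulbar_weakness"],
            erectile_dysfunction=tri["erectile_dysfunction"],
            weight_loss_ge5pct=tri["weight_loss_ge5pct"],
            smoking_at_onset=tri["smoking_at_onset"],
            karnofsky=None if karnofsky is None else int(karnofsky),
            karnofsky_lt70=k70,
            vgcc_titre_pM=_opt_float(raw["vgcc_titre_pM"], rownum,
                                     "vgcc_titre_pM", problems, minimum=0),
            followup_months=_opt_float(raw["followup_months"], rownum,
                                       "followup_months", problems, minimum=0),
            tumour_detection_months=_opt_float(raw["tumour_detection_months"],
                                               rownum, "tumour_detection_months",
                                               problems, minimum=0),
            survival_months=_opt_float(raw["survival_months"], rownum,
                                       "survival_months", problems, minimum=0),
            death_event=None if death is None else int(death),
            site=None if "site" not in df.columns or pd.isna(raw.get("site"))
            else str(raw["site"]),
        )
        for msg in rec.validate():
            problems.append((rownum, "-", msg))
        records.append(rec)

    if problems:
        raise CohortValidationError(problems)
    logger.info("read %d records from %s (%d SCLC, %d NT)", len(records), path,
                sum(r.group is Group.SCLC for r in records),
                sum(r.group is Group.NT for r in records))
    return records


def _cell(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, TriState):
        return MISSING_TOKEN if value is TriState.MISSING else value.value
    if isinstance(value, (Group, Sex)):
        return value.value
    return str(value)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records in the standard cohort CSV schema (round-trip safe)."""
    cols = REQUIRED_COLUMNS + ["site"]
    rows = []
    for r in records:
        rows.append({c: _cell(getattr(r, c)) for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Full report bundle
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (Group, Sex, TriState, ScoreVariant)):
        return obj.value
    if hasattr(obj, "value") and isinstance(obj, object) and obj.__class__.__module__.startswith("deltap"):
        try:
            return obj.value
        except Exception:
            pass
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


def run_validate(cohort: Sequence[PatientRecord], options: Optional[dict] = None) -> dict:
    """Run the complete validation analysis and return the report bundle.

    Sections mirror the published analysis: univariable table,
    multivariable logistic fit, per-score risk tables for both score
    variants, item performance with contrasts, 6- vs 5-point AUC
    comparison, subgroup AUCs, per-patient screening schedules and the
    tumour-detection summary.  Statistical failures in a section are
    recorded in the section (``error`` key) and flagged in the manifest,
    never swallowed.
    """
    options = dict(options or {})
    report: dict = {"sections": {}, "partial": False}

    def section(name, fn):
        try:
            report["sections"][name] = _jsonable(fn())
        except Exception as exc:  # surfaced, flagged, not swallowed
            report["sections"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            report["partial"] = True

    scores6 = pipeline.cohort_scores(cohort, ScoreVariant.DELTAP6)

    section("univariable", lambda: pipeline.univariable_summary(cohort))
    section("multivariable", lambda: _multivariable_section(cohort))
    section("risk_table_deltap6",
            lambda: pipeline.risk_table(cohort, ScoreVariant.DELTAP6))
    section("risk_table_dltap5",
            lambda: pipeline.risk_table(cohort, ScoreVariant.DLTAP5))
    section("item_performance", lambda: _item_section(cohort))
    section("auc_comparison", lambda: _auc_section(cohort))
    section("subgroup_auc_sex", lambda: pipeline.subgroup_aucs(cohort, by="sex"))
    if any(getattr(r, "site", None) for r in cohort):
        section("subgroup_auc_site", lambda: pipeline.subgroup_aucs(cohort, by="site"))
    section("screening", lambda: _screening_section(cohort, scores6, options))

    blob = json.dumps(_jsonable(options), sort_keys=True).encode()
    report["manifest"] = {
        "package": "deltap",
        "version": __version__,
        "n_patients": len(cohort),
        "options": _jsonable(options),
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": options.get("seed"),
        "versions": _library_versions(),
        "partial": report["partial"],
    }
    return report


def _library_versions() -> dict:
    import scipy
    import statsmodels

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__}


def _multivariable_section(cohort):
    rep = pipeline.multivariable_summary(cohort)
    frame = rep.fit.summary_frame()
    return {
        "n_included": rep.n_included,
        "n_excluded": rep.n_excluded,
        "converged": rep.fit.converged,
        "n_iterations": rep.fit.n_iterations,
        "rows": {name: {k: (None if v != v else float(v))
                        for k, v in frame.loc[name].items()}
                 for name in frame.index},
    }


def _item_section(cohort):
    rows = pipeline.item_performance(cohort)
    contrasts = pipeline.compare_items(rows)
    return {
        "rows": {k: {**asdict(v), "total_correct": v.total_correct,
                     "total_incorrect": v.total_incorrect,
                     "accuracy_pct": v.accuracy_pct} for k, v in rows.items()},
        "contrasts": contrasts,
    }


def _auc_section(cohort):
    cmp = pipeline.compare_score_variants(cohort)
    return {
        "deltap6": cmp.auc_deltap,
        "dltap5": cmp.auc_dltap,
        "paired": cmp.paired,
        "n": cmp.n,
    }


def _screening_section(cohort, scores6, options):
    semester = bool(options.get("high_on_semester_grid", False))
    schedules = {}
    for r in cohort:
        s = scores6.get(r.patient_id)
        if s is None:
            schedules[r.patient_id] = None
        else:
            sch = screening.schedule_for_score(s, high_on_semester_grid=semester)
            schedules[r.patient_id] = {"score": s,
                                       "stratum": sch.score_stratum.value,
                                       "scan_months": list(sch.scan_months)}
    det = screening.detection_summary(cohort, scores=scores6)
    return {"schedules": schedules, "detection": asdict(det)}


def report_to_json(report: dict, path=None, indent: int = 2) -> str:
    text = json.dumps(_jsonable(report), indent=indent, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def report_to_text(report: dict) -> str:
    """Aligned plain-text rendering, one block per analysis section.

    Percentages are rounded to integers as in the published tables; the
    JSON rendering keeps full precision.
    """
    lines = []
    sec = report["sections"]

    def fmt_p(p):
        if p is None:
            return "-"
        return "<0.0001" if p < 1e-4 else f"{p:.4g}"

    if "univariable" in sec and isinstance(sec["univariable"], list):
        lines.append("== Univariable comparison (SCLC vs NT) ==")
        for row in sec["univariable"]:
            if not row.get("available", True):
                lines.append(f"{row['name']:<28} unavailable")
                continue
            lines.append(f"{row['name']:<28} {str(row.get('sclc')):<22} "
                         f"{str(row.get('nt')):<22} P = {fmt_p(row.get('p_value'))}")
        lines.append("")
    mv = sec.get("multivariable", {})
    if "rows" in mv:
        lines.append(f"== Multivariable logistic regression (n = {mv['n_included']}) ==")
        lines.append(f"{'item':<6}{'events':>7}{'OR':>8}{'LCL':>8}{'UCL':>9}{'P':>10}")
        for name, r in mv["rows"].items():
            if name == "intercept":
                continue
            lines.append(f"{name:<6}{r['n_events']:>7.0f}{r['odds_ratio']:>8.3f}"
                         f"{r['lcl']:>8.3f}{r['ucl']:>9.3f}{fmt_p(r['p_value']):>10}")
        lines.append("")
    for key, label in (("risk_table_deltap6", "DELTA-P (0-6)"),
                       ("risk_table_dltap5", "DLTA-P (0-5)")):
        rt = sec.get(key, {})
        if "scores" in rt:
            lines.append(f"== SCLC risk by {label} score ==")
            for s, ntot, nev, risk in zip(rt["scores"], rt["n_total"],
                                          rt["n_sclc"], rt["risk"]):
                if risk is None:
                    lines.append(f"score {s}: 0 patients")
                else:
                    lines.append(f"score {s}: {nev}/{ntot} ({100 * risk:.1f}%)")
            lines.append("")
    auc = sec.get("auc_comparison", {})
    if "deltap6" in auc:
        a6, a5 = auc["deltap6"], auc["dltap5"]
        lines.append("== Discrimination ==")
        lines.append(f"DELTA-P AUC {100 * a6['auc']:.1f}% "
                     f"(95% CI {100 * a6['ci_95'][0]:.1f}% to {100 * a6['ci_95'][1]:.1f}%)")
        lines.append(f"DLTA-P  AUC {100 * a5['auc']:.1f}% "
                     f"(95% CI {100 * a5['ci_95'][0]:.1f}% to {100 * a5['ci_95'][1]:.1f}%)")
        lines.append(f"paired comparison P = {fmt_p(auc['paired']['p_two_sided'])}")
        lines.append("")
    det = sec.get("screening", {}).get("detection")
    if det and det.get("n_with_times"):
        lines.append("== Tumour detection timing (SCLC) ==")
        lines.append(f"within 6 months: {100 * det['frac_within_6mo']:.0f}%   "
                     f"within 12 months: {100 * det['frac_within_12mo']:.0f}%   "
                     f"median {det['median_detection_months']:g} months")
        lines.append("")
    man = report.get("manifest", {})
    lines.append(f"[manifest] deltap {man.get('version')} "
                 f"config {man.get('config_hash')} n={man.get('n_patients')}")
    return "\n".join(lines) + "\n"
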