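"""DELTA-P-stratified PET/CT tumour-surveillance schedules.

Every newly diagnosed LEMS patient is scanned at diagnosis (month 0).
Follow-up imaging depends on the DELTA-P stratum:

    LOW  (score 0-1): one repeat scan after six months.
    MID  (score 2):   every six months for two years.
    HIGH (score 3-6): repeat at three months, then every six months for
                      two years.

For the HIGH stratum "every six months" after the month-3 scan is read by
default as scans at 9, 15 and 21 months, ending at the 24-month horizon;
an alternative reading that returns to the 6/12/18/24 grid after the
month-3 scan is available via ``high_on_semester_grid=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from statistics import median
from typing import Optional, Sequence

__all__ = ["Stratum", "ScreeningSchedule", "schedule_for_score", "detection_summary"]


class Stratum(str, Enum):
    LOW = "LOW"    # scores 0-1
    MID = "MID"    # score 2
    HIGH = "HIGH"  # scores 3-6


@dataclass(frozen=True)
class ScreeningSchedule:
    score_stratum: Stratum
    scan_months: tuple
    horizon_months: int


_LOW = ScreeningSchedule(Stratum.LOW, (0, 6), 6)
_MID = ScreeningSchedule(Stratum.MID, (0, 6, 12, 18, 24), 24)
_HIGH = ScreeningSchedule(Stratum.HIGH, (0, 3, 9, 15, 21), 24)
_HIGH_SEMESTER = ScreeningSchedule(Stratum.HIGH, (0, 3, 6, 12, 18, 24), 24)


def stratum_for_score(score: int) -> Stratum:
    if not 0 <= score <= 6:
        raise ValueError(f"score {score} outside 0-6")
    if score <= 1:
        return Stratum.LOW
    if score == 2:
        return Stratum.MID
    return Stratum.HIGH


def schedule_for_score(score: int, high_on_semester_grid: bool = False) -> ScreeningSchedule:
    """Deterministic scan schedule for a DELTA-P score."""
    stratum = stratum_for_score(score)
    if stratum is Stratum.LOW:
        return _LOW
    if stratum is Stratum.MID:
        return _MID
    return _HIGH_SEMESTER if high_on_semester_grid else _HIGH


@dataclass
class DetectionSummary:
    n_sclc: int
    n_with_times: int
    frac_within_6mo: Optional[float]
    frac_within_12mo: Optional[float]
    median_detection_months: Optional[float]
    late_detections: list  # (patient_id, detection_months, score or None)
    warning: Optional[str] = None


def detection_summary(cohort: Sequence, scores: Optional[dict] = None) -> DetectionSummary:
    """Empirical tumour-detection timing over the SCLC patients of a cohort.

    ``scores`` optionally maps patient_id to a DELTA-P score so that
    late-detected outliers (> 6 months) can be reported with their scores.
    """
    from .scoring import Group

    sclc = [r for r in cohort if r.group is Group.SCLC]
    times = [(r.patient_id, r.tumour_detection_months)
             for r in sclc if r.tumour_detection_months is not None]
    if not sclc:
        return DetectionSummary(0, 0, None, None, None, [],
                                warning="no SCLC patients in cohort")
    if not times:
        return DetectionSummary(len(sclc), 0, None, None, None, [],
                                warning="no detection times recorded")
    values = [t for _, t in times]
    n = len(values)
    late = [(pid, t, scores.get(pid) if scores else None)
            for pid, t in times if t > 6.0]
    return DetectionSummary(
        n_sclc=len(sclc),
        n_with_times=n,
        frac_within_6mo=sum(t <= 6.0 for t in values) / n,
        frac_within_12mo=sum(t <= 12.0 for t in values) / n,
        median_detection_months=float(median(values)),
        late_detections=sorted(late, key=lambda x: x[1]),
    )
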