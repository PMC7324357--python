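"""DELTA-P clinical scoring for Lambert-Eaton myasthenic syndrome (LEMS).

The DELTA-P score sums six equally weighted binary clinical items assessed
within three months of symptom onset:

    D  bulbar/neck weakness
    E  erectile dysfunction (males only; females scored as not affected)
    L  weight loss >= 5%
    T  tobacco use at LEMS onset
    A  age at onset >= 50 years
    P  Karnofsky performance score < 70

Higher scores indicate a higher risk of an underlying small-cell lung
cancer (SCLC).  The 5-point DLTA-P variant drops item E, which performs
poorly in practice (onset timing of erectile dysfunction is hard to
establish in older men with comorbid illness).

This module owns the patient record type, the derivation of the six items
from raw clinical fields, and the score computations.  Missing items make
a score *undefined*; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Group",
    "Sex",
    "TriState",
    "ScoreVariant",
    "PatientRecord",
    "ItemVector",
    "ScoreResult",
    "ValidationError",
    "derive_items",
    "compute_deltap",
    "compute_dltap_variant",
    "ITEM_NAMES",
]

ITEM_NAMES = ("D", "E", "L", "T", "A", "P")

#: age-at-onset threshold for item A (inclusive)
AGE_THRESHOLD = 50.0
#: Karnofsky threshold for item P (strictly below)
KARNOFSKY_THRESHOLD = 70
#: minimum follow-up (months) required to classify a patient as non-tumour
NT_MIN_FOLLOWUP_MONTHS = 36.0


class Group(str, Enum):
    SCLC = "SCLC"
    NT = "NT"
    UNKNOWN = "UNKNOWN"


class Sex(str, Enum):
    M = "M"
    F = "F"


class TriState(str, Enum):
    YES = "yes"
    NO = "no"
    MISSING = "missing"

    @classmethod
    def coerce(cls, value) -> "TriState":
        """Accept TriState, bool, 0/1, yes/no strings, or None/'NA'."""
        if isinstance(value, cls):
            return value
        if value is None:
            return cls.MISSING
        if isinstance(value, bool):
            return cls.YES if value else cls.NO
        if isinstance(value, (int, float)):
            if value != value:  # NaN
                return cls.MISSING
            return cls.YES if value else cls.NO
        s = str(value).strip().lower()
        if s in {"yes", "y", "true", "1"}:
            return cls.YES
        if s in {"no", "n", "false", "0"}:
            return cls.NO
        if s in {"", "na", "nan", "missing", "none"}:
            return cls.MISSING
        raise ValueError(f"cannot interpret {value!r} as yes/no/missing")


class ScoreVariant(str, Enum):
    DELTAP6 = "DELTAP6"
    DLTAP5 = "DLTAP5"


class ValidationError(ValueError):
    """A patient record violates an invariant; the message names the patient."""


@dataclass
class PatientRecord:
    """One subject's clinical fields at LEMS diagnosis.

    Tri-state fields refer to the 0-3 month window from symptom onset; the
    data provider is responsible for applying that window.
    """

    patient_id: str
    group: Group = Group.UNKNOWN
    sex: Sex = Sex.F
    age_years: Optional[float] = None
    bulbar_weakness: TriState = TriState.MISSING
    erectile_dysfunction: TriState = TriState.MISSING
    weight_loss_ge5pct: TriState = TriState.MISSING
    smoking_at_onset: TriState = TriState.MISSING
    karnofsky: Optional[int] = None
    karnofsky_lt70: TriState = TriState.MISSING
    vgcc_titre_pM: Optional[float] = None
    followup_months: Optional[float] = None
    tumour_detection_months: Optional[float] = None
    survival_months: Optional[float] = None
    death_event: Optional[int] = None
    site: Optional[str] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sex = Sex(self.sex)
        self.bulbar_weakness = TriState.coerce(self.bulbar_weakness)
        self.erectile_dysfunction = TriState.coerce(self.erectile_dysfunction)
        self.weight_loss_ge5pct = TriState.coerce(self.weight_loss_ge5pct)
        self.smoking_at_onset = TriState.coerce(self.smoking_at_onset)
        self.karnofsky_lt70 = TriState.coerce(self.karnofsky_lt70)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean).

        Violations are flagged, never silently repaired or dropped.
        """
        problems: list[str] = []
        pid = self.patient_id
        if self.age_years is not None and self.age_years < 0:
            problems.append(f"{pid}: negative age {self.age_years}")
        if self.karnofsky is not None and not (0 <= self.karnofsky <= 100):
            problems.append(f"{pid}: Karnofsky {self.karnofsky} outside 0-100")
        if self.karnofsky is not None and self.karnofsky_lt70 is not TriState.MISSING:
            derived = TriState.YES if self.karnofsky < KARNOFSKY_THRESHOLD else TriState.NO
            if derived is not self.karnofsky_lt70:
                problems.append(
                    f"{pid}: karnofsky={self.karnofsky} contradicts "
                    f"karnofsky_lt70={self.karnofsky_lt70.value}"
                )
        if self.group is Group.NT:
            if self.followup_months is None:
                problems.append(f"{pid}: NT patient without follow-up duration")
            elif self.followup_months < NT_MIN_FOLLOWUP_MONTHS:
                problems.append(
                    f"{pid}: NT patient with follow-up {self.followup_months} "
                    f"< {NT_MIN_FOLLOWUP_MONTHS} months"
                )
        for name in ("vgcc_titre_pM", "followup_months", "tumour_detection_months",
                     "survival_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{pid}: negative {name} = {v}")
        if self.death_event is not None and self.death_event not in (0, 1):
            problems.append(f"{pid}: death_event must be 0 or 1")
        return problems


@dataclass(frozen=True)
class ItemVector:
    """The six DELTA-P items; each 0, 1, or None (missing).

    All six item symbols of the score live here; for females E is always 0
    by definition ("females scored as not affected"), never missing.
    """

    d: Optional[int]
    e: Optional[int]
    l: Optional[int]
    t: Optional[int]
    a: Optional[int]
    p: Optional[int]

    def as_tuple(self) -> tuple:
        return (self.d, self.e, self.l, self.t, self.a, self.p)

    def as_dict(self) -> dict:
        return dict(zip(ITEM_NAMES, self.as_tuple()))

    @property
    def n_missing(self) -> int:
        return sum(v is None for v in self.as_tuple())

    def missing_items(self) -> list[str]:
        return [n for n, v in zip(ITEM_NAMES, self.as_tuple()) if v is None]


@dataclass(frozen=True)
class ScoreResult:
    """A computed score; ``None`` when any contributing item is missing."""

    deltap: Optional[int]
    dltap: Optional[int]
    n_missing_items: int
    variant: ScoreVariant
    missing_items: tuple = field(default=())

    @property
    def defined(self) -> bool:
        primary = self.deltap if self.variant is ScoreVariant.DELTAP6 else self.dltap
        return primary is not None


def _tri_to_item(ts: TriState) -> Optional[int]:
    if ts is TriState.MISSING:
        return None
    return 1 if ts is TriState.YES else 0


def derive_items(record: PatientRecord) -> ItemVector:
    """Derive the six binary items from raw clinical fields.

    Thresholds follow the item definitions: A is inclusive (age >= 50),
    P is strict (Karnofsky < 70), L is inclusive (weight loss >= 5%, encoded
    upstream as a flag).  For females E is forced to 0.  Missing tri-state
    fields propagate to missing items; contradictory Karnofsky entries raise
    a :class:`ValidationError` naming the patient.
    """
    if record.age_years is None:
        raise ValidationError(f"{record.patient_id}: age required to derive item A")

    d = _tri_to_item(record.bulbar_weakness)
    if record.sex is Sex.F:
        e: Optional[int] = 0
    else:
        e = _tri_to_item(record.erectile_dysfunction)
    l = _tri_to_item(record.weight_loss_ge5pct)
    t = _tri_to_item(record.smoking_at_onset)
    a = 1 if record.age_years >= AGE_THRESHOLD else 0

    if record.karnofsky is not None:
        p: Optional[int] = 1 if record.karnofsky < KARNOFSKY_THRESHOLD else 0
        if record.karnofsky_lt70 is not TriState.MISSING:
            if p != _tri_to_item(record.karnofsky_lt70):
                raise ValidationError(
                    f"{record.patient_id}: karnofsky={record.karnofsky} contradicts "
                    f"karnofsky_lt70={record.karnofsky_lt70.value}"
                )
    else:
        p = _tri_to_item(record.karnofsky_lt70)

    return ItemVector(d=d, e=e, l=l, t=t, a=a, p=p)


def compute_deltap(items: ItemVector) -> ScoreResult:
    """Compute the 6-point DELTA-P score (and the 5-point variant alongside).

    Any missing item leaves the score undefined with the offending items
    listed; missing values are never treated as zero.
    """
    vals = items.as_tuple()
    missing = tuple(items.missing_items())
    if missing:
        # dltap may still be defined when only E is missing
        non_e = (items.d, items.l, items.t, items.a, items.p)
        dltap = sum(non_e) if all(v is not None for v in non_e) else None
        return ScoreResult(
            deltap=None, dltap=dltap, n_missing_items=len(missing),
            variant=ScoreVariant.DELTAP6, missing_items=missing,
        )
    total = sum(vals)
    return ScoreResult(
        deltap=total, dltap=total - items.e, n_missing_items=0,
        variant=ScoreVariant.DELTAP6,
    )


def compute_dltap_variant(items: ItemVector) -> ScoreResult:
    """Compute the 5-point DLTA-P score: item E excluded from the sum and
    from missingness accounting."""
    non_e = (items.d, items.l, items.t, items.a, items.p)
    missing = tuple(n for n in items.missing_items() if n != "E")
    if missing:
        return ScoreResult(
            deltap=None, dltap=None, n_missing_items=len(missing),
            variant=ScoreVariant.DLTAP5, missing_items=missing,
        )
    dltap = sum(non_e)
    deltap = dltap + items.e if items.e is not None else None
    return ScoreResult(
        deltap=deltap, dltap=dltap, n_missing_items=0,
        variant=ScoreVariant.DLTAP5,
    )


def score_patient(record: PatientRecord,
                  variant: ScoreVariant = ScoreVariant.DELTAP6) -> ScoreResult:
    """Convenience wrapper: derive items then score under the given variant."""
    items = derive_items(record)
    if variant is ScoreVariant.DELTAP6:
        return compute_deltap(items)
    return compute_dltap_variant(items)
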