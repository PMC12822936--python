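"""Typed clinical data model for diabetic foot ulcer validation studies.

One :class:`WoundRecord` captures the index-ulcer assessment of a single
patient — every predictor consumed by the four classification systems
(Meggitt–Wagner, University of Texas, SINBAD, Saint Elian) — and one
:class:`OutcomeRecord` captures the six-month amputation outcome and care
setting. A :class:`Cohort` pairs them.

Enum levels are closed sets with an explicit severity ordering (IntEnum),
so binary derivations such as "any ischemia" are simple threshold
comparisons. CSV tokens are the lower-snake-case member names; anything
else is rejected at parse time, never coerced.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "Depth",
    "GangreneExtent",
    "InfectionSeverity",
    "IschemiaGrade",
    "NeuropathyGrade",
    "EdemaGrade",
    "SiteRegion",
    "SeLocation",
    "SeTopography",
    "SeZones",
    "HealingPhase",
    "WoundRecord",
    "OutcomeRecord",
    "OutcomeGroup",
    "Cohort",
    "Violation",
    "validate_record",
    "outcome_group",
]


class _Token(enum.IntEnum):
    """IntEnum with lower-snake-case serialization tokens."""

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "_Token":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown {cls.__name__} token {token!r}; "
                f"expected one of {[m.token for m in cls]}"
            ) from None


class Depth(_Token):
    """Deepest tissue reached by the ulcer."""

    INTACT = 0
    SUPERFICIAL = 1
    TENDON_CAPSULE = 2
    BONE_JOINT = 3


class GangreneExtent(_Token):
    """Necrosis extent: localized (toes/forefoot) vs whole-foot."""

    NONE = 0
    LOCALIZED = 1
    EXTENSIVE = 2


class InfectionSeverity(_Token):
    """IDSA wound infection severity."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class IschemiaGrade(_Token):
    """Ischemia severity from arterial Doppler waveform assessment."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class NeuropathyGrade(_Token):
    """Sensory neuropathy: LOPS = loss of protective sensation."""

    NONE = 0
    DIMINISHED = 1
    LOPS = 2
    CHARCOT = 3


class EdemaGrade(_Token):
    NONE = 0
    PERILESIONAL = 1
    UNILATERAL = 2
    BILATERAL = 3


class SiteRegion(_Token):
    """Ulcer site along the foot axis (SINBAD site item)."""

    FOREFOOT = 0
    MIDFOOT = 1
    HINDFOOT = 2


class SeLocation(_Token):
    """Saint Elian anatomical location."""

    PHALANGEAL = 1
    METATARSAL = 2
    TARSAL = 3


class SeTopography(_Token):
    """Saint Elian topographic aspect of the wound."""

    DORSAL_OR_PLANTAR = 1
    LATERAL_OR_MEDIAL = 2
    TWO_OR_MORE = 3


class SeZones(_Token):
    """Number of affected foot regions (Saint Elian)."""

    ONE = 1
    TWO = 2
    WHOLE_FOOT = 3


class HealingPhase(_Token):
    EPITHELIALIZATION = 1
    GRANULATION = 2
    INFLAMMATORY = 3


#: CSV/field order shared by the readers and writers in :mod:`dfuvalid.pipeline`.
ENUM_FIELDS: dict[str, type[_Token]] = {
    "depth": Depth,
    "gangrene": GangreneExtent,
    "infection_idsa": InfectionSeverity,
    "ischemia_grade": IschemiaGrade,
    "neuropathy_grade": NeuropathyGrade,
    "edema_grade": EdemaGrade,
    "site_region": SiteRegion,
    "se_location": SeLocation,
    "se_topography": SeTopography,
    "se_zones": SeZones,
    "healing_phase": HealingPhase,
}


@dataclass(frozen=True)
class WoundRecord:
    """One patient's index-ulcer assessment (single limb, single ulcer)."""

    patient_id: str
    depth: Depth
    osteomyelitis_or_abscess: bool
    gangrene: GangreneExtent
    infection_idsa: InfectionSeverity
    ischemia_grade: IschemiaGrade
    neuropathy_grade: NeuropathyGrade
    edema_grade: EdemaGrade
    site_region: SiteRegion
    se_location: SeLocation
    se_topography: SeTopography
    se_zones: SeZones
    area_cm2: float
    healing_phase: HealingPhase
    covariates: Mapping[str, str] = field(default_factory=dict, compare=False)

    # Binary derivations shared by UT and SINBAD (graded fields serve Saint Elian).
    @property
    def has_infection(self) -> bool:
        return self.infection_idsa >= InfectionSeverity.MILD

    @property
    def has_ischemia(self) -> bool:
        return self.ischemia_grade >= IschemiaGrade.MILD

    @property
    def has_neuropathy(self) -> bool:
        return self.neuropathy_grade >= NeuropathyGrade.DIMINISHED


@dataclass(frozen=True)
class OutcomeRecord:
    """Six-month outcome: amputation status and care setting.

    A major amputation is any amputation above the ankle, ipsilateral to the
    index ulcer. Minor (toe/transmetatarsal) amputations belong to the
    "no major amputation" group in the primary analysis.
    """

    major_amputation: bool
    minor_amputation: bool
    inpatient: bool
    follow_up_months: float


class OutcomeGroup(enum.Enum):
    """Disjoint outcome groups: major > minor > none."""

    MAJOR = "major"
    MINOR = "minor"
    NONE = "none"


def outcome_group(outcome: OutcomeRecord) -> OutcomeGroup:
    """Assign an outcome to exactly one of the three disjoint groups."""
    if outcome.major_amputation:
        return OutcomeGroup.MAJOR
    if outcome.minor_amputation:
        return OutcomeGroup.MINOR
    return OutcomeGroup.NONE


@dataclass(frozen=True)
class Violation:
    """One invariant violation; data, never an exception."""

    field: str
    rule: str
    message: str


#: Minimum follow-up (months) for cohort eligibility.
MIN_FOLLOW_UP_MONTHS = 6.0


def validate_record(wound: WoundRecord, outcome: OutcomeRecord) -> list[Violation]:
    """Check a wound/outcome pair against the data-model invariants.

    Returns an empty list iff every invariant holds; each violation names the
    offending field and the rule. Idempotent and side-effect free.
    """
    violations: list[Violation] = []

    if not wound.patient_id:
        violations.append(
            Violation("patient_id", "nonempty", "patient_id must be a nonempty string")
        )

    for name, enum_cls in ENUM_FIELDS.items():
        value = getattr(wound, name)
        if not isinstance(value, enum_cls):
            violations.append(
                Violation(name, "closed_enum", f"{name} must be a {enum_cls.__name__} level")
            )

    if not isinstance(wound.area_cm2, (int, float)) or wound.area_cm2 != wound.area_cm2:
        violations.append(Violation("area_cm2", "numeric", "area_cm2 must be a real number"))
    elif wound.area_cm2 < 0:
        violations.append(
            Violation("area_cm2", "nonnegative", f"area_cm2 = {wound.area_cm2} is negative")
        )
    elif wound.area_cm2 == 0 and wound.depth is not Depth.INTACT:
        violations.append(
            Violation(
                "area_cm2",
                "zero_area_requires_intact_skin",
                "area_cm2 = 0 is only permitted when depth is intact",
            )
        )

    if outcome.follow_up_months < 0:
        violations.append(
            Violation("follow_up_months", "nonnegative", "follow-up must be nonnegative")
        )
    elif outcome.follow_up_months < MIN_FOLLOW_UP_MONTHS:
        violations.append(
            Violation(
                "follow_up_months",
                "min_follow_up",
                f"eligibility requires at least {MIN_FOLLOW_UP_MONTHS:g} months of "
                f"follow-up, got {outcome.follow_up_months:g}",
            )
        )

    return violations


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of (wound, outcome) pairs with provenance.

    Construction enforces uniqueness of patient identifiers and a minimum
    size of one; per-record invariants are checked by :func:`validate_record`
    (violations are data, so imperfect records can still be carried).
    """

    records: tuple[tuple[WoundRecord, OutcomeRecord], ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 1:
            raise ValueError("a cohort must contain at least one record")
        ids = [w.patient_id for w, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s) in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[WoundRecord, OutcomeRecord]]:
        return iter(self.records)

    @property
    def wounds(self) -> tuple[WoundRecord, ...]:
        return tuple(w for w, _ in self.records)

    @property
    def outcomes(self) -> tuple[OutcomeRecord, ...]:
        return tuple(o for _, o in self.records)

    def group_counts(self) -> dict[OutcomeGroup, int]:
        """Sizes of the three disjoint outcome groups (they sum to len(self))."""
        counts = {g: 0 for g in OutcomeGroup}
        for _, outcome in self.records:
            counts[outcome_group(outcome)] += 1
        return counts
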