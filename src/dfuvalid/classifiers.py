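"""The four diabetic foot ulcer classification systems.

Deterministic, total functions on valid :class:`~dfuvalid.model.WoundRecord`
objects:

* :func:`mw_grade` — Meggitt–Wagner grade 0–5 (depth/necrosis ladder,
  most-severe-wins precedence).
* :func:`ut_classify` — University of Texas grade 0–3 (depth) x stage A–D
  (infection/ischemia grid), 16 combinations.
* :func:`sinbad_score` — SINBAD 0–6: one point per adverse binary item
  (Site, Ischemia, Neuropathy, Bacterial infection, Area, Depth).
* :func:`saint_elian` — Saint Elian 6–30 points across ten items in three
  domains (anatomical, aggravating, contributing), banded as
  mild (<=10) / moderate (11–20) / severe (21–30).

:func:`collapse_risk_category` reproduces the sparse-category collapses used
in the validation analysis (Wagner 1–3 vs 4–5, UT "3D" vs other, SINBAD
1–4/5/6, Saint Elian <16 / 16–20 / >20), and :data:`SCORE_VARIANTS` exposes
the seven ordinal score readouts whose ROC curves the analysis compares.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping

from .model import (
    Depth,
    GangreneExtent,
    HealingPhase,
    WoundRecord,
)

__all__ = [
    "UtStage",
    "UtClass",
    "SinbadResult",
    "SeSeverity",
    "SaintElianResult",
    "System",
    "mw_grade",
    "ut_classify",
    "sinbad_score",
    "saint_elian",
    "collapse_risk_category",
    "risk_bands",
    "SCORE_VARIANTS",
]


# ---------------------------------------------------------------------------
# Meggitt–Wagner
# ---------------------------------------------------------------------------

def mw_grade(wound: WoundRecord) -> int:
    """Meggitt–Wagner grade 0–5.

    Ladder (highest applicable grade wins): 5 extensive gangrene involving
    the whole foot; 4 localized gangrene; 3 deep ulcer with osteomyelitis or
    abscess; 2 ulcer reaching tendon or joint capsule; 1 superficial ulcer;
    0 intact skin.
    """
    if wound.gangrene is GangreneExtent.EXTENSIVE:
        return 5
    if wound.gangrene is GangreneExtent.LOCALIZED:
        return 4
    if wound.osteomyelitis_or_abscess:
        return 3
    if wound.depth in (Depth.TENDON_CAPSULE, Depth.BONE_JOINT):
        return 2
    if wound.depth is Depth.SUPERFICIAL:
        return 1
    return 0


# ---------------------------------------------------------------------------
# University of Texas
# ---------------------------------------------------------------------------

class UtStage(enum.Enum):
    """UT stage: A neither, B infection, C ischemia, D both."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"


@dataclass(frozen=True)
class UtClass:
    """One of the 16 University of Texas (grade, stage) combinations."""

    grade: int  # 0–3, the depth axis
    stage: UtStage

    @property
    def is_3d(self) -> bool:
        return self.grade == 3 and self.stage is UtStage.D

    def __str__(self) -> str:
        return f"{self.grade}{self.stage.value}"


_UT_DEPTH_GRADE = {
    Depth.INTACT: 0,
    Depth.SUPERFICIAL: 1,
    Depth.TENDON_CAPSULE: 2,
    Depth.BONE_JOINT: 3,
}


def ut_classify(wound: WoundRecord) -> UtClass:
    """University of Texas classification: depth grade 0–3, stage A–D."""
    infection = wound.has_infection
    ischemia = wound.has_ischemia
    if infection and ischemia:
        stage = UtStage.D
    elif ischemia:
        stage = UtStage.C
    elif infection:
        stage = UtStage.B
    else:
        stage = UtStage.A
    return UtClass(grade=_UT_DEPTH_GRADE[wound.depth], stage=stage)


# ---------------------------------------------------------------------------
# SINBAD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinbadResult:
    """SINBAD total with the six per-item indicators."""

    site: bool  # midfoot/hindfoot
    ischemia: bool
    neuropathy: bool
    infection: bool
    area: bool  # area >= 1 cm^2
    depth: bool  # involving tendon/muscle/bone

    @property
    def total(self) -> int:
        return sum(
            (self.site, self.ischemia, self.neuropathy, self.infection, self.area, self.depth)
        )


def sinbad_score(wound: WoundRecord) -> SinbadResult:
    """SINBAD score: one point per adverse item, total 0–6.

    Adverse items: site midfoot/hindfoot; ischemia present; neuropathy
    present; bacterial infection present; area >= 1 cm^2; depth beyond
    superficial (tendon/capsule or bone/joint).
    """
    return SinbadResult(
        site=wound.site_region.value >= 1,
        ischemia=wound.has_ischemia,
        neuropathy=wound.has_neuropathy,
        infection=wound.has_infection,
        area=wound.area_cm2 >= 1.0,
        depth=wound.depth in (Depth.TENDON_CAPSULE, Depth.BONE_JOINT),
    )


# ---------------------------------------------------------------------------
# Saint Elian
# ---------------------------------------------------------------------------

class SeSeverity(enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class SaintElianResult:
    """Saint Elian total (6–30), the ten per-item points, and severity band."""

    per_item: Mapping[str, int]
    total: int
    severity: SeSeverity


# Contributing-domain depth bucket: superficial -> 1, below dermis -> 2,
# full-thickness -> 3. Intact skin is scored with the superficial bucket.
_SE_DEPTH_POINTS = {
    Depth.INTACT: 1,
    Depth.SUPERFICIAL: 1,
    Depth.TENDON_CAPSULE: 2,
    Depth.BONE_JOINT: 3,
}


def _se_area_points(area_cm2: float) -> int:
    if area_cm2 < 10.0:
        return 1
    if area_cm2 <= 40.0:
        return 2
    return 3


def _se_severity(total: int) -> SeSeverity:
    # Published bands are mild <10, moderate 11-20, severe 21-30, leaving 10
    # unassigned; a total of exactly 10 is banded mild for contiguity.
    if total <= 10:
        return SeSeverity.MILD
    if total <= 20:
        return SeSeverity.MODERATE
    return SeSeverity.SEVERE


def saint_elian(wound: WoundRecord) -> SaintElianResult:
    """Saint Elian score across ten items in three domains.

    Anatomical items (location, topography, affected zones) and contributing
    items (depth, area <10 / 10–40 / >40 cm^2, healing phase) score 1–3;
    aggravating items (ischemia, infection, edema, neuropathy) score 0–3 by
    severity level. Total ranges 6–30; severity bands mild (<=10),
    moderate (11–20), severe (21–30).
    """
    per_item = {
        # anatomical (1-3)
        "location": wound.se_location.value,
        "topography": wound.se_topography.value,
        "zones": wound.se_zones.value,
        # aggravating (0-3)
        "ischemia": wound.ischemia_grade.value,
        "infection": wound.infection_idsa.value,
        "edema": wound.edema_grade.value,
        "neuropathy": wound.neuropathy_grade.value,
        # contributing (1-3)
        "depth": _SE_DEPTH_POINTS[wound.depth],
        "area": _se_area_points(wound.area_cm2),
        "healing_phase": wound.healing_phase.value
        if isinstance(wound.healing_phase, HealingPhase)
        else int(wound.healing_phase),
    }
    total = sum(per_item.values())
    return SaintElianResult(per_item=per_item, total=total, severity=_se_severity(total))


# ---------------------------------------------------------------------------
# Risk-category collapses (sparse categories merged as in the analysis)
# ---------------------------------------------------------------------------

class System(enum.Enum):
    """The four classification systems."""

    MW = "mw"
    UT = "ut"
    SINBAD = "sinbad"
    SE = "se"


_BANDS: dict[System, tuple[str, ...]] = {
    System.MW: ("1-3", "4-5"),
    System.UT: ("other", "3D"),
    System.SINBAD: ("1-4", "5", "6"),
    System.SE: ("<16", "16-20", ">20"),
}


def risk_bands(system: System) -> tuple[str, ...]:
    """Ordered band labels for a system, lowest theoretical risk first."""
    return _BANDS[system]


def collapse_risk_category(system: System, score_or_class) -> str:
    """Collapse a classifier output into the analysis risk band.

    Wagner grades 0–3 merge into "1-3" (no events occurred below grade 3)
    and 4–5 into "4-5"; UT collapses to "3D" vs "other"; SINBAD keeps 5 and
    6 separate above a merged "1-4"; Saint Elian uses <16 / 16–20 / >20.
    Band order reflects theoretical risk, lowest band first.
    """
    if system is System.MW:
        grade = int(score_or_class)
        if not 0 <= grade <= 5:
            raise ValueError(f"Wagner grade out of range: {grade}")
        return "4-5" if grade >= 4 else "1-3"
    if system is System.UT:
        if not isinstance(score_or_class, UtClass):
            raise TypeError("UT collapse expects a UtClass")
        return "3D" if score_or_class.is_3d else "other"
    if system is System.SINBAD:
        total = score_or_class.total if isinstance(score_or_class, SinbadResult) else int(score_or_class)
        if not 0 <= total <= 6:
            raise ValueError(f"SINBAD total out of range: {total}")
        if total >= 6:
            return "6"
        if total == 5:
            return "5"
        return "1-4"
    if system is System.SE:
        total = score_or_class.total if isinstance(score_or_class, SaintElianResult) else int(score_or_class)
        if not 6 <= total <= 30:
            raise ValueError(f"Saint Elian total out of range: {total}")
        if total > 20:
            return ">20"
        if total >= 16:
            return "16-20"
        return "<16"
    raise ValueError(f"unknown system: {system!r}")


# ---------------------------------------------------------------------------
# Ordinal score readouts for ROC analysis
# ---------------------------------------------------------------------------

#: The seven score variants analysed as ROC curves: the four system scores
#: plus the three University of Texas components. UT is never treated as a
#: single 16-level ordinal; its depth grade, binary infection, binary
#: ischemia and the 3D-vs-other indicator are separate curves. Higher score
#: always means higher theoretical amputation risk.
SCORE_VARIANTS: dict[str, Callable[[WoundRecord], float]] = {
    "se": lambda w: float(saint_elian(w).total),
    "mw": lambda w: float(mw_grade(w)),
    "sinbad": lambda w: float(sinbad_score(w).total),
    "ut_3d": lambda w: float(ut_classify(w).is_3d),
    "ut_depth": lambda w: float(ut_classify(w).grade),
    "ut_ischemia": lambda w: float(w.has_ischemia),
    "ut_infection": lambda w: float(w.has_infection),
}
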