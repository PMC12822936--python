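"""Synthetic diabetic-foot cohorts with a shared latent severity.

The generator emulates the statistical structure a validation analysis
assumes: a single latent severity per patient drives both the amputation
outcome (logistic link, intercept root-found to the target incidence) and
every wound item (ordered-threshold model on latent + item noise). Because
all items share one latent, the four system scores are positively
correlated — the condition that makes paired DeLong comparisons meaningful
— while per-item noise lets each system's discrimination be tuned
separately.

Defaults mirror the reference validation cohort: n = 342, six-month
major-amputation incidence 11.4%, 31.9% inpatients containing every event
(so the outpatient stratum is incalculable), and target AUROCs of 0.900
(Saint Elian), 0.805 (Meggitt–Wagner), 0.802 (UT depth), 0.747 (SINBAD),
0.655 (UT ischemia) and 0.650 (UT infection). Noise scales are calibrated
by bisection against a large pilot sample with common random numbers, so
the calibration is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .classifiers import SCORE_VARIANTS
from .model import (
    Cohort,
    Depth,
    EdemaGrade,
    GangreneExtent,
    HealingPhase,
    InfectionSeverity,
    IschemiaGrade,
    NeuropathyGrade,
    OutcomeRecord,
    SeLocation,
    SeTopography,
    SeZones,
    SiteRegion,
    WoundRecord,
)
from .stats import roc_auc

__all__ = [
    "SimulationConfig",
    "CalibrationError",
    "calibrate_noise",
    "generate_cohort",
    "fixture_small",
    "DEFAULT_TARGET_AUC",
]


class CalibrationError(ValueError):
    """A target AUC is unattainable for the latent model's noise floor/ceiling."""


#: Population AUROC targets per score variant (the generator's study conditions).
DEFAULT_TARGET_AUC: Mapping[str, float] = MappingProxyType(
    {
        "se": 0.900,
        "mw": 0.805,
        "sinbad": 0.747,
        "ut_depth": 0.802,
        "ut_ischemia": 0.655,
        "ut_infection": 0.650,
    }
)

# Marginal level probabilities per wound item, ordered by ascending severity.
# Depth, ischemia, IDSA infection, site and the area bands follow the study
# cohort's printed marginals; the remainder are fixed plausible values for a
# referral-hospital diabetic foot population.
_MARGINALS: Mapping[str, tuple[float, ...]] = MappingProxyType(
    {
        "depth": (0.366, 0.169, 0.465),  # superficial / tendon-capsule / bone-joint
        "osteomyelitis_or_abscess": (0.75, 0.25),
        "gangrene": (0.567, 0.410, 0.023),
        "infection_idsa": (0.267, 0.301, 0.359, 0.073),
        "ischemia_grade": (0.403, 0.250, 0.250, 0.097),
        "neuropathy_grade": (0.25, 0.35, 0.30, 0.10),
        "edema_grade": (0.40, 0.30, 0.20, 0.10),
        "site_region": (0.743, 0.150, 0.107),
        "se_location": (0.45, 0.35, 0.20),
        "se_topography": (0.40, 0.35, 0.25),
        "se_zones": (0.50, 0.35, 0.15),
        "healing_phase": (0.20, 0.45, 0.35),
    }
)

# Log-area model: ln(area) = 2.53 + 1.80 * u matches the cohort's extension
# bands (<10 / 10-40 / >40 cm^2 at roughly 45/28/26%).
_AREA_MU, _AREA_SIGMA = 2.53, 1.80

_ALL_ITEMS = tuple(_MARGINALS) + ("area_cm2",)

# Noise-calibration groups: each group shares one noise scale and is tuned
# to one score variant's target AUC, in dependency order (later groups see
# the earlier groups' calibrated values).
_CALIBRATION_PLAN: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("ut_depth", ("depth",), "ut_depth"),
    ("ut_ischemia", ("ischemia_grade",), "ut_ischemia"),
    ("ut_infection", ("infection_idsa",), "ut_infection"),
    ("mw", ("gangrene", "osteomyelitis_or_abscess"), "mw"),
    ("sinbad", ("site_region", "neuropathy_grade", "area_cm2"), "sinbad"),
    ("se", ("se_location", "se_topography", "se_zones", "edema_grade", "healing_phase"), "se"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``latent_slope`` is the logistic slope of the outcome on the latent
    severity; 4.5 puts the latent AUROC near 0.96, above the highest target
    so every score can be degraded to its target by noise (the discrete
    depth score's ceiling is intrinsically capped near 0.80 by its level
    structure, within the calibration tolerance of its target).
    ``latent_noise`` maps wound items to noise standard deviations (latent
    scale); when None it is calibrated from ``target_auc`` at generation
    time.
    """

    n_patients: int = 342
    target_incidence: float = 0.114
    inpatient_fraction: float = 0.319
    events_inpatient_only: bool = True
    minor_fraction: float = 0.251  # of non-major patients
    target_auc: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_AUC))
    latent_noise: Optional[Mapping[str, float]] = None
    latent_slope: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be at least 20")
        for name in ("target_incidence", "inpatient_fraction", "minor_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for key, auc in self.target_auc.items():
            if not 0.5 < auc < 1.0:
                raise ValueError(f"target_auc[{key!r}] must lie in (0.5, 1), got {auc}")
        if self.latent_noise is not None:
            bad = [k for k, v in self.latent_noise.items() if v <= 0]
            if bad:
                raise ValueError(f"latent_noise must be positive, offending items: {bad}")


def _outcome_intercept(slope: float, incidence: float) -> float:
    """Root-find the logistic intercept so E[expit(a + slope*Z)] = incidence."""
    grid = ndtri((np.arange(4001) + 0.5) / 4001)

    def mean_risk(a: float) -> float:
        return float(expit(a + slope * grid).mean()) - incidence

    return brentq(mean_risk, -40.0, 10.0, xtol=1e-10)


def _categorize(u: np.ndarray, probs: tuple[float, ...]) -> np.ndarray:
    """Ordered-threshold model: level = #cutpoints below u (0-based)."""
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    cuts = ndtri(np.cumsum(p)[:-1])
    return (u[:, None] > cuts[None, :]).sum(axis=1)


def _draw_item_latents(
    z: np.ndarray, eps: Mapping[str, np.ndarray], noise: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Standardized per-item latents u = (z + sigma*eps) / sqrt(1 + sigma^2)."""
    out = {}
    for item in _ALL_ITEMS:
        sigma = float(noise[item])
        out[item] = (z + sigma * eps[item]) / math.sqrt(1.0 + sigma * sigma)
    return out


_DEPTH_LEVELS = (Depth.SUPERFICIAL, Depth.TENDON_CAPSULE, Depth.BONE_JOINT)


def _build_records(
    u: Mapping[str, np.ndarray], id_prefix: str = "SYN"
) -> list[WoundRecord]:
    codes = {item: _categorize(u[item], _MARGINALS[item]) for item in _MARGINALS}
    area = np.exp(_AREA_MU + _AREA_SIGMA * u["area_cm2"])
    n = area.size
    records = []
    for i in range(n):
        records.append(
            WoundRecord(
                patient_id=f"{id_prefix}-{i + 1:05d}",
                depth=_DEPTH_LEVELS[codes["depth"][i]],
                osteomyelitis_or_abscess=bool(codes["osteomyelitis_or_abscess"][i]),
                gangrene=GangreneExtent(int(codes["gangrene"][i])),
                infection_idsa=InfectionSeverity(int(codes["infection_idsa"][i])),
                ischemia_grade=IschemiaGrade(int(codes["ischemia_grade"][i])),
                neuropathy_grade=NeuropathyGrade(int(codes["neuropathy_grade"][i])),
                edema_grade=EdemaGrade(int(codes["edema_grade"][i])),
                site_region=SiteRegion(int(codes["site_region"][i])),
                se_location=SeLocation(int(codes["se_location"][i]) + 1),
                se_topography=SeTopography(int(codes["se_topography"][i]) + 1),
                se_zones=SeZones(int(codes["se_zones"][i]) + 1),
                area_cm2=float(area[i]),
                healing_phase=HealingPhase(int(codes["healing_phase"][i]) + 1),
            )
        )
    return records


def calibrate_noise(
    config: SimulationConfig,
    pilot_n: int = 10000,
    tolerance: float = 0.02,
    bisect_tol: float = 0.003,
    max_iter: int = 40,
) -> dict[str, float]:
    """Bisection-calibrate per-item noise scales to the target AUCs.

    Uses one pilot sample (latent severities, outcomes and per-item noise
    draws) held fixed across all bisection evaluations — common random
    numbers make each group's AUC a smooth, monotone-decreasing function of
    its noise scale, so plain bisection on log-sigma converges to within
    ``bisect_tol``. Groups are calibrated in dependency order.
    ``tolerance`` is the overall calibration tolerance: a target within it
    of the attainable ceiling (a discrete score cannot exceed the AUC its
    level structure supports) is clamped at minimal noise, while a target
    outside the attainable [floor - tolerance, ceiling + tolerance] band
    raises :class:`CalibrationError`.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    z = rng.standard_normal(pilot_n)
    a = _outcome_intercept(config.latent_slope, config.target_incidence)
    y = rng.random(pilot_n) < expit(a + config.latent_slope * z)
    if y.sum() < 10 or (~y).sum() < 10:
        raise CalibrationError("pilot sample too unbalanced for calibration")
    eps = {item: rng.standard_normal(pilot_n) for item in _ALL_ITEMS}

    noise: dict[str, float] = {item: 1.0 for item in _ALL_ITEMS}
    lo_sigma, hi_sigma = 0.01, 80.0

    def system_auc(variant: str) -> float:
        u = _draw_item_latents(z, eps, noise)
        records = _build_records(u)
        score = SCORE_VARIANTS[variant]
        scores = [score(w) for w in records]
        return roc_auc(scores, y).auc

    for _, items, variant in _CALIBRATION_PLAN:
        target = config.target_auc.get(variant)
        if target is None:
            continue  # no target for this variant: keep unit noise

        def auc_at(sigma: float) -> float:
            for item in items:
                noise[item] = sigma
            return system_auc(variant)

        ceiling = auc_at(lo_sigma)
        floor = auc_at(hi_sigma)
        if target > ceiling + tolerance:
            raise CalibrationError(
                f"target AUC {target} for {variant!r} exceeds attainable ceiling {ceiling:.3f}"
            )
        if target < floor - tolerance:
            raise CalibrationError(
                f"target AUC {target} for {variant!r} below attainable floor {floor:.3f}"
            )
        if target >= ceiling:
            sigma = lo_sigma  # clamp at the score's structural ceiling
        else:
            lo, hi = math.log(lo_sigma), math.log(hi_sigma)
            sigma = math.exp(0.5 * (lo + hi))
            for _ in range(max_iter):
                value = auc_at(sigma)
                if abs(value - target) <= bisect_tol:
                    break
                if value > target:  # too discriminative -> more noise
                    lo = math.log(sigma)
                else:
                    hi = math.log(sigma)
                sigma = math.exp(0.5 * (lo + hi))
        for item in items:
            noise[item] = sigma
    return noise


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a fully synthetic cohort under the configured study conditions.

    Reproducible: the same config (including seed) yields an identical
    cohort. When ``events_inpatient_only`` is set, every event patient is an
    inpatient and the remaining inpatient slots (up to
    ``inpatient_fraction``) are filled by the most severe non-event
    patients, reproducing both the zero-event outpatient stratum and the
    severity-homogeneous inpatient case mix that drives spectrum bias.
    """
    noise = dict(config.latent_noise) if config.latent_noise is not None else None
    if noise is None:
        noise = calibrate_noise(config)
    missing = sorted(set(_ALL_ITEMS) - set(noise))
    if missing:
        raise ValueError(f"latent_noise missing items: {missing}")

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    n = config.n_patients
    z = rng.standard_normal(n)
    a = _outcome_intercept(config.latent_slope, config.target_incidence)
    major = rng.random(n) < expit(a + config.latent_slope * z)
    eps = {item: rng.standard_normal(n) for item in _ALL_ITEMS}
    wounds = _build_records(_draw_item_latents(z, eps, noise))

    minor = np.zeros(n, dtype=bool)
    minor[~major] = rng.random(int((~major).sum())) < config.minor_fraction

    inpatient = np.zeros(n, dtype=bool)
    k = int(round(config.inpatient_fraction * n))
    if config.events_inpatient_only:
        inpatient[major] = True
        slots = max(k - int(major.sum()), 0)
        nonevent_idx = np.flatnonzero(~major)
        severity_rank = z[nonevent_idx] + 0.5 * rng.standard_normal(nonevent_idx.size)
        chosen = nonevent_idx[np.argsort(severity_rank)[::-1][:slots]]
        inpatient[chosen] = True
    else:
        inpatient = rng.random(n) < config.inpatient_fraction

    follow_up = rng.uniform(6.0, 60.0, size=n)

    records = tuple(
        (
            wounds[i],
            OutcomeRecord(
                major_amputation=bool(major[i]),
                minor_amputation=bool(minor[i]),
                inpatient=bool(inpatient[i]),
                follow_up_months=float(follow_up[i]),
            ),
        )
        for i in range(n)
    )
    return Cohort(records=records, provenance=f"synthetic(seed={config.seed})")


# ---------------------------------------------------------------------------
# Deterministic 12-patient worked example
# ---------------------------------------------------------------------------

def fixture_small() -> Cohort:
    """A hand-written 12-patient cohort spanning all four classifiers' ranges.

    Covers Wagner grades 0–5, UT stages A–D, SINBAD totals 0–6 and all
    three Saint Elian severity bands (including a total of exactly 10, the
    band edge). Three major amputations, three minor, six none; every event
    patient is an inpatient, so the outpatient stratum has zero events.
    Deterministic: repeated calls return identical cohorts.
    """
    W = WoundRecord
    O = OutcomeRecord
    rows = [
        # pid, depth, osteo, gangrene, infection, ischemia, neuropathy, edema,
        # site, se_loc, se_top, se_zones, area, healing, (major, minor, inpt, fu)
        ("P01", Depth.INTACT, False, "none", "none", "none", "none", "none",
         "forefoot", "phalangeal", "dorsal_or_plantar", "one", 0.0, "epithelialization",
         (False, False, False, 12.0)),
        ("P02", Depth.SUPERFICIAL, False, "none", "none", "none", "none", "none",
         "forefoot", "phalangeal", "dorsal_or_plantar", "one", 1.5, "epithelialization",
         (False, False, False, 24.0)),
        ("P03", Depth.TENDON_CAPSULE, False, "none", "none", "none", "diminished", "none",
         "midfoot", "metatarsal", "lateral_or_medial", "one", 2.0, "granulation",
         (False, False, False, 18.0)),
        ("P04", Depth.BONE_JOINT, True, "none", "mild", "none", "lops", "perilesional",
         "forefoot", "phalangeal", "dorsal_or_plantar", "one", 4.0, "inflammatory",
         (False, True, True, 9.0)),
        ("P05", Depth.SUPERFICIAL, False, "localized", "moderate", "moderate", "lops", "unilateral",
         "forefoot", "phalangeal", "lateral_or_medial", "two", 8.0, "inflammatory",
         (False, True, True, 8.0)),
        ("P06", Depth.BONE_JOINT, True, "extensive", "severe", "severe", "charcot", "bilateral",
         "hindfoot", "tarsal", "two_or_more", "whole_foot", 50.0, "inflammatory",
         (True, False, True, 6.0)),
        ("P07", Depth.BONE_JOINT, False, "none", "moderate", "mild", "lops", "perilesional",
         "forefoot", "metatarsal", "two_or_more", "two", 15.0, "inflammatory",
         (True, False, True, 7.0)),
        ("P08", Depth.TENDON_CAPSULE, False, "none", "mild", "none", "none", "none",
         "forefoot", "phalangeal", "dorsal_or_plantar", "one", 1.0, "granulation",
         (False, False, False, 30.0)),
        ("P09", Depth.SUPERFICIAL, False, "none", "none", "moderate", "none", "none",
         "midfoot", "metatarsal", "lateral_or_medial", "one", 0.8, "epithelialization",
         (False, False, False, 12.0)),
        ("P10", Depth.BONE_JOINT, True, "localized", "severe", "severe", "diminished", "unilateral",
         "forefoot", "tarsal", "lateral_or_medial", "two", 42.0, "inflammatory",
         (True, False, True, 6.5)),
        ("P11", Depth.SUPERFICIAL, False, "none", "mild", "mild", "diminished", "perilesional",
         "hindfoot", "tarsal", "dorsal_or_plantar", "one", 1.5, "granulation",
         (False, False, False, 20.0)),
        ("P12", Depth.TENDON_CAPSULE, False, "none", "moderate", "none", "lops", "bilateral",
         "midfoot", "metatarsal", "two_or_more", "two", 12.0, "granulation",
         (False, True, True, 10.0)),
    ]
    records = []
    for (pid, depth, osteo, gang, inf, isch, neuro, edema,
         site, loc, top, zones, area, heal, (maj, mino, inpt, fu)) in rows:
        wound = W(
            patient_id=pid,
            depth=depth,
            osteomyelitis_or_abscess=osteo,
            gangrene=GangreneExtent.from_token(gang),
            infection_idsa=InfectionSeverity.from_token(inf),
            ischemia_grade=IschemiaGrade.from_token(isch),
            neuropathy_grade=NeuropathyGrade.from_token(neuro),
            edema_grade=EdemaGrade.from_token(edema),
            site_region=SiteRegion.from_token(site),
            se_location=SeLocation.from_token(loc),
            se_topography=SeTopography.from_token(top),
            se_zones=SeZones.from_token(zones),
            area_cm2=area,
            healing_phase=HealingPhase.from_token(heal),
        )
        records.append((wound, O(maj, mino, inpt, fu)))
    return Cohort(records=tuple(records), provenance="fixture_small")
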