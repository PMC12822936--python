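"""Discrimination and risk statistics for external validation.

Implements the statistical layer of a prognostic-score validation:

* banded contingency tables with relative risks under a robust-variance
  Poisson model (closed form for a saturated categorical exposure),
* operating characteristics (sensitivity, specificity, predictive values,
  likelihood ratios, Youden index) with exact Clopper–Pearson intervals,
* tie-aware empirical ROC curves and AUROC with DeLong standard errors,
* the DeLong test for two correlated ROC curves,
* threshold sweeps and Youden-optimal cut-off selection,
* care-setting–stratified AUROC with explicit incalculable markers,
* Monte-Carlo power for paired AUROC comparisons under a correlated
  binormal model.

All estimators take plain sequences/arrays; nothing here knows about wound
records. Scores are oriented so that higher values mean higher risk.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import ndtr, ndtri

__all__ = [
    "Z_95",
    "ContingencyTable",
    "RiskRatioResult",
    "OperatingPoint",
    "RocResult",
    "PairedAucComparison",
    "Incidence",
    "Incalculable",
    "DiscriminationBand",
    "DiscriminationLabel",
    "PowerResult",
    "OutcomeSelector",
    "build_contingency",
    "risk_ratio",
    "clopper_pearson",
    "operating_point",
    "threshold_sweep",
    "roc_auc",
    "delong_placements",
    "delong_paired_test",
    "youden_best",
    "cumulative_incidence",
    "stratified_auc",
    "discrimination_label",
    "power_paired_auc",
    "round_half_away",
]

#: Two-sided 97.5% normal quantile used throughout for 95% intervals.
Z_95 = 1.959964


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of clinical tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Contingency tables and relative risks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """K x 2 event/no-event counts per ordinal risk band."""

    band_labels: tuple[str, ...]
    events: tuple[int, ...]
    nonevents: tuple[int, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not (len(self.band_labels) == len(self.events) == len(self.nonevents)):
            raise ValueError("band_labels, events, nonevents must align")
        if any(e < 0 for e in self.events) or any(n < 0 for n in self.nonevents):
            raise ValueError("counts must be nonnegative")
        if not 0 <= self.reference_index < len(self.band_labels):
            raise ValueError("reference_index out of range")

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(e + n for e, n in zip(self.events, self.nonevents))

    @property
    def n(self) -> int:
        return sum(self.totals)

    def band_index(self, band: str) -> int:
        try:
            return self.band_labels.index(band)
        except ValueError:
            raise KeyError(f"band {band!r} not in table {self.band_labels}") from None


def build_contingency(
    bands: Sequence[str],
    outcomes: Sequence[bool],
    reference: str,
    band_order: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Count events/non-events per band, recording the reference band.

    ``band_order`` fixes the row order (and retains empty bands); by default
    rows follow first appearance. The reference must be one of the rows.
    """
    if len(bands) != len(outcomes):
        raise ValueError("bands and outcomes must have the same length")
    if len(bands) == 0:
        raise ValueError("empty cohort")
    if band_order is None:
        order: list[str] = []
        for b in bands:
            if b not in order:
                order.append(b)
    else:
        order = list(band_order)
        unknown = sorted(set(bands) - set(order))
        if unknown:
            raise ValueError(f"bands outside declared order: {unknown}")
    if reference not in order:
        raise ValueError(f"reference band {reference!r} absent from {order}")
    events = {b: 0 for b in order}
    nonevents = {b: 0 for b in order}
    for b, y in zip(bands, outcomes):
        if y:
            events[b] += 1
        else:
            nonevents[b] += 1
    return ContingencyTable(
        band_labels=tuple(order),
        events=tuple(events[b] for b in order),
        nonevents=tuple(nonevents[b] for b in order),
        reference_index=order.index(reference),
    )


@dataclass(frozen=True)
class RiskRatioResult:
    """Relative risk of a band vs the reference band with robust 95% CI.

    ``calculable`` is False (mirroring "NC" table entries) when either the
    band or the reference has zero events, in which case the numeric fields
    are NaN.
    """

    band: str
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    calculable: bool


def risk_ratio(table: ContingencyTable, band: str) -> RiskRatioResult:
    """Relative risk of ``band`` vs the table's reference band.

    Point estimate is the ratio of event proportions. The standard error is
    the robust (sandwich) Poisson-regression standard error, which for a
    saturated model on a categorical exposure has the closed form
    ``sqrt(1/e_b - 1/n_b + 1/e_ref - 1/n_ref)``; the CI is
    ``exp(log rr +/- z * se)`` and the p-value is the two-sided Wald test of
    log rr = 0.
    """
    i = table.band_index(band)
    r = table.reference_index
    if i == r:
        raise ValueError("band must differ from the reference band")
    e_b, n_b = table.events[i], table.totals[i]
    e_r, n_r = table.events[r], table.totals[r]
    if n_b == 0 or n_r == 0 or e_b == 0 or e_r == 0:
        nan = float("nan")
        return RiskRatioResult(band, nan, nan, nan, nan, calculable=False)
    rr = (e_b / n_b) / (e_r / n_r)
    se = math.sqrt(1.0 / e_b - 1.0 / n_b + 1.0 / e_r - 1.0 / n_r)
    log_rr = math.log(rr)
    ci_low = math.exp(log_rr - Z_95 * se)
    ci_high = math.exp(log_rr + Z_95 * se)
    if se == 0.0:
        p = 1.0 if log_rr == 0.0 else 0.0
    else:
        p = 2.0 * (1.0 - ndtr(abs(log_rr) / se))
    return RiskRatioResult(band, rr, ci_low, ci_high, p, calculable=True)


# ---------------------------------------------------------------------------
# Exact binomial intervals and operating characteristics
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial CI via Beta-distribution quantiles."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return low, high


@dataclass(frozen=True)
class _PropCI:
    """A proportion with its exact binomial CI; undefined when n = 0."""

    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    defined: bool


def _prop(x: int, n: int) -> _PropCI:
    if n == 0:
        return _PropCI(None, None, None, defined=False)
    low, high = clopper_pearson(x, n)
    return _PropCI(x / n, low, high, defined=True)


@dataclass(frozen=True)
class _LrCI:
    """A likelihood ratio with log-method CI; CI undefined at boundary cells."""

    value: float  # may be inf (LR+ with perfect specificity) or 0 (LR- with perfect sensitivity)
    ci_low: Optional[float]
    ci_high: Optional[float]


@dataclass(frozen=True)
class OperatingPoint:
    """Confusion counts and operating characteristics at one threshold."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: _PropCI
    specificity: _PropCI
    ppv: _PropCI
    npv: _PropCI
    lr_pos: _LrCI
    lr_neg: _LrCI
    youden: float  # sensitivity + specificity - 1, as a fraction in [-1, 1]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _lr_ci(lr: float, a: int, m: int, b: int, n: int) -> _LrCI:
    """Log-method CI for a ratio of two proportions (a/m) / (b/n)."""
    if a == 0 or b == 0 or lr == 0.0 or math.isinf(lr):
        return _LrCI(lr, None, None)
    se = math.sqrt(1.0 / a - 1.0 / m + 1.0 / b - 1.0 / n)
    return _LrCI(lr, lr * math.exp(-Z_95 * se), lr * math.exp(Z_95 * se))


def operating_point(tp: int, fp: int, fn: int, tn: int, threshold: float = float("nan")) -> OperatingPoint:
    """Operating characteristics from a 2x2 confusion table.

    Sensitivity/specificity/PPV/NPV carry exact Clopper–Pearson intervals;
    likelihood ratios carry log-method intervals (undefined at boundary
    cells). PPV/NPV with a zero denominator are flagged undefined, not
    raised. Requires at least one diseased (tp+fn) and one non-diseased
    (fp+tn) subject.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fn < 1 or fp + tn < 1:
        raise ValueError("need at least one positive and one negative subject")
    sens = _prop(tp, tp + fn)
    spec = _prop(tn, fp + tn)
    ppv = _prop(tp, tp + fp)
    npv = _prop(tn, tn + fn)

    assert sens.value is not None and spec.value is not None
    fpr = 1.0 - spec.value
    fnr = 1.0 - sens.value
    lr_pos_val = math.inf if fpr == 0.0 else sens.value / fpr
    lr_pos = _lr_ci(lr_pos_val, tp, tp + fn, fp, fp + tn)
    lr_neg_val = fnr / spec.value if spec.value > 0.0 else math.inf
    lr_neg = _lr_ci(lr_neg_val, fn, tp + fn, tn, fp + tn)

    return OperatingPoint(
        threshold=threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        youden=sens.value + spec.value - 1.0,
    )


def threshold_sweep(scores: Sequence[float], outcomes: Sequence[bool]) -> list[OperatingPoint]:
    """One operating point per rule "score >= t" for each distinct score.

    Thresholds are the distinct observed score values in ascending order,
    so the first point classifies everyone positive. Requires at least one
    event and one non-event.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be aligned 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate outcome vector: need both events and non-events")
    points = []
    for t in np.unique(s):
        pred = s >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        points.append(operating_point(tp, fp, fn, tn, threshold=float(t)))
    return points


def youden_best(sweep: Sequence[OperatingPoint]) -> OperatingPoint:
    """The sweep point maximizing the Youden index.

    Ties break toward the lowest threshold, which maximizes sensitivity
    among the maximizers.
    """
    if not sweep:
        raise ValueError("empty sweep")
    best = sweep[0]
    for p in sweep[1:]:
        if p.youden > best.youden + 1e-12 or (
            abs(p.youden - best.youden) <= 1e-12 and p.threshold < best.threshold
        ):
            best = p
    return best


# ---------------------------------------------------------------------------
# ROC / AUROC with DeLong machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """Empirical tie-aware ROC curve with DeLong AUC inference."""

    score_levels: tuple[float, ...]
    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    auc: float
    se_auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def delong_placements(scores: Sequence[float], outcomes: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (structural components) for one score.

    For each event subject i, ``v10[i]`` is the fraction of non-event
    subjects scored strictly below, counting ties as one half; ``v01``
    is the mirror for non-event subjects. ``mean(v10) == mean(v01)`` is the
    tie-corrected AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos = s[y]
    neg = s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("degenerate outcome vector: need both events and non-events")
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # counts of strictly-below and ties via binary search (O(n log n))
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties = np.searchsorted(neg_sorted, pos, side="right") - below
    v10 = (below + 0.5 * ties) / neg.size
    above = pos.size - np.searchsorted(pos_sorted, neg, side="right")
    ties_n = np.searchsorted(pos_sorted, neg, side="right") - np.searchsorted(
        pos_sorted, neg, side="left"
    )
    v01 = (above + 0.5 * ties_n) / pos.size
    return v10, v01


def roc_auc(scores: Sequence[float], outcomes: Sequence[bool], conf: float = 0.95) -> RocResult:
    """Tie-aware AUROC with DeLong standard error and normal CI.

    The AUC is the Mann–Whitney pair statistic
    ``[#(pos > neg) + 0.5 * #(pos = neg)] / (n_pos * n_neg)``, identical to
    the trapezoidal area under the empirical ROC curve. The CI is
    ``auc +/- z * se`` truncated to [0, 1], with the DeLong variance
    ``var(v10)/m + var(v01)/n`` (sample variances).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    v10, v01 = delong_placements(s, y)
    m, n = v10.size, v01.size
    auc = float(v10.mean())
    var10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(var10 / m + var01 / n)
    z = float(ndtri(0.5 + conf / 2.0))
    levels = np.unique(s)
    sens = []
    spec = []
    pos = s[y]
    neg = s[~y]
    for t in levels:
        sens.append(float((pos >= t).sum()) / m)
        spec.append(float((neg < t).sum()) / n)
    return RocResult(
        score_levels=tuple(float(t) for t in levels),
        sensitivities=tuple(sens),
        specificities=tuple(spec),
        auc=auc,
        se_auc=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        n_pos=m,
        n_neg=n,
    )


@dataclass(frozen=True)
class PairedAucComparison:
    """DeLong test for two correlated ROC curves on the same subjects."""

    auc_a: float
    auc_b: float
    delta_auc: float
    se_delta: float
    ci_low: float
    ci_high: float
    p_value: float
    covariance: float  # cov(AUC_a, AUC_b)


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[bool],
    conf: float = 0.95,
) -> PairedAucComparison:
    """DeLong test comparing the AUCs of two scores on the same patients.

    The variance of the AUC difference combines the event- and
    non-event-side covariance matrices of the placement values:
    ``var = (s10_aa + s10_bb - 2 s10_ab)/m + (s01_aa + s01_bb - 2 s01_ab)/n``.
    Two-sided p from the normal reference; a zero variance with a zero
    difference yields p = 1 (identical curves).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors and outcomes must be aligned")
    v10a, v01a = delong_placements(a, y)
    v10b, v01b = delong_placements(b, y)
    m, n = v10a.size, v01a.size
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    delta = auc_a - auc_b
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]
    ) / n
    var = max(float(var), 0.0)
    se = math.sqrt(var)
    cov_ab = float(s10[0, 1] / m + s01[0, 1] / n)
    z_crit = float(ndtri(0.5 + conf / 2.0))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = 2.0 * (1.0 - ndtr(abs(delta) / se))
    return PairedAucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta_auc=delta,
        se_delta=se,
        ci_low=delta - z_crit * se,
        ci_high=delta + z_crit * se,
        p_value=p,
        covariance=cov_ab,
    )


# ---------------------------------------------------------------------------
# Incidence, stratification, discrimination bands
# ---------------------------------------------------------------------------

class OutcomeSelector(enum.Enum):
    """Which amputation outcome defines an event."""

    MAJOR = "major"
    ANY = "any"


@dataclass(frozen=True)
class Incidence:
    """Cumulative incidence (events/n) with exact binomial CI."""

    events: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float


def cumulative_incidence(
    outcomes: Sequence, selector: Optional[OutcomeSelector] = None
) -> Incidence:
    """Cumulative incidence (events/n) with Clopper–Pearson CI.

    ``outcomes`` is either a boolean event vector, or — when ``selector`` is
    given — a sequence of outcome records carrying ``major_amputation`` and
    ``minor_amputation`` flags, from which the MAJOR or ANY (major or minor,
    derived, never stored) event indicator is taken.
    """
    if selector is None:
        events: Sequence[bool] = outcomes
    elif selector is OutcomeSelector.MAJOR:
        events = [o.major_amputation for o in outcomes]
    else:
        events = [o.major_amputation or o.minor_amputation for o in outcomes]
    y = np.asarray(events, dtype=bool)
    if y.size == 0:
        raise ValueError("empty cohort")
    x = int(y.sum())
    n = int(y.size)
    low, high = clopper_pearson(x, n)
    return Incidence(events=x, n=n, proportion=x / n, ci_low=low, ci_high=high)


@dataclass(frozen=True)
class Incalculable:
    """Explicit marker for a stratum where the AUROC is not estimable."""

    n: int
    n_pos: int
    n_neg: int
    reason: str


def stratified_auc(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    strata: Sequence[Hashable],
) -> dict[Hashable, RocResult | Incalculable]:
    """AUROC per stratum; zero-event (or zero-non-event) strata are flagged.

    A stratum with no events — e.g. outpatients in a cohort where every
    amputation occurred among inpatients — yields an :class:`Incalculable`
    marker rather than a number.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    g = np.asarray(strata, dtype=object)
    if not (s.shape == y.shape == g.shape):
        raise ValueError("scores, outcomes, strata must be aligned")
    out: dict[Hashable, RocResult | Incalculable] = {}
    for stratum in dict.fromkeys(g.tolist()):  # preserve first-appearance order
        mask = g == stratum
        ys = y[mask]
        n_pos = int(ys.sum())
        n_neg = int((~ys).sum())
        if n_pos == 0 or n_neg == 0:
            reason = "no events in stratum" if n_pos == 0 else "no non-events in stratum"
            out[stratum] = Incalculable(n=int(mask.sum()), n_pos=n_pos, n_neg=n_neg, reason=reason)
        else:
            out[stratum] = roc_auc(s[mask], ys)
    return out


class DiscriminationBand(enum.Enum):
    CHANCE = "chance"
    VERY_POOR = "very poor"
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class DiscriminationLabel:
    band: DiscriminationBand
    below_chance: bool


def discrimination_label(auc: float) -> DiscriminationLabel:
    """Qualitative discrimination band for an AUROC.

    0.50 is chance; (0.50, 0.60) very poor; [0.60, 0.70) poor; [0.70, 0.80)
    moderate; [0.80, 0.90) good; >= 0.90 excellent. Values below 0.50 are
    labelled chance with a below-chance flag.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must lie in [0, 1], got {auc}")
    if auc < 0.5:
        return DiscriminationLabel(DiscriminationBand.CHANCE, below_chance=True)
    if auc == 0.5:
        band = DiscriminationBand.CHANCE
    elif auc < 0.6:
        band = DiscriminationBand.VERY_POOR
    elif auc < 0.7:
        band = DiscriminationBand.POOR
    elif auc < 0.8:
        band = DiscriminationBand.MODERATE
    elif auc < 0.9:
        band = DiscriminationBand.GOOD
    else:
        band = DiscriminationBand.EXCELLENT
    return DiscriminationLabel(band, below_chance=False)


# ---------------------------------------------------------------------------
# Monte-Carlo power for paired AUROC comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    rejections: int


def power_paired_auc(
    auc_a: float,
    auc_b: float,
    n_pos: int,
    n_neg: int,
    correlation: float = 0.5,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
) -> PowerResult:
    """Simulated power of the paired DeLong test at the given design.

    Scores follow a correlated binormal model: within each outcome class the
    two scores are bivariate normal with unit variances and the requested
    correlation, and events are mean-shifted by ``sqrt(2) * Phi^-1(auc)``
    per score so each score's population AUC matches its target. Each
    replicate applies :func:`delong_paired_test`; power is the two-sided
    rejection fraction at ``alpha``, with a Clopper–Pearson Monte-Carlo CI.
    Deterministic under a fixed seed.
    """
    for name, auc in (("auc_a", auc_a), ("auc_b", auc_b)):
        if not 0.5 <= auc < 1.0:
            raise ValueError(f"{name} must lie in [0.5, 1), got {auc}")
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must lie strictly within (-1, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    mu_a = math.sqrt(2.0) * float(ndtri(auc_a))
    mu_b = math.sqrt(2.0) * float(ndtri(auc_b))
    chol = np.linalg.cholesky(np.array([[1.0, correlation], [correlation, 1.0]]))
    rejections = 0
    y = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    for _ in range(n_reps):
        eps = rng.standard_normal((n_pos + n_neg, 2)) @ chol.T
        eps[:n_pos, 0] += mu_a
        eps[:n_pos, 1] += mu_b
        result = delong_paired_test(eps[:, 0], eps[:, 1], y)
        if result.p_value < alpha:
            rejections += 1
    low, high = clopper_pearson(rejections, n_reps)
    return PowerResult(
        power=rejections / n_reps, ci_low=low, ci_high=high, n_reps=n_reps, rejections=rejections
    )
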