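"""Statistics layer: oracles, invariants, and cross-library checks.

The tie-aware AUC is checked against exhaustive pair counting and against
scikit-learn; the DeLong variance against a brute-force placement-value
computation; Clopper-Pearson intervals against statsmodels; the closed-form
robust relative risk against a statsmodels Poisson GLM with HC sandwich
errors.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfuvalid.stats import (
    DiscriminationBand,
    Incalculable,
    build_contingency,
    clopper_pearson,
    cumulative_incidence,
    delong_paired_test,
    discrimination_label,
    operating_point,
    power_paired_auc,
    risk_ratio,
    roc_auc,
    round_half_away,
    stratified_auc,
    threshold_sweep,
    youden_best,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def auc_pair_oracle(scores, outcomes):
    """Exhaustive Mann-Whitney pair counting in exact rational arithmetic."""
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, outcomes):
    """Brute-force placement values and covariance structure (n^2 loops)."""

    def placements(scores):
        pos = [s for s, y in zip(scores, outcomes) if y]
        neg = [s for s, y in zip(scores, outcomes) if not y]
        v10 = [sum(1.0 if p > n else 0.5 if p == n else 0.0 for n in neg) / len(neg) for p in pos]
        v01 = [sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos) / len(pos) for n in neg]
        return np.array(v10), np.array(v01)

    v10a, v01a = placements(scores_a)
    v10b, v01b = placements(scores_b)
    m, n = v10a.size, v01a.size
    delta = v10a.mean() - v10b.mean()
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return delta, max(var, 0.0)


score_vectors = st.integers(2, 10).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 5), min_size=n, max_size=n),
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(score_vectors)
def test_auc_matches_pair_counting_oracle(data):
    scores, outcomes = data
    expected = auc_pair_oracle(scores, outcomes)
    assert roc_auc(scores, outcomes).auc == pytest.approx(float(expected), abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(score_vectors)
def test_auc_label_swap_symmetry(data):
    scores, outcomes = data
    auc = roc_auc(scores, outcomes).auc
    flipped = roc_auc(scores, [not y for y in outcomes]).auc
    assert auc + flipped == pytest.approx(1.0, abs=1e-12)


def test_auc_against_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    scores = rng.integers(0, 8, size=200).astype(float)
    outcomes = rng.random(200) < 0.3
    assert roc_auc(scores, outcomes).auc == pytest.approx(
        roc_auc_score(outcomes, scores), abs=1e-12
    )


def test_auc_trivial_cases():
    assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5
    # (1,2,3,4) with the single event at score 3: 2 wins, 1 loss of 3 pairs
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 0]).auc == pytest.approx(2 / 3)


def test_auc_ci_shrinks_with_n():
    rng = np.random.default_rng(0)
    widths = []
    for n in (100, 400, 1600):
        scores = rng.standard_normal(n) + np.repeat([1.0, 0.0], [n // 4, n - n // 4])
        outcomes = np.repeat([True, False], [n // 4, n - n // 4])
        r = roc_auc(scores, outcomes)
        widths.append(r.ci_high - r.ci_low)
    assert widths[0] > widths[1] > widths[2]
    # ~ n^(-1/2): quadrupling n should roughly halve the width
    assert widths[1] / widths[0] == pytest.approx(0.5, abs=0.2)


def test_roc_sensitivity_monotone():
    rng = np.random.default_rng(1)
    scores = rng.integers(0, 6, size=120).astype(float)
    outcomes = rng.random(120) < 0.25
    r = roc_auc(scores, outcomes)
    assert all(a >= b for a, b in zip(r.sensitivities, r.sensitivities[1:]))


def test_degenerate_outcomes_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        roc_auc([1, 2, 3], [True, True, True])
    with pytest.raises(ValueError, match="degenerate"):
        threshold_sweep([1, 2, 3], [False, False, False])


# ---------------------------------------------------------------------------
# DeLong paired test
# ---------------------------------------------------------------------------

def test_delong_identical_scores_p_one():
    scores = [1.0, 2.0, 3.0, 4.0, 5.0]
    outcomes = [False, False, True, False, True]
    r = delong_paired_test(scores, scores, outcomes)
    assert r.delta_auc == 0.0
    assert r.p_value == 1.0


def test_delong_antisymmetry():
    rng = np.random.default_rng(7)
    a = rng.standard_normal(60)
    b = rng.standard_normal(60)
    y = rng.random(60) < 0.3
    ab = delong_paired_test(a, b, y)
    ba = delong_paired_test(b, a, y)
    assert ab.delta_auc == pytest.approx(-ba.delta_auc, abs=1e-14)
    assert ab.p_value == pytest.approx(ba.p_value, abs=1e-14)
    assert ab.se_delta == pytest.approx(ba.se_delta, abs=1e-14)


small_paired = st.integers(4, 8).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(small_paired)
def test_delong_matches_placement_oracle(data):
    a, b, y = data
    result = delong_paired_test(a, b, y)
    delta, var = delong_oracle(a, b, y)
    assert result.delta_auc == pytest.approx(delta, abs=1e-12)
    assert result.se_delta**2 == pytest.approx(var, abs=1e-12)


def test_delong_variance_nonnegative():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = rng.integers(6, 40)
        a = rng.integers(0, 3, size=n).astype(float)
        b = rng.integers(0, 3, size=n).astype(float)
        y = rng.random(n) < 0.4
        if 0 < y.sum() < n:
            assert delong_paired_test(a, b, y).se_delta >= 0.0


# ---------------------------------------------------------------------------
# Contingency tables and relative risks
# ---------------------------------------------------------------------------

def test_build_contingency_counts_and_reference():
    bands = ["1-3"] * 194 + ["4-5"] * 148
    outcomes = [False] * 191 + [True] * 3 + [True] * 36 + [False] * 112
    table = build_contingency(bands, outcomes, reference="1-3")
    assert table.band_labels == ("1-3", "4-5")
    assert table.events == (3, 36)
    assert table.nonevents == (191, 112)
    assert table.reference_index == 0


def test_build_contingency_retains_empty_band():
    table = build_contingency(["a", "a"], [True, False], reference="a", band_order=["a", "b"])
    assert table.band_labels == ("a", "b")
    assert table.events == (1, 0)
    assert table.totals == (2, 0)


def test_build_contingency_unknown_reference():
    with pytest.raises(ValueError, match="reference"):
        build_contingency(["a"], [True], reference="z")


def test_risk_ratio_identical_risks_is_one():
    table = build_contingency(
        ["a"] * 20 + ["b"] * 20, [True] * 5 + [False] * 15 + [True] * 5 + [False] * 15, "a"
    )
    r = risk_ratio(table, "b")
    assert r.rr == pytest.approx(1.0)
    assert r.p_value == pytest.approx(1.0)


def test_risk_ratio_not_calculable_with_zero_events():
    table = build_contingency(
        ["a"] * 10 + ["b"] * 10, [False] * 10 + [True] * 3 + [False] * 7, "a"
    )
    r = risk_ratio(table, "b")
    assert r.calculable is False
    assert math.isnan(r.rr)


def test_risk_ratio_band_equals_reference_rejected():
    table = build_contingency(["a", "b"], [True, False], "a")
    with pytest.raises(ValueError):
        risk_ratio(table, "a")


def test_risk_ratio_matches_statsmodels_sandwich():
    """Closed form == Poisson GLM with HC0 robust (sandwich) variance."""
    import statsmodels.api as sm

    e_b, n_b, e_r, n_r = 26, 120, 5, 182
    y = np.concatenate([np.ones(e_b), np.zeros(n_b - e_b), np.ones(e_r), np.zeros(n_r - e_r)])
    x = sm.add_constant(np.concatenate([np.ones(n_b), np.zeros(n_r)]))
    fit = sm.GLM(y, x, family=sm.families.Poisson()).fit(cov_type="HC0")
    table = build_contingency(
        ["b"] * n_b + ["ref"] * n_r, y.astype(bool).tolist(), reference="ref"
    )
    r = risk_ratio(table, "b")
    assert math.log(r.rr) == pytest.approx(fit.params[1], abs=1e-8)
    # HC0 uses 1/n normalization; the closed form is the same sandwich
    assert (math.log(r.ci_high) - math.log(r.rr)) / 1.959964 == pytest.approx(
        fit.bse[1], rel=1e-6
    )


# ---------------------------------------------------------------------------
# Operating points, sweeps, Youden
# ---------------------------------------------------------------------------

def test_operating_point_perfect_2x2():
    op = operating_point(tp=1, fp=0, fn=0, tn=1)
    assert op.sensitivity.value == 1.0
    assert op.specificity.value == 1.0
    assert op.youden == pytest.approx(1.0)


def test_operating_point_rejects_empty_margins():
    with pytest.raises(ValueError):
        operating_point(tp=0, fp=1, fn=0, tn=1)


def test_operating_point_undefined_ppv_flagged():
    op = operating_point(tp=0, fp=0, fn=2, tn=3)
    assert op.ppv.defined is False
    assert op.ppv.value is None


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for x, n in [(0, 10), (3, 10), (39, 39), (34, 39), (227, 303)]:
        low, high = clopper_pearson(x, n)
        sm_low, sm_high = proportion_confint(x, n, method="beta")
        assert low == pytest.approx(sm_low, abs=1e-12)
        assert high == pytest.approx(sm_high, abs=1e-12)


def test_threshold_sweep_structure():
    scores = [0, 1, 1, 2, 3, 3, 3]
    outcomes = [False, False, True, False, True, True, False]
    sweep = threshold_sweep(scores, outcomes)
    assert [p.threshold for p in sweep] == [0, 1, 2, 3]
    # lowest threshold classifies everyone positive
    assert sweep[0].tp == 3 and sweep[0].tn == 0
    for p in sweep:
        assert p.n == len(scores)
        assert p.youden == pytest.approx(p.sensitivity.value + p.specificity.value - 1.0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(score_vectors)
def test_youden_identity_exact_on_counts(data):
    scores, outcomes = data
    for p in threshold_sweep(scores, outcomes):
        sens = Fraction(p.tp, p.tp + p.fn)
        spec = Fraction(p.tn, p.fp + p.tn)
        assert Fraction(p.youden).limit_denominator(10**9) == sens + spec - 1 or (
            abs(p.youden - float(sens + spec - 1)) < 1e-12
        )


def test_youden_best_picks_maximum():
    scores = [0, 1, 2, 3, 4, 5]
    outcomes = [False, False, False, True, True, True]
    sweep = threshold_sweep(scores, outcomes)
    best = youden_best(sweep)
    assert best.threshold == 3.0
    assert best.youden == pytest.approx(1.0)


def test_youden_best_tie_breaks_to_lowest_threshold():
    a = operating_point(tp=3, fp=2, fn=1, tn=6, threshold=2.0)
    b = operating_point(tp=3, fp=2, fn=1, tn=6, threshold=4.0)
    assert youden_best([b, a]).threshold == 2.0


def test_youden_best_single_point():
    p = operating_point(tp=1, fp=1, fn=1, tn=1, threshold=1.0)
    assert youden_best([p]) is p


# ---------------------------------------------------------------------------
# Incidence, stratification, labels
# ---------------------------------------------------------------------------

def test_cumulative_incidence_zero_events():
    r = cumulative_incidence([False] * 25)
    assert r.proportion == 0.0
    assert r.ci_low == 0.0
    assert r.ci_high > 0.0


def test_stratified_auc_partition_consistency():
    rng = np.random.default_rng(2)
    scores = rng.integers(0, 10, size=200).astype(float)
    outcomes = rng.random(200) < 0.3
    strata = np.where(rng.random(200) < 0.5, "a", "b")
    result = stratified_auc(scores, outcomes, strata)
    for s in ("a", "b"):
        mask = strata == s
        expected = roc_auc(scores[mask], outcomes[mask])
        assert result[s].auc == pytest.approx(expected.auc, abs=1e-14)


def test_stratified_auc_single_stratum_matches_overall():
    scores = [1, 2, 3, 4]
    outcomes = [False, True, False, True]
    result = stratified_auc(scores, outcomes, ["only"] * 4)
    assert result["only"].auc == pytest.approx(roc_auc(scores, outcomes).auc)


def test_stratified_auc_zero_event_stratum_incalculable():
    scores = [1, 2, 3, 4, 5, 6]
    outcomes = [True, False, False, False, False, False]
    strata = ["in", "in", "in", "out", "out", "out"]
    result = stratified_auc(scores, outcomes, strata)
    assert isinstance(result["out"], Incalculable)
    assert result["out"].n_pos == 0
    assert not isinstance(result["in"], Incalculable)


@pytest.mark.parametrize(
    "auc, band, below",
    [
        (0.900, DiscriminationBand.EXCELLENT, False),
        (0.811, DiscriminationBand.GOOD, False),
        (0.747, DiscriminationBand.MODERATE, False),
        (0.655, DiscriminationBand.POOR, False),
        (0.55, DiscriminationBand.VERY_POOR, False),
        (0.50, DiscriminationBand.CHANCE, False),
        (0.40, DiscriminationBand.CHANCE, True),
    ],
)
def test_discrimination_bands(auc, band, below):
    label = discrimination_label(auc)
    assert label.band is band
    assert label.below_chance is below


def test_discrimination_label_rejects_out_of_range():
    with pytest.raises(ValueError):
        discrimination_label(1.2)


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

def test_power_null_configuration_near_alpha():
    r = power_paired_auc(0.8, 0.8, n_pos=40, n_neg=120, correlation=0.5,
                         alpha=0.05, n_reps=400, seed=4)
    assert r.ci_low <= 0.05 <= r.ci_high or abs(r.power - 0.05) < 0.03


def test_power_extreme_separation_near_one():
    r = power_paired_auc(0.99, 0.55, n_pos=60, n_neg=200, correlation=0.3,
                         alpha=0.05, n_reps=200, seed=4)
    assert r.power > 0.99


def test_power_deterministic_under_seed():
    a = power_paired_auc(0.9, 0.75, n_pos=39, n_neg=303, n_reps=150, seed=9)
    b = power_paired_auc(0.9, 0.75, n_pos=39, n_neg=303, n_reps=150, seed=9)
    assert a == b


def test_power_rejects_bad_inputs():
    with pytest.raises(ValueError):
        power_paired_auc(0.4, 0.8, 10, 10)
    with pytest.raises(ValueError):
        power_paired_auc(0.8, 0.7, 10, 10, correlation=1.0)


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def test_round_half_away_from_zero():
    assert round_half_away(21.25, 1) == 21.3  # 34/160 as a percentage
    assert round_half_away(0.125, 2) == 0.13
    assert round_half_away(-0.125, 2) == -0.13
    assert round_half_away(62.05, 1) == 62.1
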