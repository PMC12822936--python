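# Methods

This note documents the statistical model behind `dfuvalid`, the design
decisions that were genuinely open, the numerical conventions, and what the
synthetic generator does and does not emulate.

## The validation problem

Four ordinal wound-severity scores — Meggitt–Wagner (MW, 0–5), University
of Texas (UT, depth 0–3 × stage A–D), SINBAD (0–6) and Saint Elian (SE,
6–30) — are evaluated against a binary six-month outcome, major amputation
(any amputation above the ankle, ipsilateral to the index ulcer). Minor
(toe/transmetatarsal) amputations count as "no major amputation"; the
composite outcome "any amputation" is derived, never stored. One wound
record per patient (the index ulcer); eligibility requires at least six
months of follow-up.

## Scoring conventions

Shared binary derivations: "infection" means IDSA grade ≥ mild (a cohort
row with IDSA "none" is UT/SINBAD infection-negative), "ischemia" means
Doppler-waveform grade ≥ mild, "neuropathy" means ≥ diminished sensation.
The graded fields serve Saint Elian's 0–3 aggravating items directly.

Open points that required a decision:

- **SE per-item points.** The published severity bands fix only the scale
  top (30) and bottom; the per-item values used here — 1/2/3 for the three
  anatomical and three contributing items, 0/1/2/3 for the four
  aggravating items — are the original Saint Elian scheme, giving the
  range 6–30 consistent with those bands.
- **SE total of exactly 10.** The published bands ("mild <10, moderate
  11–20") leave 10 unassigned; it is banded *mild* for contiguity.
- **SE area bands.** The middle band is closed at 40 cm² ([10, 40] → 2
  points, >40 → 3). Descriptive tables elsewhere print "10–39.9"; for
  continuous areas the difference is a set of measure zero and immaterial
  in practice.
- **MW precedence.** When several grades apply, the most severe wins
  (extensive gangrene > localized gangrene > deep infection > depth), per
  the ordered-severity reading of the scale; extensive gangrene forces
  grade 5 regardless of all other fields.
- **SINBAD area boundary** is closed below: area ≥ 1 cm² scores the point.
- **Risk-band collapses** mirror the sparse-category merges of the
  analysis: MW 1–3 vs 4–5, UT 3D vs other, SINBAD 1–4 / 5 / 6, SE <16 /
  16–20 / >20, each ordered with the lowest theoretical risk first (grade-0
  records fall in the lowest band).
- **UT as ROC input.** UT is never treated as a single 16-level ordinal;
  the seven analysed curves are SE, MW, SINBAD, UT-3D (binary), UT depth
  (0–3), UT ischemia (binary), UT infection (binary), all oriented so
  higher = riskier.

## Estimators

**Relative risk.** For band *b* against reference *r*:
RR = (e_b/n_b)/(e_r/n_r), with the robust (sandwich) Poisson standard
error in closed form, se(log RR) = √(1/e_b − 1/n_b + 1/e_r − 1/n_r); 95%
CI exp(log RR ± 1.959964·se); two-sided Wald p. For a saturated Poisson
regression on a categorical exposure the closed form and the iterative GLM
with HC0 covariance are the same estimator (verified against a GLM fit in
the tests); the closed form is exact and dependency-free. A band or
reference with zero events yields `calculable = False` ("NC"), not an
exception and not a number.

**Exact binomial intervals.** Clopper–Pearson via Beta quantiles:
lower = B(α/2; x, n−x+1), upper = B(1−α/2; x+1, n−x), with the natural
conventions at x = 0 and x = n. Applied to incidences and to
sensitivity/specificity/PPV/NPV. Likelihood-ratio CIs use the log method;
boundary cells (LR+ = ∞ at perfect specificity, LR− = 0 at perfect
sensitivity) carry no CI. PPV/NPV with an empty denominator are flagged
undefined rather than raised.

**AUROC.** Tie-aware Mann–Whitney statistic, computed from DeLong
placement values: for event *i*, V10_i is the fraction of non-events
scored strictly below, ties counting ½; AUC = mean(V10) = mean(V01), which
equals the trapezoidal area under the empirical ROC. Standard error
√(var(V10)/m + var(V01)/n) with sample variances; 95% CI AUC ± z·se
truncated to [0, 1]. The normal (untransformed) DeLong interval is used
throughout — the source material prints two mutually inconsistent CI sets
for the same AUROCs without naming either method, so one method is fixed
here and documented.

**DeLong paired test.** var(ΔAUC) = (s10_aa + s10_bb − 2s10_ab)/m +
(s01_aa + s01_bb − 2s01_ab)/n from the placement-value covariance
matrices; two-sided normal p; identical score vectors (zero variance, zero
difference) give p = 1 by convention. No multiplicity adjustment across
the 21 pairwise comparisons. Implementation uses O(n log n) binary-search
placements; the tests compare it against an O(n²) brute-force enumeration.

**Youden selection.** Threshold sweeps evaluate the rule "score ≥ t" at
every distinct observed value in ascending order; the Youden-optimal point
maximizes J = sens + spec − 1, ties broken toward the lowest threshold
(maximizing sensitivity among maximizers).

**Discrimination bands.** 0.50 chance; (0.50, 0.60) very poor; [0.60,
0.70) poor; [0.70, 0.80) moderate; [0.80, 0.90) good; ≥ 0.90 excellent;
AUROC < 0.50 is labelled chance with a below-chance flag.

**Paired-AUC power.** The a-priori power computation is a Monte-Carlo
stand-in (the original procedure is not published): within each outcome
class the two scores are bivariate normal with unit variance and
correlation ρ (default 0.5), events mean-shifted by √2·Φ⁻¹(AUC) per score;
each replicate runs the DeLong test and power is the rejection fraction at
α with a Clopper–Pearson Monte-Carlo CI.

**Rounding and formatting.** Table output rounds half away from zero at
the printed precision (so 34/160 = 21.25% prints as 21.3); p-values below
0.001 print as "<0.001"; percentage CI bounds drop a trailing ".0". The
JSON report carries the unrounded values; formatting is the only lossy
step.

## Synthetic cohort model

Each patient has a latent severity Z ~ N(0, 1).

- **Outcome:** P(major amputation | Z) = expit(a + βZ) with slope β = 4.5
  and intercept *a* root-found so the population incidence equals the
  target (default 0.114). β = 4.5 puts the latent AUROC near 0.96, above
  the highest score target so calibration always degrades, never
  manufactures, discrimination.
- **Wound items:** each item sees U = (Z + σ·ε)/√(1+σ²) with item-specific
  noise σ and fresh ε ~ N(0,1), thresholded at the normal quantiles of its
  marginal level probabilities (ordered-threshold model). Ulcer area is
  log-normal, ln(area) = 2.53 + 1.80·U, matching extension bands of
  roughly 45% / 28% / 26% for <10 / 10–40 / >40 cm².
- **Marginals:** depth 36.6/16.9/46.5%, ischemia 59.7% any, IDSA infection
  26.7/30.1/35.9/7.3%, forefoot site 74.3%, inpatient fraction 31.9%, and
  minor amputation in 25.1% of non-major patients are the study cohort's
  descriptives. Marginals not published anywhere (gangrene 56.7/41.0/2.3%,
  osteomyelitis 25%, neuropathy 25/35/30/10%, edema 40/30/20/10%, SE
  anatomical items, healing phase 20/45/35%) were fixed once at clinically
  plausible referral-hospital values and are not tuning knobs.
- **Noise calibration:** six groups of items are tuned sequentially (UT
  depth → ischemia → infection → MW extras → SINBAD extras → SE extras),
  each by bisection on log σ against one pilot sample of 10 000 patients
  held fixed across evaluations (common random numbers make the pilot AUC
  a smooth decreasing function of σ). Default targets are AUROC 0.900
  (SE), 0.805 (MW), 0.802 (UT depth), 0.747 (SINBAD), 0.655 (ischemia),
  0.650 (infection); overall calibration tolerance ±0.02 with an inner
  bisection tolerance of 0.003. A discrete score has a structural AUC
  ceiling (the 3-level depth item caps near 0.80 — reaching 0.802 exactly
  would require every event to sit in the deepest level); a target within
  the tolerance of the ceiling is clamped at minimal noise, a target
  outside the attainable band raises `CalibrationError`. UT-3D is a
  deterministic function of depth, infection and ischemia, so its AUROC is
  emergent rather than separately calibrated.
- **Care setting:** with `events_inpatient_only` (default), every event
  patient is an inpatient and the remaining inpatient slots up to the
  31.9% fraction are filled by the most severe non-event patients (ranked
  by Z plus noise). This reproduces two qualitative features of the study:
  the outpatient stratum has zero events (stratified AUROC not
  calculable), and the inpatient stratum is severity-homogeneous, so every
  score's AUROC drops on restriction — spectrum bias as a directional
  property, not a numeric target.
- **Determinism:** all draws derive from `numpy.random.default_rng` seeded
  through a `SeedSequence` spawned from the config seed (calibration and
  generation use separate children), so a fixed config reproduces a
  byte-identical cohort across platforms.

### What the generator does not emulate

The single-latent model induces positive inter-score correlation but makes
no claim to match the real joint distribution of the ten SE items, the
real covariance of comorbidity covariates (which are not generated), ulcer
recurrence, or time-to-event structure (the outcome is a six-month
binary; follow-up times are decorative uniform draws ≥ 6 months). Passing
tests therefore demonstrate that the estimators are correct and that the
pipeline behaves properly on data with the assumed structure — not that
the real study's patient-level AUROCs are recoverable, which printed
tables do not permit.

## Problem sizes used in tests and the acceptance script

Calibration uses a 10 000-patient pilot; AUC recovery is checked at
n = 5000 (±0.02); DeLong CI coverage over 500 replicates of n = 342
against a truth estimated at n = 100 000 (band 92–98%); spectrum bias at
n = 3000; power at the study design (39 events, 303 non-events, 1000
replicates). These sizes keep every run deterministic-fast while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- The closed-form robust RR assumes the saturated one-exposure model; it
  is not a general GLM replacement.
- DeLong normal intervals are slightly anticonservative for AUROC near
  1 with few events (coverage ~93% at AUC 0.90 with 39 events — inside
  the accepted 92–98% band but below nominal); a logit-transformed
  interval would be closer to nominal at the cost of breaking the
  documented convention.
- Printed relative risks in the source tables that do not equal the
  closed-form ratio of their own printed counts (two rows differ in the
  final digit) are treated as unrecoverable fitting artifacts; this
  package reports the closed-form values.
- The generator's unpublished marginals are plausible but unverifiable;
  results that depend on them (e.g. exact calibrated noise scales) are
  conditional on those choices.
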