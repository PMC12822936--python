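# dfuvalid

External validation toolkit for diabetic foot ulcer (DFU) classification
systems. It implements, as tested reusable code, everything needed to ask:
*how well do the Meggitt–Wagner, University of Texas, SINBAD and Saint
Elian scores predict six-month major amputation in a cohort of patients
with diabetic foot ulcers?*

It is written for clinical epidemiologists and biostatisticians validating
prognostic wound scores: the scoring rules themselves, the discrimination
statistics, a synthetic cohort generator for end-to-end testing, and a CLI
pipeline.

## What it computes

**Classifiers** (deterministic, total functions on a typed wound record):

- **Meggitt–Wagner (MW)** — grades 0–5 on a most-severe-wins ladder:
  intact skin (0), superficial ulcer (1), tendon/capsule (2), deep ulcer
  with osteomyelitis or abscess (3), localized gangrene (4), extensive
  gangrene of the whole foot (5).
- **University of Texas (UT)** — depth grade 0–3 crossed with stage
  A (neither), B (infection), C (ischemia), D (both): 16 combinations.
  For discrimination the components are analysed as separate ordinal
  scores (depth, binary infection, binary ischemia, 3D-vs-other).
- **SINBAD** — one point each for Site (mid/hindfoot), Ischemia,
  Neuropathy, Bacterial infection, Area ≥ 1 cm², Depth beyond superficial;
  total 0–6.
- **Saint Elian (SE)** — ten items in three domains: anatomical (location,
  topography, affected zones; 1–3 points each), aggravating (ischemia,
  infection, edema, neuropathy; 0–3 each), contributing (depth, area
  <10 / 10–40 / >40 cm², healing phase; 1–3 each); total 6–30, banded
  mild (≤10) / moderate (11–20) / severe (21–30).

**Statistics** (in `dfuvalid.stats`): the six-month cumulative incidence
with exact Clopper–Pearson intervals; banded relative risks

    RR = (e_band / n_band) / (e_ref / n_ref),
    se(log RR) = sqrt(1/e_band − 1/n_band + 1/e_ref − 1/n_ref)

(the robust Poisson sandwich standard error, in closed form for a saturated
categorical exposure, with "not calculable" propagated for zero-event
bands); the tie-aware AUROC as the Mann–Whitney pair statistic
`[#(pos>neg) + ½#(pos=neg)] / (m·n)` with DeLong placement-value standard
errors; the DeLong test for two correlated ROC curves; full threshold
sweeps with sensitivity/specificity/PPV/NPV/LR±, the Youden index
J = sens + spec − 1, and Youden-optimal cut-off selection; care-setting
stratified AUROC with explicit incalculable markers for zero-event strata;
and Monte-Carlo power for paired AUROC comparisons under a correlated
binormal model.

**Synthetic cohorts** (in `dfuvalid.simulate`): one latent severity per
patient drives both the outcome (logistic link, intercept root-found to
the target incidence) and all wound items (ordered-threshold model with
per-item noise). Per-item noise is calibrated by bisection so each system's
score attains a configured AUROC; by default every event is an inpatient,
so the outpatient stratum reproduces the classic not-calculable case and
restriction to inpatients exhibits spectrum bias.

## Worked example

Score the bundled 12-patient example cohort:

```
dfuvalid score --in examples/cohort_example.csv --out scores.tsv
```

```
patient_id  mw_grade  ut_class  sinbad_total  se_total  se_severity  ...
P01         0         0A        0             6         mild
P02         1         1A        1             6         mild
P03         2         2A        4             11        moderate
P06         5         3D        6             30        severe
P07         2         3D        5             21        severe
P09         1         1C        2             10        mild
P10         4         3D        5             25        severe
```

P06 is the worst-case wound: whole-foot gangrene (Wagner 5), bone-deep
infected ischemic ulcer (UT 3D), every SINBAD item adverse (6/6), and the
Saint Elian maximum of 30 (severe). P09 shows the SE band edge: a total of
exactly 10 is still "mild". Run the full analysis:

```
dfuvalid validate --config examples/run_example.yaml
```

which writes `report.json` plus TSV tables. The AUROC table for this tiny
cohort (3 major amputations, all inpatients) reads:

```
score        auroc   auroc_95ci   band       stratum_1                        stratum_2
se           1.000   1.000-1.000  excellent  inpatient: 1.000 (1.000-1.000)   outpatient: NC (no events in stratum)
mw           0.852   0.588-1.000  good       inpatient: 0.667 (0.133-1.000)   outpatient: NC (no events in stratum)
sinbad       0.926   0.806-1.000  excellent  inpatient: 0.889 (0.645-1.000)   outpatient: NC (no events in stratum)
```

Here the Saint Elian total separates the three amputated patients
perfectly (AUROC 1.0), the outpatient stratum has no events so its AUROC
is reported as not calculable rather than as a number, and the inpatient
AUROCs sit below the overall ones — the spectrum-bias pattern that the
synthetic generator reproduces at scale.

A library-level session looks like:

```python
from dfuvalid import SimulationConfig, generate_cohort, roc_auc, SCORE_VARIANTS

cohort = generate_cohort(SimulationConfig(seed=1))          # n=342, 11.4% incidence
events = [o.major_amputation for o in cohort.outcomes]
scores = [SCORE_VARIANTS["se"](w) for w in cohort.wounds]
print(roc_auc(scores, events).auc)                          # ~0.90
```

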