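# Methods

## Model and assumptions

The longitudinal score treats a subject's repeated measurements of one
continuous variable as noisy observations of a slowly varying (ideally
stationary) subject-level trajectory. The plausibility of observation
yᵢ at time tᵢ is judged against a time-decayed EWMA of the *entire*
sequence (including yᵢ itself), with weights wⱼ = exp(−|tⱼ − tᵢ|/τ) and
wᵢ = 1. Same-timestamp neighbors receive weight exp(0) = 1, identical to
the self weight; no special-casing.

The deviation dᵢ = |yᵢ − ȳᵢ| is standardized under two assumptions: the
measurements are mutually independent given the trajectory, and share a
common within-subject variance Var(y). Under those assumptions
ȳᵢ − yᵢ is a linear combination of independent variables, so

    Var(dᵢ) = ( Σⱼwⱼ²/W² − 2wᵢ/W + 1 ) · Var(y),   W = Σⱼwⱼ,

which is exact, nonnegative (it equals Σ_{j≠i} wⱼ²/W² + (wᵢ/W − 1)²), and
shrinks as informative neighbors accumulate. Z = dᵢ/SE(dᵢ) is then exactly
half-normal under the null, so Q_R = 2(1 − Φ(Z)) is exactly uniform — the
calibration the test suite verifies by simulation.

A second variance variant (`variance_variant="paper"`) replaces the minus
cross term with a plus: Σwⱼ²/W² **+** 2wᵢ/W + 1. This is the form printed
in the literature this method derives from, kept available for literal
reproduction. Direct expansion of Var(ȳᵢ − yᵢ) under the stated
independence assumption yields the minus sign, and Monte-Carlo simulation
(tests) confirms the minus-sign factor and rejects the plus-sign one at
3 MC standard errors, so `derived` is the default. The plus variant is
conservative: its factor exceeds 1, its SE grows with the number of
neighbors, and its null flag rate is far below nominal.

Both scores are invariant to the measurement unit (scaling values and
variance together) and to the time origin (only intervals enter).

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| τ (height) | years | 9.49 | heuristic τ = −(ξ/12)/ln ω with ω = 0.9, ξ = 12 months: adult height is stable, so a neighbor a year away deserves 90% weight |
| τ (weight) | years | 0.5 | validation-optimized value; the heuristic at ω = 0.9, ξ = 0.5 months gives 0.4, but the optimized 0.5 ships |
| Var(y) (weight) | lb² | 210 | validation-optimized value |
| Var(y) (height) | in² | estimated from input | no validated value exists; see below |
| cutoff | p-value | 0.05 | conventional two-sided level; 0.01 for stricter QA |
| plausible range | native | 40–100 in, 40–1000 lb | record-level eligibility, inclusive bounds |
| min age | years | 17 | adult-cohort eligibility (height stability assumption) |
| max same-day | count | 3 | days with more measurements are treated as entry errors and dropped whole |
| subject cutoff | proportion | 0.20 | subject flagged when *more than* this fraction of its records is flagged (strict) |
| reference μ, σ (Q_S) | native | 69 ± 3 in, 185 ± 35 lb | prespecified typical-adult statistics; see below |

**Height Var(y).** When `var_y` is null, the pipeline estimates it from the
data being scored with the one-way random-effects (subject as random
intercept) within-subject variance component, using the closed-form ANOVA
method-of-moments estimator — the pooled within-subject mean square
Σⱼ Σᵢ (yᵢⱼ − ȳⱼ)² / Σⱼ (nⱼ − 1). A method-of-moments estimator is used
rather than a likelihood fit because it is deterministic and closed-form,
which is adequate for a tuning constant. Note the estimate absorbs whatever
errors the data contains; this inflates it and makes the score
*conservative* — gross errors remain many SEs out and stay flagged, while
their clean neighbors (whose EWMAs the error has shifted) do not breach the
inflated SE. For weight this safety margin is instead provided by the
validated Var(y) = 210 lb², which is well above the visit-to-visit noise of
a stable subject.

**Thresholding reference.** The comparator score ships with *prespecified*
reference statistics rather than refitting μ, σ to each input: thresholding
QA as practiced uses fixed plausible-range/norm tables, and a cohort-fitted
SD absorbs both heavy/light subpopulations and the very errors under test,
silently changing what the comparator means. `estimate_reference_stats`
(optionally stratified) is available when fitting is wanted explicitly.

**Scoring requires ≥ 2 measurements.** Single-measurement subjects receive
an undefined score, are never flagged, and are excluded from both the
numerator and denominator of subject-level proportions.

## Synthetic cohorts

The generator emulates the data structure the score assumes: per-subject
stable adult height (Gaussian baselines, 69 ± 3 in); baseline weight drawn
from a 75/25 mixture of a lean component N(180, 28) and an obese component
N(240, 50) — adult weight distributions are right-skewed, and the genuinely
heavy subjects this produces are precisely the failure mode of population
thresholding (their consistent records all sit > 2 reference SDs out);
weight drifting as a Gaussian random walk (4 lb/√year); irregular visits
from an exponential renewal process (2/year height, 3/year weight) over
12 ± 5 years of follow-up starting around age 55; observation = trajectory
+ N(0, within-SD) with within-SD 0.6 in and √210 lb; times rounded to day
precision. Subject trajectories are drawn from per-subject substreams keyed
by (seed, subject index), so cohorts are reproducible and subject k is
identical across cohort sizes.

A configurable fraction of records (default 5%) is corrupted by one of:
unit conversion (×/÷ 2.54 for height, ×/÷ 2.2046 for weight), digit error
(transpose/drop/duplicate a digit), gross outlier (uniform over the
plausible range), or wrong-patient substitution (another subject's value).
The default mix (0.35/0.25/0.25/0.15 wrong-patient/unit/digit/gross) leans
toward errors that resemble plausible values — the kind range checks cannot
catch. Every corruption is recorded with its mechanism and original value.

What the cohorts do **not** emulate: real visit clustering (inpatient
episodes), informative observation (sicker patients measured more),
measurement-device autocorrelation, demographic structure, secular trends,
or true clinical weight-change events (the score flags a genuine sudden
loss exactly as it flags an error — on real data a flag means "inconsistent
with history", not "wrong"). Passing tests therefore demonstrate the
statistical behavior of the scores under their stated assumptions plus
realistic error mechanisms, not performance on any particular health
system's data, whose absolute FPR/power depend on its actual error mix and
magnitudes.

## Numerical and design choices

- Two-sided p-values are computed as 2·Φ̄(|Z|); for Q_R the absolute value
  is redundant (d ≥ 0) but applied defensively, and for Q_S it is required —
  the signed form would exceed 1 for below-mean values.
- A reference SD of 0 is rejected (configuration error) rather than
  producing infinite Z.
- Range and age bounds are inclusive ("within 40 and 100" keeps 40 and 100;
  "at least 17" keeps 17.0).
- The same-day rule groups times within 0.5/365.25 years and removes *all*
  records of a day exceeding the count limit: such days indicate entry
  errors with no way to designate a surviving record.
- Same-day BMI pairing produces one BMI per weight record per day; among
  multiple same-day heights the smallest record id wins, making the output
  invariant to input order.
- BMI = 703·lb/in²; classes split at 18.5, 30 and 40 kg/m² with
  left-inclusive boundaries; "ever in class" counts a subject once per
  class, so proportions across classes need not sum to 1.
- Subject-level flagging uses a strict inequality ("more than 20%"), so
  exactly 20% flagged is not flagged; the flagged set is nonincreasing in
  the cutoff.
- The ROC sweep calls a record positive at q ≤ cutoff over a grid that
  always contains 0.01 and 0.05, anchors the curve at (0,0) and (1,1), and
  integrates by trapezoid; it agrees with rank-based AUC on continuous
  scores (cross-checked in tests).
- The τ×Var(y) sweep selects max power subject to FDR ≤ 0.25 (FDR =
  1 − PPV); when no grid point meets the bound it reports the minimum-FDR
  point and says so. Ties break toward smaller FDR, then smaller (τ, Var).
- Evaluation excludes preprocessing-removed records: the harness measures
  the scores, not the range filter.
- CSV round trips render floats with `repr`, so write-then-read is
  bit-exact.

## Known limitations

- The independence assumption ignores measurement-error autocorrelation;
  runs of correlated errors (a miscalibrated scale over months) inflate the
  EWMA toward the errors and lower power against them.
- A gross error still shifts its neighbors' EWMAs; with a small τ and
  sparse visits this can flag adjacent clean records. Inflated Var(y)
  (weight's 210, or height's data-estimated value) damps but does not
  eliminate this.
- The score presumes near-stationary trajectories. Variables with genuine
  fast dynamics (inpatient blood pressure) violate the model; flags there
  are not interpretable as data errors.
- The evaluation metrics on synthetic cohorts depend on the injected error
  mix; they are meant for comparing scoring variants and tuning, not as
  forecasts of real-data operating characteristics.

## Problem sizes

Default test and example cohorts use 100–400 subjects (≈6k–25k records),
null-calibration checks use 1,000 subjects, and Monte-Carlo variance checks
use 20 weight configurations × 10⁵ replicates — sizes at which every
stochastic assertion has comfortable margin while the full suite runs in
about a minute.
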