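# ehrqa — longitudinal plausibility scoring for continuous EHR measurements

Routine EHR vitals (height, weight, and other slowly varying continuous
variables) carry unit mix-ups, transcription slips, and wrong-patient
entries. The standard defense — flagging values outside a prespecified
plausible range or population threshold — judges each value in isolation,
so it wholesale-flags the consistent records of genuinely heavy or light
patients while passing an in-range value that is wildly inconsistent with
the patient's own history. `ehrqa` implements a *temporal* plausibility
score that judges each measurement against the patient's longitudinal
record, for data scientists and epidemiologists preparing EHR extracts for
research use.

## The scores

For a subject's measurements y₁…yₙ at times t₁…tₙ (decimal years), the
longitudinal score of observation *i* uses a time-decayed exponentially
weighted moving average over the whole sequence,

    ȳᵢ = Σⱼ wⱼ yⱼ / Σⱼ wⱼ,   wⱼ = 1 if j = i, else exp(−|tⱼ − tᵢ|/τ),

with deviation dᵢ = |yᵢ − ȳᵢ|. Assuming independent measurements with
within-subject variance Var(y), Var(dᵢ) = (Σwⱼ²/W² − 2wᵢ/W + 1)·Var(y)
with W = Σwⱼ, giving a Z score and a two-sided normal p-value

    Q_R,ᵢ = 2(1 − Φ(dᵢ / SE(dᵢ))).

Small Q_R marks a value implausible *given the patient's history*. The decay
scale τ comes from a heuristic: to put dependency ω on neighbors ξ months
away, τ = −(ξ/12)/ln ω (ω = 0.9 at ξ = 12 months gives τ = 9.49 years for
height; weight ships with the validation-optimized τ = 0.5, Var(y) = 210 lb²).

The comparator thresholding score is atemporal: Q_S = 2(1 − Φ(|y − μ|/σ))
against population reference statistics μ, σ. Records are flagged at
Q ≤ cutoff (0.05 by default); subjects with more than a configurable
proportion of flagged records (20%, 50%) are flagged as a whole.

The package also ships a labeled synthetic-cohort generator (stable heights,
drifting weights, irregular visits, injected unit/digit/gross/wrong-patient
errors), an evaluation harness (FPR, power, PPV/NPV, ROC/AUC, τ×Var(y)
sweeps), and a BMI use case (same-day pairing, WHO-based classes, ever-in-
class proportions under each QA regime).

## Worked example

```sh
ehrqa simulate --n-subjects 200 --seed 0 --out records.csv --labels labels.csv
ehrqa score --input records.csv --subject-cutoff 0.2 --output scored.csv
ehrqa evaluate --records records.csv --labels labels.csv --cutoff 0.05 --out metrics.csv
```

`scored.csv` appends the per-record columns
`ewma,d,se_d,z_r,q_r,z_s,q_s,flag_r,flag_s` to the input. `metrics.csv`
compares both scores against the injected-error labels:

```
   method  cutoff  tp   fp    tn  fn   fpr  power   ppv   npv   auc
     ewma    0.05 295  787 10910 140 0.067  0.678 0.273 0.987 0.869
threshold    0.05 211 1158 10539 224 0.099  0.485 0.154 0.979 0.715
```

The longitudinal score dominates the thresholding comparator: higher AUC
(0.87 vs 0.72) and, at the 0.05 cutoff, simultaneously lower false-positive
rate (6.7% vs 9.9%) and higher power (68% vs 49%). The thresholding false
positives are concentrated on the cohort's genuinely heavy subjects, whose
perfectly consistent records sit far from the population mean; the
longitudinal misses are mostly wrong-patient values close to the subject's
own trajectory.

Downstream impact on BMI classification:

```sh
ehrqa bmi --input records.csv --output bmi_raw.csv
ehrqa bmi --input records.csv --scores scored.csv --regime longitudinal --output bmi_qa.csv
```

```
ever obese_III: 11.11%    # no QA — inflated by unit-conversion errors
ever obese_III: 6.67%     # after longitudinal QA
```

A small fixture cohort and a config template live in `examples/`
(`records.csv`, `labels.csv`, `vars.yaml`); per-variable settings (τ,
Var(y), plausible range, reference mean/SD, cutoff) are YAML blocks passed
via `--config`.

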