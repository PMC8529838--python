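"""Labeled synthetic longitudinal height/weight cohorts with injected errors.

The generator emulates the statistical structure the longitudinal score
assumes: each subject has a stable true adult height and a weight that
drifts slowly (baseline plus Gaussian random walk in time); visits arrive
irregularly as a renewal process over roughly a decade of follow-up; each
observation is truth plus independent Gaussian measurement noise.  A known
fraction of records is then corrupted by one of four realistic mechanisms —
unit conversion (cm recorded as inches, kg as pounds or vice versa), digit
errors (transposition, dropped or doubled digit), gross outliers (uniform
over the plausible range), and wrong-patient values — and every corruption
is recorded in a ground-truth label, so flagging performance can be
evaluated without any external data.

Unit-conversion errors are the interesting ones: on heavy or short subjects
they often land *inside* the plausible range, where only the subject's own
history can reveal them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .records import MeasurementRecord

__all__ = ["CohortSpec", "ErrorModel", "ErrorLabel", "ErrorMechanism", "generate_cohort"]


class ErrorMechanism(str, Enum):
    UNIT = "unit_error"
    DIGIT = "digit_error"
    GROSS = "gross_outlier"
    WRONG_PATIENT = "wrong_patient"


@dataclass(frozen=True)
class ErrorLabel:
    """Ground-truth annotation of one record."""

    record_id: str
    is_error: bool
    mechanism: ErrorMechanism | None = None
    original_value: float | None = None

    def __post_init__(self) -> None:
        if self.is_error != (self.mechanism is not None):
            raise ValueError("is_error must hold exactly when a mechanism is present")


@dataclass(frozen=True)
class ErrorModel:
    """Corruption rate and mechanism mix.

    ``rate`` is the fraction of records corrupted; ``mix`` gives the
    relative probability of each mechanism (normalized to sum to 1).
    """

    rate: float = 0.05
    mix: dict = field(
        default_factory=lambda: {
            ErrorMechanism.WRONG_PATIENT: 0.35,
            ErrorMechanism.UNIT: 0.25,
            ErrorMechanism.DIGIT: 0.25,
            ErrorMechanism.GROSS: 0.15,
        }
    )

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError(f"rate must be in [0,1), got {self.rate}")
        total = sum(self.mix.values())
        if not total > 0:
            raise ValueError("mechanism mix must have positive total probability")
        object.__setattr__(
            self, "mix", {ErrorMechanism(k): v / total for k, v in self.mix.items()}
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    Follow-up defaults to 12 +/- 5 years with about 2 height and 3 weight
    measurements per year, mirroring a large adult primary-care cohort.
    Heights are stable over adult follow-up; weights drift as a random walk
    with scale ``weight_drift_sd`` pounds per sqrt(year).  Within-subject
    measurement SDs default to 0.6 in (height) and sqrt(210) lb (weight,
    matching the weight score's default variance constant).

    Baseline heights are Gaussian.  Baseline weights are a two-component
    mixture — a lean majority and an obese subpopulation
    (``obese_fraction``, shifted by ``obese_shift`` pounds with a wider
    component SD) — because adult weight distributions are right-skewed
    with genuinely heavy subjects whose perfectly consistent values sit far
    from the population mean.  ``weight_mean``/``weight_sd`` parameterize
    the marginal scale: component means are placed so the mixture mean is
    ``weight_mean``, and component SDs are 0.7x / 1.25x ``weight_sd``
    (marginal SD comes out slightly above ``weight_sd``).
    """

    n_subjects: int = 200
    followup_mean: float = 12.0
    followup_sd: float = 5.0
    visits_per_year: dict = field(
        default_factory=lambda: {"height": 2.0, "weight": 3.0}
    )
    height_mean: float = 69.0
    height_sd: float = 3.0
    weight_mean: float = 195.0
    weight_sd: float = 40.0
    obese_fraction: float = 0.25
    obese_shift: float = 60.0
    within_sd: dict = field(
        default_factory=lambda: {"height": 0.6, "weight": math.sqrt(210.0)}
    )
    weight_drift_sd: float = 4.0  # lb per sqrt(year)
    baseline_age_mean: float = 55.0
    baseline_age_sd: float = 12.0
    min_age: float = 18.0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, sd in [
            ("followup_sd", self.followup_sd),
            ("height_sd", self.height_sd),
            ("weight_sd", self.weight_sd),
            ("weight_drift_sd", self.weight_drift_sd),
        ]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


#: Plausible ranges used by the gross-outlier mechanism.
_PLAUSIBLE = {"height": (40.0, 100.0), "weight": (40.0, 1000.0)}

_UNIT_FACTORS = {
    # height recorded in cm as if inches (x2.54) or converted the wrong way
    "height": (2.54, 1 / 2.54),
    # weight kg<->lb confusion
    "weight": (2.2046, 1 / 2.2046),
}


def _visit_times(rng: np.random.Generator, start: float, span: float, rate: float) -> np.ndarray:
    """Irregular visit ages: exponential renewal process at `rate`/year."""
    if span <= 0 or rate <= 0:
        return np.array([start])
    n_max = max(2, int(rate * span * 4) + 8)
    gaps = rng.exponential(1.0 / rate, size=n_max)
    t = start + np.cumsum(gaps)
    t = t[t <= start + span]
    if len(t) == 0:
        t = np.array([start + rng.uniform(0, span)])
    return np.round(t * 365.25) / 365.25  # day precision, like real EHR stamps


def _digit_error(rng: np.random.Generator, value: float) -> float:
    """Transpose two adjacent digits, or drop/duplicate one digit."""
    s = f"{value:.1f}"
    digits = [c for c in s if c.isdigit()]
    if len(digits) < 2:
        return value * 10.0
    kind = rng.integers(0, 3)
    i = int(rng.integers(0, len(digits) - 1))
    if kind == 0:  # transpose
        digits[i], digits[i + 1] = digits[i + 1], digits[i]
    elif kind == 1:  # drop
        del digits[i]
    else:  # duplicate
        digits.insert(i, digits[i])
    # reassemble keeping the decimal point position from the right
    dec = len(s) - s.index(".") - 1 if "." in s else 0
    txt = "".join(digits)
    if dec:
        txt = (txt[:-dec] or "0") + "." + txt[-dec:]
    try:
        out = float(txt)
    except ValueError:
        return value * 10.0
    return out if out != value else value * 10.0


def _corrupt(
    rng: np.random.Generator,
    mechanism: ErrorMechanism,
    variable: str,
    value: float,
    donor_pool: Sequence[float],
) -> float:
    if mechanism is ErrorMechanism.UNIT:
        factors = _UNIT_FACTORS[variable]
        return value * factors[int(rng.integers(0, len(factors)))]
    if mechanism is ErrorMechanism.DIGIT:
        return _digit_error(rng, value)
    if mechanism is ErrorMechanism.GROSS:
        low, high = _PLAUSIBLE.get(variable, (value * 0.1, value * 10))
        return float(rng.uniform(low, high))
    # wrong patient: another subject's concurrent value
    if len(donor_pool) == 0:
        low, high = _PLAUSIBLE.get(variable, (value * 0.1, value * 10))
        return float(rng.uniform(low, high))
    return float(donor_pool[int(rng.integers(0, len(donor_pool)))])


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[MeasurementRecord], list[ErrorLabel]]:
    """Generate a labeled synthetic cohort.

    Fully reproducible from ``spec.seed``: each subject draws from a
    deterministic substream keyed by (seed, subject index), so cohorts are
    stable under changes to ``n_subjects`` — subject k is identical in a
    100- and a 1000-subject cohort.  Error injection uses a separate stream
    so the clean trajectories do not depend on the error model.
    """
    records: list[MeasurementRecord] = []
    clean_values: dict[str, list[float]] = {"height": [], "weight": []}

    for k in range(spec.n_subjects):
        srng = np.random.default_rng([spec.seed, 1, k])
        sid = f"S{k:06d}"
        height_true = srng.normal(spec.height_mean, spec.height_sd)
        lean_mean = spec.weight_mean - spec.obese_fraction * spec.obese_shift
        if srng.uniform() < spec.obese_fraction:
            weight_base = srng.normal(lean_mean + spec.obese_shift, 1.25 * spec.weight_sd)
        else:
            weight_base = srng.normal(lean_mean, 0.7 * spec.weight_sd)
        start = max(spec.min_age, srng.normal(spec.baseline_age_mean, spec.baseline_age_sd))
        span = max(0.5, srng.normal(spec.followup_mean, spec.followup_sd))

        for variable in ("height", "weight"):
            rate = spec.visits_per_year.get(variable, 2.0)
            times = _visit_times(srng, start, span, rate)
            n = len(times)
            if variable == "height":
                truth = np.full(n, height_true)
            else:
                # Brownian drift: independent increments over visit gaps
                gaps = np.diff(times, prepend=times[0])
                walk = np.cumsum(
                    srng.normal(0.0, spec.weight_drift_sd * np.sqrt(np.maximum(gaps, 0)))
                )
                truth = weight_base + walk
            obs = truth + srng.normal(0.0, spec.within_sd[variable], size=n)
            for j, (t, v) in enumerate(zip(times, obs)):
                rid = f"{sid}:{variable[0]}{j}"
                records.append(
                    MeasurementRecord(
                        subject_id=sid, variable=variable,
                        time=float(t), value=float(v), record_id=rid,
                    )
                )
                clean_values[variable].append(float(v))

    # error injection pass — separate stream, independent of trajectories
    erng = np.random.default_rng([spec.seed, 2])
    em = spec.error_model
    mechanisms = list(em.mix)
    probs = np.array([em.mix[m] for m in mechanisms])
    labels: list[ErrorLabel] = []
    out_records: list[MeasurementRecord] = []
    for rec in records:
        if em.rate > 0 and erng.uniform() < em.rate:
            mech = mechanisms[int(erng.choice(len(mechanisms), p=probs))]
            new_value = _corrupt(erng, mech, rec.variable, rec.value, clean_values[rec.variable])
            out_records.append(replace(rec, value=new_value))
            labels.append(
                ErrorLabel(
                    record_id=rec.record_id, is_error=True,
                    mechanism=mech, original_value=rec.value,
                )
            )
        else:
            out_records.append(rec)
            labels.append(ErrorLabel(record_id=rec.record_id, is_error=False))
    return out_records, labels


def labels_to_frame(labels: Sequence[ErrorLabel]):
    """Labels as a DataFrame (record_id, is_error, mechanism, original_value)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": [l.record_id for l in labels],
            "is_error": [l.is_error for l in labels],
            "mechanism": [l.mechanism.value if l.mechanism else "" for l in labels],
            "original_value": [
                l.original_value if l.original_value is not None else np.nan
                for l in labels
            ],
        }
    )
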