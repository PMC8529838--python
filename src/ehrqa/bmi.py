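"""BMI use case: same-day height/weight pairing, WHO-based classes, and
"ever in class" cohort proportions under different QA regimes.

BMI is computed from inch/pound pairs measured on the same day as
``703 * weight / height**2`` (kg/m²) and bucketed into four non-exclusive
"ever" classes: underweight (< 18.5), normal-to-overweight ([18.5, 30)),
obese I/II/III ([30, 40)) and obese III (>= 40).  A subject counts once per
class regardless of how many of their records fall in it, so proportions
across classes need not sum to 1.

A QA regime drops pairs before classification: ``threshold`` drops a pair
when either component's Q_S is at or below the cutoff, ``longitudinal``
does the same with Q_R, ``none`` keeps everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .preprocess import DAY_TOLERANCE
from .records import SubjectSeries

__all__ = [
    "BmiClass", "QaRegime", "BmiPair", "pair_same_day", "compute_bmi",
    "classify_bmi", "ever_in_class", "ever_proportions", "qa_regime_filter",
]

LB_IN2_TO_KG_M2 = 703.0


class BmiClass(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL_TO_OVERWEIGHT = "normal_to_overweight"
    OBESE_I_II_III = "obese_I_II_III"
    OBESE_III = "obese_III"


class QaRegime(str, Enum):
    NONE = "none"
    THRESHOLD = "threshold"
    LONGITUDINAL = "longitudinal"


@dataclass(frozen=True)
class BmiPair:
    """A same-day height/weight pair with its derived BMI."""

    subject_id: str
    time: float
    height_record_id: str
    weight_record_id: str
    height: float  # inches
    weight: float  # pounds
    bmi: float     # kg/m^2


def compute_bmi(height_in: float, weight_lb: float) -> float:
    """BMI in kg/m² from height in inches and weight in pounds."""
    if not height_in > 0:
        raise ValueError(f"height must be positive, got {height_in}")
    return LB_IN2_TO_KG_M2 * weight_lb / height_in**2


def classify_bmi(bmi: float) -> BmiClass:
    """WHO-based class of a BMI value (disjoint intervals, boundaries
    inclusive on the left: 18.5, 30 and 40)."""
    if not (math.isfinite(bmi) and bmi > 0):
        raise ValueError(f"bmi must be finite and positive, got {bmi}")
    if bmi < 18.5:
        return BmiClass.UNDERWEIGHT
    if bmi < 30:
        return BmiClass.NORMAL_TO_OVERWEIGHT
    if bmi < 40:
        return BmiClass.OBESE_I_II_III
    return BmiClass.OBESE_III


def _in_class(bmi: float, cls: BmiClass) -> bool:
    # classes are disjoint intervals; "ever" non-exclusivity arises only
    # across a subject's multiple records
    return classify_bmi(bmi) is cls


def pair_same_day(
    height_series: SubjectSeries,
    weight_series: SubjectSeries,
    day_tolerance: float = DAY_TOLERANCE,
) -> list[BmiPair]:
    """Pair each weight record with a same-day height record.

    One BMI per (weight record, day): when several heights survived on the
    day, the first by record_id is used — a deterministic tie-break that
    makes the result invariant to input ordering.
    """
    if height_series.subject_id != weight_series.subject_id:
        raise ValueError("height and weight series belong to different subjects")
    pairs: list[BmiPair] = []
    for k in range(len(weight_series)):
        t_w = weight_series.times[k]
        same_day = [
            j for j in range(len(height_series))
            if abs(height_series.times[j] - t_w) <= day_tolerance
        ]
        if not same_day:
            continue
        j = min(same_day, key=lambda j: height_series.record_ids[j])
        h = float(height_series.values[j])
        w = float(weight_series.values[k])
        pairs.append(
            BmiPair(
                subject_id=weight_series.subject_id,
                time=float(t_w),
                height_record_id=height_series.record_ids[j],
                weight_record_id=weight_series.record_ids[k],
                height=h,
                weight=w,
                bmi=compute_bmi(h, w),
            )
        )
    return pairs


def qa_regime_filter(
    pairs: Sequence[BmiPair],
    scores: Mapping[str, Mapping[str, float]],
    regime: QaRegime | str = QaRegime.NONE,
    cutoff: float = 0.05,
) -> list[BmiPair]:
    """Keep pairs that survive the chosen QA regime.

    ``scores`` maps record_id -> {"q_r": ..., "q_s": ...} (either key may be
    absent when that score was not computed).  Regime ``none`` keeps all;
    ``threshold`` drops a pair when either component's q_s <= cutoff;
    ``longitudinal`` the same with q_r.  A record with an undefined (NaN or
    missing) score is never dropped by it.
    """
    regime = QaRegime(regime)
    if regime is QaRegime.NONE:
        return list(pairs)
    key = "q_s" if regime is QaRegime.THRESHOLD else "q_r"

    def q_of(rid: str) -> float:
        try:
            q = scores[rid][key]
        except KeyError:
            raise KeyError(
                f"regime {regime.value!r} requested but no {key} score for record {rid!r}"
            ) from None
        return q

    kept = []
    for p in pairs:
        qs = (q_of(p.height_record_id), q_of(p.weight_record_id))
        if any(not math.isnan(q) and q <= cutoff for q in qs):
            continue
        kept.append(p)
    return kept


def ever_in_class(bmis: Sequence[float], cls: BmiClass) -> bool:
    """Whether any of a subject's BMI values falls in the class."""
    return any(_in_class(b, cls) for b in bmis)


def ever_proportions(
    pairs_by_subject: Mapping[str, Sequence[BmiPair]] | Iterable[tuple[str, Sequence[BmiPair]]],
) -> dict[BmiClass, float]:
    """Cohort proportion of subjects who ever had a BMI in each class.

    Subjects with no usable pairs are excluded from the denominator.
    Proportions are non-exclusive across classes and need not sum to 1.
    """
    items = pairs_by_subject.items() if isinstance(pairs_by_subject, Mapping) else pairs_by_subject
    counts = {cls: 0 for cls in BmiClass}
    n_subjects = 0
    for _, pairs in items:
        if not pairs:
            continue
        n_subjects += 1
        bmis = [p.bmi for p in pairs]
        for cls in BmiClass:
            if ever_in_class(bmis, cls):
                counts[cls] += 1
    if n_subjects == 0:
        raise ValueError("no subject with a usable BMI pair")
    return {cls: counts[cls] / n_subjects for cls in BmiClass}
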