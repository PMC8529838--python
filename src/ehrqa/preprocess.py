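"""Record-level eligibility filters applied before scoring.

Three rules: a plausible-range filter (inclusive bounds), a minimum-age
filter (record time must encode age for this to be meaningful), and a
same-day rule that removes *all* measurements of a day on which a variable
was recorded more than ``max_same_day`` times — such days are treated as
likely data-entry errors with no designated survivor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import DAYS_PER_YEAR, MeasurementRecord, SubjectSeries

#: Times closer than this (in years) belong to the same day when times are
#: recorded to day precision.
DAY_TOLERANCE = 0.5 / DAYS_PER_YEAR


@dataclass(frozen=True)
class RangeRule:
    """Plausible-range and eligibility parameters for one variable."""

    variable: str
    low: float
    high: float
    min_age: float = 17.0
    max_same_day: int = 3

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.variable}: low must be < high")
        if self.max_same_day < 1:
            raise ValueError(f"{self.variable}: max_same_day must be >= 1")


def apply_range_filter(
    records: Iterable[MeasurementRecord], rule: RangeRule
) -> tuple[list[MeasurementRecord], list[MeasurementRecord]]:
    """Partition records into (kept, removed) by the inclusive plausible range."""
    kept, removed = [], []
    for r in records:
        (kept if rule.low <= r.value <= rule.high else removed).append(r)
    return kept, removed


def apply_age_filter(
    records: Iterable[MeasurementRecord], min_age: float
) -> tuple[list[MeasurementRecord], list[MeasurementRecord]]:
    """Partition records into (kept, removed) by minimum age in years.

    Record time must encode age for the filter to be meaningful.
    """
    kept, removed = [], []
    for r in records:
        (kept if r.time >= min_age else removed).append(r)
    return kept, removed


def _same_day_groups(times: np.ndarray, day_tolerance: float) -> list[list[int]]:
    """Chain sorted times into groups of same-day indices."""
    groups: list[list[int]] = []
    for i in range(len(times)):
        if groups and times[i] - times[groups[-1][-1]] <= day_tolerance:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def apply_same_day_rule(
    series: SubjectSeries,
    max_same_day: int = 3,
    day_tolerance: float = DAY_TOLERANCE,
) -> tuple[SubjectSeries | None, list[str]]:
    """Remove whole days with more than ``max_same_day`` measurements.

    Returns the filtered series (None when nothing survives) and the list of
    removed record_ids.  Exactly ``max_same_day`` measurements on a day are
    allowed; only days exceeding it are dropped, all records of that day.
    """
    groups = _same_day_groups(series.times, day_tolerance)
    keep_idx: list[int] = []
    removed: list[str] = []
    for g in groups:
        if len(g) > max_same_day:
            removed.extend(series.record_ids[i] for i in g)
        else:
            keep_idx.extend(g)
    if not keep_idx:
        return None, removed
    return (
        SubjectSeries(
            subject_id=series.subject_id,
            variable=series.variable,
            times=series.times[keep_idx],
            values=series.values[keep_idx],
            record_ids=[series.record_ids[i] for i in keep_idx],
        ),
        removed,
    )


def preprocess_records(
    records: Sequence[MeasurementRecord],
    rule: RangeRule,
    day_tolerance: float = DAY_TOLERANCE,
) -> tuple[list[MeasurementRecord], list[str]]:
    """Apply range, age, and same-day rules; return (kept records, removed ids).

    Range and age act record-wise; the same-day rule acts per subject on the
    time-sorted survivors.
    """
    from .records import group_series

    subset = [r for r in records if r.variable == rule.variable]
    kept, removed = apply_range_filter(subset, rule)
    kept, removed_age = apply_age_filter(kept, rule.min_age)
    removed_ids = [r.record_id for r in removed + removed_age]
    out: list[MeasurementRecord] = []
    for series in group_series(kept):
        filtered, dropped = apply_same_day_rule(series, rule.max_same_day, day_tolerance)
        removed_ids.extend(dropped)
        if filtered is not None:
            by_id = {r.record_id: r for r in kept}
            out.extend(by_id[rid] for rid in filtered.record_ids)
    return out, removed_ids
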