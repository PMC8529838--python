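"""Long-format measurement records and their CSV dialect.

One row = one observation of one continuous variable on one subject at one
time.  Time is a decimal number of years (the scoring depends only on time
*intervals*, so any origin works; age in years is the conventional choice).
Values are in the variable's native unit (inches for height, pounds for
weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default column names of the CSV dialect.
DEFAULT_SCHEMA: dict[str, str] = {
    "subject_id": "subject_id",
    "variable": "variable",
    "time": "time",
    "value": "value",
    "record_id": "record_id",
}

#: Columns appended by scoring, in output order.
SCORE_COLUMNS = ["ewma", "d", "se_d", "z_r", "q_r", "z_s", "q_s", "flag_r", "flag_s"]

DAYS_PER_YEAR = 365.25


class SchemaError(ValueError):
    """A required column is missing from the input file."""


@dataclass(frozen=True)
class MeasurementRecord:
    """A single observation of a continuous variable.

    Attributes
    ----------
    subject_id : opaque subject identifier.
    variable : variable name, e.g. ``"height"`` or ``"weight"``.
    time : decimal years (age, or any origin — only intervals matter).
    value : measurement in the variable's native unit.
    record_id : unique record identifier within a dataset.
    """

    subject_id: str
    variable: str
    time: float
    value: float
    record_id: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError(f"record {self.record_id}: time is not finite")
        if not math.isfinite(self.value):
            raise ValueError(f"record {self.record_id}: value is not finite")


@dataclass
class SubjectSeries:
    """Time-sorted measurements of one variable for one subject.

    ``times`` are nondecreasing; ties (same-day measurements) are permitted
    and kept in record-id order.  Scoring requires length >= 2.
    """

    subject_id: str
    variable: str
    times: np.ndarray
    values: np.ndarray
    record_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times) == len(self.values) == len(self.record_ids)):
            raise ValueError("times, values and record_ids must have equal length")
        if len(self.times) == 0:
            raise ValueError("a series must contain at least one measurement")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.times)


def days_to_years(days: float) -> float:
    """Convert a day count to decimal years (365.25 days per year)."""
    return days / DAYS_PER_YEAR


def _resolve_schema(schema: Mapping[str, str] | None) -> dict[str, str]:
    resolved = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        resolved.update(schema)
    return resolved


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[MeasurementRecord], list[str]]:
    """Read measurement records from a long-format CSV file.

    Parameters
    ----------
    path : CSV file with a header row.
    schema : optional mapping from canonical column names
        (``subject_id``, ``variable``, ``time``, ``value``, ``record_id``)
        to the names used in the file.

    Returns
    -------
    (records, diagnostics) : rows with unparseable time/value are rejected
        with a row-numbered diagnostic message, never silently dropped.
        ``record_id`` is auto-generated as ``"<subject>:<row#>"`` when the
        column is absent.

    Raises
    ------
    SchemaError : if a mapped required column is missing.
    """
    cols = _resolve_schema(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [cols[k] for k in ("subject_id", "variable", "time", "value")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    has_rid = cols["record_id"] in df.columns

    records: list[MeasurementRecord] = []
    diagnostics: list[str] = []
    for idx, rowvals in enumerate(df.itertuples(index=False, name=None), start=2):
        row = dict(zip(df.columns, rowvals))  # row 1 = header
        subject = str(row[cols["subject_id"]])
        try:
            t = float(row[cols["time"]])
            v = float(row[cols["value"]])
        except (TypeError, ValueError):
            diagnostics.append(
                f"row {idx}: unparseable time={row[cols['time']]!r} "
                f"or value={row[cols['value']]!r}; row skipped"
            )
            continue
        if not (math.isfinite(t) and math.isfinite(v)):
            diagnostics.append(f"row {idx}: non-finite time or value; row skipped")
            continue
        rid = str(row[cols["record_id"]]) if has_rid else f"{subject}:{idx - 1}"
        records.append(
            MeasurementRecord(
                subject_id=subject,
                variable=str(row[cols["variable"]]),
                time=t,
                value=v,
                record_id=rid,
            )
        )
    _check_unique_ids(records)
    return records, diagnostics


def _check_unique_ids(records: Sequence[MeasurementRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record_id: {r.record_id!r}")
        seen.add(r.record_id)


def write_records(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write records as long-format CSV (the same dialect `read_records` reads).

    Values and times are rendered with `repr`, so a write/read round trip is
    bit-exact for any float.
    """
    df = records_to_frame(records)
    df["time"] = df["time"].map(repr)
    df["value"] = df["value"].map(repr)
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Return the records as a DataFrame in canonical column order."""
    rows = [
        (r.subject_id, r.variable, r.time, r.value, r.record_id) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "variable", "time", "value", "record_id"]
    )


def group_series(records: Iterable[MeasurementRecord]) -> list[SubjectSeries]:
    """Group records into one SubjectSeries per (subject_id, variable).

    Within a series, records are sorted by time with ties broken by
    record_id, so the result is invariant to the input ordering.  Series
    are returned sorted by (subject_id, variable).
    """
    groups: dict[tuple[str, str], list[MeasurementRecord]] = {}
    for r in records:
        groups.setdefault((r.subject_id, r.variable), []).append(r)
    out: list[SubjectSeries] = []
    for (sid, var) in sorted(groups):
        recs = sorted(groups[(sid, var)], key=lambda r: (r.time, r.record_id))
        out.append(
            SubjectSeries(
                subject_id=sid,
                variable=var,
                times=np.array([r.time for r in recs]),
                values=np.array([r.value for r in recs]),
                record_ids=[r.record_id for r in recs],
            )
        )
    return out
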