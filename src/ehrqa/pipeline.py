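"""End-to-end scoring pipeline: preprocess, score, aggregate.

Ties the per-module operations together over a whole multi-variable record
set and returns flat DataFrames suitable for CSV output.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, VariableConfig
from .longitudinal import qr_scores
from .preprocess import RangeRule, preprocess_records
from .records import MeasurementRecord, group_series, records_to_frame
from .reference import estimate_reference_stats, estimate_within_variance, qs_scores
from .subject_qa import summarize_subject

__all__ = ["score_records", "subject_summary_frame"]


def score_records(
    records: Sequence[MeasurementRecord],
    config: Mapping[str, VariableConfig],
    methods: Sequence[str] = ("ewma", "threshold"),
    estimate_ref: bool = True,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Score all records, returning the long table plus score columns.

    Each record of a configured variable is scored with the longitudinal
    EWMA score (``q_r``) and/or the population thresholding score (``q_s``).
    Reference mean/SD come from the config block or, with ``estimate_ref``,
    from the (preprocessed) data.  Records removed by preprocessing appear
    with ``status="removed"`` and no scores; single-measurement subjects
    get ``status="too_few"`` for the longitudinal method.

    Raises ConfigError if an input variable has no config block.
    """
    variables = sorted({r.variable for r in records})
    missing = [v for v in variables if v not in config]
    if missing:
        raise ConfigError(f"no config block for variable(s): {missing}")

    frames = []
    for var in variables:
        cfg = config[var]
        subset = [r for r in records if r.variable == var]
        if preprocess:
            rule = RangeRule(
                variable=var, low=cfg.low, high=cfg.high,
                min_age=cfg.min_age, max_same_day=cfg.max_same_day,
            )
            kept, removed_ids = preprocess_records(subset, rule)
        else:
            kept, removed_ids = list(subset), []

        df = records_to_frame(subset).set_index("record_id", drop=False)
        for col in ("ewma", "d", "se_d", "z_r", "q_r", "z_s", "q_s"):
            df[col] = np.nan
        df["flag_r"] = False
        df["flag_s"] = False
        df["status"] = "scored"
        df.loc[removed_ids, "status"] = "removed"

        if "ewma" in methods:
            if cfg.var_y is None:
                var_y = estimate_within_variance(group_series(kept))
                if not var_y > 0:
                    raise ConfigError(
                        f"{var}: estimated within-subject variance is 0; supply var_y"
                    )
                params = cfg.longitudinal_params(var_y=var_y)
            else:
                params = cfg.longitudinal_params()
            for series in group_series(kept):
                for sr in qr_scores(series, params):
                    df.loc[sr.record_id, ["ewma", "d", "se_d", "z_r", "q_r"]] = [
                        sr.ewma, sr.d, sr.se_d, sr.z_r, sr.q_r,
                    ]
                    df.loc[sr.record_id, "flag_r"] = sr.flag_r
                    if sr.status != "scored":
                        df.loc[sr.record_id, "status"] = sr.status

        if "threshold" in methods:
            ref = cfg.reference_stats()
            if ref is None:
                if not estimate_ref:
                    raise ConfigError(
                        f"{var}: no reference mean/sd configured and estimate_ref is off"
                    )
                ref = estimate_reference_stats(kept)
            kept_ids = [r.record_id for r in kept]
            qs = qs_scores([r.value for r in kept], ref, cfg.cutoff)
            df.loc[kept_ids, "z_s"] = qs["z_s"].to_numpy()
            df.loc[kept_ids, "q_s"] = qs["q_s"].to_numpy()
            df.loc[kept_ids, "flag_s"] = qs["flag_s"].to_numpy()

        frames.append(df.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def subject_summary_frame(
    scored: pd.DataFrame, proportion_cutoff: float = 0.20
) -> pd.DataFrame:
    """Subject-level QA summaries from a scored table (longitudinal flags)."""
    from .longitudinal import ScoredRecord

    rows = []
    for (sid, var), grp in scored.groupby(["subject_id", "variable"], sort=True):
        recs = [
            ScoredRecord(
                record_id=r.record_id, value=r.value, ewma=r.ewma, d=r.d,
                se_d=r.se_d, z_r=r.z_r, q_r=r.q_r, flag_r=bool(r.flag_r),
                status=r.status if r.status in ("scored", "too_few") else "removed",
            )
            for r in grp.itertuples(index=False)
        ]
        s = summarize_subject(sid, var, recs, proportion_cutoff)
        rows.append(
            {
                "subject_id": s.subject_id, "variable": s.variable,
                "n_scored": s.n_scored, "n_flagged": s.n_flagged,
                "proportion": s.proportion, "subject_flagged": s.subject_flagged,
            }
        )
    return pd.DataFrame(rows)
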