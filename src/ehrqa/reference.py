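"""Atemporal thresholding score Q_S and variance-component estimation.

Q_S judges each value in isolation against population reference statistics:
``Z = (y - mean)/sd`` and ``Q_S = 2(1 - Phi(|Z|))``.  It flags anything far
from the population norm — including perfectly consistent values of
subjects who simply sit in a distribution tail, the failure mode the
longitudinal score is designed to avoid.

The module also estimates the within-subject variance component needed as
``var_y`` by a one-way random-effects (subject random intercept)
decomposition, using the closed-form ANOVA method-of-moments estimator.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, ReferenceStats
from .records import MeasurementRecord, SubjectSeries

__all__ = [
    "qs_scores",
    "estimate_reference_stats",
    "estimate_within_variance",
]


def qs_scores(
    values: np.ndarray | Sequence[float],
    ref: ReferenceStats,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Threshold-score values against a population reference.

    Returns a DataFrame with columns ``z_s`` (signed standardized distance),
    ``q_s`` (two-sided normal p-value of |z_s|), and ``flag_s``
    (q_s <= cutoff).  Invariant under any common affine rescaling of
    values, mean and sd.
    """
    if not ref.sd > 0:
        raise ConfigError("reference sd must be positive")
    v = np.asarray(values, dtype=float)
    z = (v - ref.mean) / ref.sd
    q = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"z_s": z, "q_s": q, "flag_s": q <= cutoff})


def estimate_reference_stats(
    records: Iterable[MeasurementRecord],
    strata: dict[str, str] | None = None,
) -> ReferenceStats | dict[str, ReferenceStats]:
    """Estimate reference mean/SD from data (unstratified by default).

    Parameters
    ----------
    records : measurement records of a single variable.
    strata : optional mapping subject_id -> stratum label; when given, one
        ReferenceStats per stratum is returned in a dict.

    Sample SD (ddof=1) is used.  Fewer than 2 records, or zero SD, is a
    degenerate configuration and raises.
    """
    recs = list(records)
    if strata is not None:
        out: dict[str, ReferenceStats] = {}
        for label in sorted(set(strata.values())):
            sub = [r for r in recs if strata.get(r.subject_id) == label]
            out[label] = estimate_reference_stats(sub)  # type: ignore[assignment]
        return out
    if len(recs) < 2:
        raise ValueError("need at least 2 records to estimate reference statistics")
    values = np.array([r.value for r in recs])
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise ConfigError(
            "degenerate reference: all values identical (SD = 0); "
            "a zero-SD reference would give infinite Z scores"
        )
    return ReferenceStats(
        variable=recs[0].variable,
        mean=float(values.mean()),
        sd=sd,
        n_source=len(recs),
    )


def estimate_within_variance(series_collection: Iterable[SubjectSeries]) -> float:
    """Within-subject variance component by one-way ANOVA method of moments.

    Treats subject as a random intercept and returns the pooled
    within-subject mean square

        MS_within = sum_subjects sum_i (y_ij - ybar_j)^2 / sum_subjects (n_j - 1),

    the unbiased estimator of the within-subject variance under the one-way
    random-effects model.  Subjects with a single measurement contribute
    nothing to either sum.  Suitable as the ``var_y`` tuning constant.
    """
    ss = 0.0
    df = 0
    for s in series_collection:
        n = len(s)
        if n < 2:
            continue
        ss += float(np.sum((s.values - s.values.mean()) ** 2))
        df += n - 1
    if df == 0:
        raise ValueError("no subject with >= 2 measurements; cannot estimate variance")
    ms_within = ss / df
    if ms_within == 0.0:
        warnings.warn(
            "within-subject variance estimated as 0 (all subjects constant); "
            "scoring requires var_y > 0",
            stacklevel=2,
        )
    return ms_within
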