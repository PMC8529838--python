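"""Longitudinal plausibility score Q_R based on a time-decayed EWMA.

For a subject's sequence of measurements ``y_1..y_n`` at times ``t_1..t_n``
(decimal years), the moving-average estimate for index ``i`` is

    ybar_i = sum_j(w_j * y_j) / sum_j(w_j),
    w_j    = 1 if j == i else exp(-|t_j - t_i| / tau),

a weighted average over the *entire* sequence including the index
measurement itself.  The deviation ``d_i = |y_i - ybar_i|`` is standardized
by ``SE(d_i) = sqrt(factor_i * var_y)`` where ``var_y`` is the assumed
within-subject measurement variance and ``factor_i`` depends only on the
weights.  Q_R is the two-sided normal p-value ``2 * (1 - Phi(d_i / SE))``;
small Q_R flags a value that is implausible given the subject's history.

Two deviation-variance factors are available (see
:func:`deviation_variance_factor`); the default ``"derived"`` variant is the
one that matches Monte-Carlo simulation of ``Var(ybar_i - y_i)`` under the
independence assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import LongitudinalParams
from .records import SubjectSeries

__all__ = [
    "heuristic_tau",
    "decay_weight",
    "compute_ewma",
    "deviation_variance_factor",
    "qr_scores",
    "ScoredRecord",
]


@dataclass(frozen=True)
class ScoredRecord:
    """Per-record longitudinal scoring result.

    ``q_r`` (and the other numeric fields) are NaN and ``flag_r`` is False
    when the score is undefined — a subject with a single measurement —
    in which case ``status`` is ``"too_few"`` instead of ``"scored"``.
    """

    record_id: str
    value: float
    ewma: float
    d: float
    se_d: float
    z_r: float
    q_r: float
    flag_r: bool
    status: str = "scored"


def heuristic_tau(omega: float, xi_months: float) -> float:
    """Decay scale tau (years) giving dependency ``omega`` at ``xi_months``.

    Solves ``exp(-(xi/12)/tau) = omega`` for tau:
    ``tau = -(xi_months/12) / ln(omega)``.  For example, 90% dependency on
    observations 12 months away gives tau = 9.49 years; 90% at half a month
    gives tau = 0.4.

    Strictly increasing in both ``omega`` and ``xi_months``.
    """
    if not 0 < omega < 1:
        raise ValueError(f"omega must be in (0,1), got {omega}")
    if not xi_months > 0:
        raise ValueError(f"xi_months must be positive, got {xi_months}")
    return -(xi_months / 12.0) / math.log(omega)


def decay_weight(t_j: float, t_i: float, tau: float, is_self: bool = False) -> float:
    """Weight of the measurement at ``t_j`` toward the average at ``t_i``.

    1 for the index measurement itself, else ``exp(-|t_j - t_i|/tau)``;
    symmetric in the two times.  Same-timestamp neighbors get exp(0) = 1,
    identical to the self weight.
    """
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if is_self:
        return 1.0
    return math.exp(-abs(t_j - t_i) / tau)


def _weight_matrix(times: np.ndarray, tau: float) -> np.ndarray:
    """n x n matrix of decay weights; row i holds w_j for target index i."""
    gaps = np.abs(times[:, None] - times[None, :])
    w = np.exp(-gaps / tau)
    np.fill_diagonal(w, 1.0)  # exact, also when same-time ties exist
    return w


def compute_ewma(series: SubjectSeries, i: int, tau: float) -> float:
    """Time-decayed weighted average of the whole series, targeted at index ``i``.

    ``i`` is a 0-based index.  The result is a convex combination of the
    values, hence lies within [min(values), max(values)].
    """
    n = len(series)
    if not 0 <= i < n:
        raise IndexError(f"index {i} out of range for series of length {n}")
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    w = np.exp(-np.abs(series.times - series.times[i]) / tau)
    w[i] = 1.0
    return float(np.dot(w, series.values) / w.sum())


def deviation_variance_factor(
    weights: np.ndarray, i: int, variant: str = "derived"
) -> float:
    """Multiplier turning var_y into Var(d_i) for one target index.

    With ``W = sum(w_j)`` and ``S2 = sum(w_j^2)`` (``w_i = 1``):

    * ``variant="derived"``: ``S2/W^2 - 2/W + 1`` — the factor obtained by
      expanding ``Var(ybar_i - y_i)`` with independent ``y_j`` of common
      variance; it equals ``sum_{j!=i} w_j^2/W^2 + (1/W - 1)^2 >= 0`` and
      shrinks toward 0 as informative neighbors accumulate.
    * ``variant="paper"``: ``S2/W^2 + 2/W + 1`` — the published formula,
      retained for literal reproduction; it exceeds 1 and grows the
      deviation SE instead.

    ``Var(d_i) = factor * var_y``; ``SE(d_i)`` is its square root.
    """
    w = np.asarray(weights, dtype=float)
    if not np.all(w > 0):
        raise ValueError("weights must be positive")
    if not math.isclose(w[i], 1.0):
        raise ValueError(f"w[{i}] must be 1 (the self weight), got {w[i]}")
    W = w.sum()
    S2 = float(np.dot(w, w))
    cross = 2.0 * w[i] / W
    if variant == "derived":
        factor = S2 / W**2 - cross + 1.0
    elif variant == "paper":
        factor = S2 / W**2 + cross + 1.0
    else:
        raise ValueError(f"unknown variance variant {variant!r}")
    if factor <= 0:
        # derived factor is a sum of squares; 0 only in the degenerate n=1 case
        raise ValueError("degenerate variance factor (single-measurement series?)")
    return factor


def qr_scores(series: SubjectSeries, params: LongitudinalParams) -> list[ScoredRecord]:
    """Score every measurement of one series with the longitudinal Q_R.

    For each index: EWMA over the whole sequence, absolute deviation d_i,
    SE from the deviation-variance factor times ``params.var_y``,
    Z = d_i/SE, and Q_R = 2(1 - Phi(Z)); a record is flagged when
    Q_R <= ``params.cutoff``.

    A series with fewer than two measurements yields records with NaN
    scores, ``flag_r=False`` and status ``"too_few"``.
    """
    n = len(series)
    if n < 2:
        return [
            ScoredRecord(
                record_id=series.record_ids[0],
                value=float(series.values[0]),
                ewma=math.nan, d=math.nan, se_d=math.nan,
                z_r=math.nan, q_r=math.nan, flag_r=False,
                status="too_few",
            )
        ]

    w = _weight_matrix(series.times, params.tau)
    W = w.sum(axis=1)
    ewma = (w @ series.values) / W
    d = np.abs(series.values - ewma)
    S2 = (w**2).sum(axis=1)
    cross = 2.0 * np.diag(w) / W
    if params.variance_variant == "derived":
        factor = S2 / W**2 - cross + 1.0
    else:
        factor = S2 / W**2 + cross + 1.0
    se = np.sqrt(factor * params.var_y)
    z = d / se
    q = 2.0 * stats.norm.sf(np.abs(z))
    flag = q <= params.cutoff
    return [
        ScoredRecord(
            record_id=series.record_ids[i],
            value=float(series.values[i]),
            ewma=float(ewma[i]),
            d=float(d[i]),
            se_d=float(se[i]),
            z_r=float(z[i]),
            q_r=float(q[i]),
            flag_r=bool(flag[i]),
        )
        for i in range(n)
    ]
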