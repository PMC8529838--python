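"""Flagging-performance evaluation against ground-truth error labels.

"Positive" means flagged-as-error throughout.  Beyond the confusion-matrix
rates (FPR, power, PPV, NPV), the module sweeps the p-value cutoff into an
ROC curve with trapezoidal AUC, and sweeps the tuning grid (tau x var_y)
reporting the operating point that maximizes power subject to a false
discovery rate bound (FDR = 1 - PPV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import LongitudinalParams
from .longitudinal import qr_scores
from .records import MeasurementRecord, group_series
from .simulate import ErrorLabel

__all__ = ["ConfusionMetrics", "confusion", "roc_sweep", "parameter_sweep"]

#: Default cutoff grid; always includes the two conventional reporting
#: cutoffs 0.01 and 0.05.
DEFAULT_CUTOFFS = tuple(
    sorted(set(np.round(np.geomspace(1e-6, 1.0, 41), 10)) | {0.01, 0.05})
)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates; a rate is NaN when its
    denominator is zero (never reported as 0/0 = 0)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else math.nan

    @property
    def power(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else math.nan

    @property
    def fdr(self) -> float:
        """False discovery rate, 1 - PPV."""
        p = self.ppv
        return math.nan if math.isnan(p) else 1.0 - p


def _truth_map(truth: Sequence[ErrorLabel] | Mapping[str, bool]) -> dict[str, bool]:
    if isinstance(truth, Mapping):
        return dict(truth)
    return {l.record_id: l.is_error for l in truth}


def confusion(
    flags: Mapping[str, bool],
    truth: Sequence[ErrorLabel] | Mapping[str, bool],
) -> ConfusionMetrics:
    """Confusion metrics of record flags against ground-truth labels.

    ``flags`` maps record_id -> flagged; every flagged id must have a truth
    label (alignment by record_id; mismatches raise).
    """
    t = _truth_map(truth)
    missing = set(flags) - set(t)
    if missing:
        raise ValueError(f"flags for records without truth labels: {sorted(missing)[:5]}")
    tp = fp = tn = fn = 0
    for rid, flagged in flags.items():
        if flagged:
            if t[rid]:
                tp += 1
            else:
                fp += 1
        else:
            if t[rid]:
                fn += 1
            else:
                tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_sweep(
    q_scores: Mapping[str, float],
    truth: Sequence[ErrorLabel] | Mapping[str, bool],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> tuple[pd.DataFrame, float]:
    """ROC points over a cutoff grid plus trapezoidal AUC.

    A record is called positive when its q-score is at or below the cutoff,
    so FPR and TPR are nondecreasing in the cutoff.  The AUC integrates the
    swept points anchored at (0,0) and (1,1).  Requires at least one true
    error and one clean record.
    """
    t = _truth_map(truth)
    rids = [r for r in q_scores if not math.isnan(q_scores[r])]
    y = np.array([t[r] for r in rids], dtype=bool)
    q = np.array([q_scores[r] for r in rids])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one error and one clean record")
    rows = []
    for c in sorted(cutoffs):
        called = q <= c
        rows.append(
            {
                "cutoff": c,
                "fpr": float((called & ~y).sum() / n_neg),
                "tpr": float((called & y).sum() / n_pos),
            }
        )
    points = pd.DataFrame(rows)
    fpr = np.concatenate([[0.0], points["fpr"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], points["tpr"].to_numpy(), [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return points, auc


def parameter_sweep(
    records: Sequence[MeasurementRecord],
    labels: Sequence[ErrorLabel],
    tau_grid: Sequence[float],
    var_y_grid: Sequence[float],
    cutoff: float = 0.05,
    variance_variant: str = "derived",
    fdr_bound: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Grid search over (tau, var_y) for the longitudinal score.

    Returns a deterministic table of confusion metrics per grid point and
    the selected optimum: the point maximizing power among those with
    FDR <= ``fdr_bound``, falling back to minimum FDR when no point meets
    the bound.  Ties break toward smaller FDR, then smaller (tau, var_y).
    """
    if len(tau_grid) == 0 or len(var_y_grid) == 0:
        raise ValueError("empty parameter grid")
    t = _truth_map(labels)
    if not any(t.values()):
        raise ValueError("no true errors in labels; nothing to sweep against")
    series = group_series(records)
    rows = []
    for tau in tau_grid:
        for var_y in var_y_grid:
            params = LongitudinalParams(
                tau=tau, var_y=var_y, variance_variant=variance_variant, cutoff=cutoff
            )
            flags: dict[str, bool] = {}
            for s in series:
                for sr in qr_scores(s, params):
                    if sr.status == "scored":
                        flags[sr.record_id] = sr.flag_r
            m = confusion(flags, t)
            rows.append(
                {
                    "tau": tau, "var_y": var_y, "cutoff": cutoff,
                    "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                    "fpr": m.fpr, "power": m.power, "ppv": m.ppv,
                    "npv": m.npv, "fdr": m.fdr,
                }
            )
    table = pd.DataFrame(rows)
    ok = table[table["fdr"] <= fdr_bound]
    if len(ok):
        pool = ok.sort_values(
            ["power", "fdr", "tau", "var_y"], ascending=[False, True, True, True]
        )
    else:  # bound unattainable anywhere: report the least-contaminated point
        pool = table.sort_values(
            ["fdr", "power", "tau", "var_y"], ascending=[True, False, True, True]
        )
    best = pool.iloc[0].to_dict()
    best["criterion"] = (
        f"max power s.t. FDR <= {fdr_bound}" if len(ok) else "min FDR (bound unmet)"
    )
    return table, best
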