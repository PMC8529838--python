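"""Per-variable scoring configuration.

Each scored variable carries a decay scale ``tau`` (years), an assumed
within-subject measurement variance ``var_y`` (squared native units), a
plausible range, optional population reference statistics, and a p-value
cutoff.  Shipped defaults cover adult height (inches) and weight (pounds).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Invalid or missing configuration."""


@dataclass(frozen=True)
class LongitudinalParams:
    """Tuning parameters of the longitudinal (EWMA) score.

    Attributes
    ----------
    tau : decay scale in years; larger means smoother, more history-dependent
        moving averages.
    var_y : assumed within-subject measurement variance, squared native units.
    variance_variant : ``"derived"`` uses the deviation-variance factor that
        follows from Var(EWMA - y_i) under independence (minus cross term);
        ``"paper"`` uses the published formula (plus cross term).
    cutoff : p-value at or below which a record is flagged.
    """

    tau: float
    var_y: float
    variance_variant: str = "derived"
    cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ConfigError(f"tau must be positive, got {self.tau}")
        if not (self.var_y > 0 and math.isfinite(self.var_y)):
            raise ConfigError(f"var_y must be positive, got {self.var_y}")
        if self.variance_variant not in ("derived", "paper"):
            raise ConfigError(
                f"variance_variant must be 'derived' or 'paper', got {self.variance_variant!r}"
            )
        if not 0 < self.cutoff < 1:
            raise ConfigError(f"cutoff must be in (0,1), got {self.cutoff}")


@dataclass(frozen=True)
class ReferenceStats:
    """Population reference mean/SD used by the thresholding score."""

    variable: str
    mean: float
    sd: float
    n_source: int = 0

    def __post_init__(self) -> None:
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ConfigError(f"reference sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class VariableConfig:
    """Complete per-variable configuration block.

    ``var_y=None`` means "estimate the within-subject variance from the
    input data" (one-way random-effects estimator) at scoring time — the
    procedure used when no validated value exists for a variable.
    """

    variable: str
    tau: float
    var_y: float | None
    low: float
    high: float
    min_age: float = 17.0
    max_same_day: int = 3
    cutoff: float = 0.05
    variance_variant: str = "derived"
    ref_mean: float | None = None
    ref_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError(f"{self.variable}: low must be < high")
        if self.max_same_day < 1:
            raise ConfigError(f"{self.variable}: max_same_day must be >= 1")
        # delegate tau/var_y/cutoff validation (var_y=None deferred to scoring)
        self.longitudinal_params(var_y=self.var_y if self.var_y is not None else 1.0)

    def longitudinal_params(self, var_y: float | None = None) -> LongitudinalParams:
        v = var_y if var_y is not None else self.var_y
        if v is None:
            raise ConfigError(
                f"{self.variable}: var_y not configured and no estimate supplied"
            )
        return LongitudinalParams(
            tau=self.tau,
            var_y=v,
            variance_variant=self.variance_variant,
            cutoff=self.cutoff,
        )

    def reference_stats(self) -> ReferenceStats | None:
        if self.ref_mean is None or self.ref_sd is None:
            return None
        return ReferenceStats(variable=self.variable, mean=self.ref_mean, sd=self.ref_sd)

    def with_overrides(self, **kwargs: Any) -> "VariableConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def default_config() -> dict[str, VariableConfig]:
    """Shipped defaults for adult height (inches) and weight (pounds).

    Height: tau = 9.49 from the heuristic (90% dependency at 12 months);
    var_y is estimated from the input data at scoring time (no validated
    value exists for height) — note the estimate absorbs any errors present,
    which inflates it and makes the score conservative on clean neighbors of
    gross errors while leaving the gross errors themselves flagged.
    Weight: the validation-optimized tau = 0.5 and var_y = 210 lb².

    The thresholding comparator uses *prespecified* typical-adult reference
    statistics (height 69 +/- 3 in, weight 185 +/- 35 lb) rather than
    refitting mean/SD to each input cohort: a cohort-fitted SD absorbs
    heavy/light subpopulations and any gross errors, which is not how
    prespecified-threshold QA is practiced.
    """
    return {
        "height": VariableConfig(
            variable="height", tau=9.49, var_y=None,
            low=40.0, high=100.0, ref_mean=69.0, ref_sd=3.0,
        ),
        "weight": VariableConfig(
            variable="weight", tau=0.5, var_y=210.0,
            low=40.0, high=1000.0, ref_mean=185.0, ref_sd=35.0,
        ),
    }


_FIELDS = (
    "tau", "var_y", "low", "high", "min_age", "max_same_day",
    "cutoff", "variance_variant", "ref_mean", "ref_sd",
)


def load_config(path: str | Path) -> dict[str, VariableConfig]:
    """Load per-variable configuration from a YAML (or JSON) file.

    The file maps variable names to blocks of the `VariableConfig` fields;
    unspecified fields fall back to the shipped defaults for known
    variables, else must be given.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping of variable blocks")
    defaults = default_config()
    out: dict[str, VariableConfig] = {}
    for var, block in data.items():
        if block is None:
            block = {}
        if not isinstance(block, Mapping):
            raise ConfigError(f"{path}: block for {var!r} must be a mapping")
        unknown = set(block) - set(_FIELDS)
        if unknown:
            raise ConfigError(f"{path}: unknown keys for {var!r}: {sorted(unknown)}")
        if var in defaults:
            out[var] = defaults[var].with_overrides(**dict(block))
        else:
            try:
                out[var] = VariableConfig(variable=var, **dict(block))
            except TypeError as exc:
                raise ConfigError(f"{path}: incomplete block for {var!r}: {exc}") from exc
    return out
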