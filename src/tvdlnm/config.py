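"""Run configuration: every tunable of the analysis pipeline with defaults.

Defaults mirror the main-model specification: exposure spline knot at the
75th temperature percentile, 21-day lag window with three log-spaced lag
knots, 10 df/year long-term time spline, 3-df humidity spline, lag 0-2
moving averages for PM10 and RH, annual curves centred on 1 July, and
percentile anchors {1, 10, 90, 99} for the cold/heat indicators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    exposure_knot_percentiles: tuple = (75.0,)
    max_lag: int = 21
    n_lag_knots: int = 3
    time_df_per_year: float = 10.0
    rh_df: int = 3
    ma_max_lag: int = 2            # moving average over lags 0..ma_max_lag
    interaction: bool = True
    centre_month: int = 7          # annual centring date: 1 July
    centre_day: int = 1
    n_boot: int = 1000
    seed: int = 12345
    mmt_grid_step: float = 0.1     # degrees C
    mmt_constraint: tuple = (1.0, 99.0)       # percentile constriction
    pct_extreme_cold: float = 1.0
    pct_moderate_cold: float = 10.0
    pct_moderate_heat: float = 90.0
    pct_extreme_heat: float = 99.0
    annual_percentile_basis: str = "year"     # or "period"
    strata: tuple = ("all",)

    def __post_init__(self):
        self.exposure_knot_percentiles = tuple(
            float(p) for p in self.exposure_knot_percentiles)
        self.mmt_constraint = tuple(float(p) for p in self.mmt_constraint)
        self.strata = tuple(self.strata)
        if self.time_df_per_year < 1 or self.rh_df < 1:
            raise ValueError("all spline df must be >= 1")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.mmt_grid_step <= 0:
            raise ValueError("mmt_grid_step must be > 0")
        for p in (*self.exposure_knot_percentiles, *self.mmt_constraint,
                  self.pct_extreme_cold, self.pct_moderate_cold,
                  self.pct_moderate_heat, self.pct_extreme_heat):
            if not 0.0 < p < 100.0:
                raise ValueError(f"percentile {p} outside (0, 100)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.annual_percentile_basis not in ("year", "period"):
            raise ValueError("annual_percentile_basis must be 'year' or 'period'")

    @property
    def anchor_percentiles(self) -> dict:
        return {
            "extreme_cold": self.pct_extreme_cold,
            "moderate_cold": self.pct_moderate_cold,
            "moderate_heat": self.pct_moderate_heat,
            "extreme_heat": self.pct_extreme_heat,
        }

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
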