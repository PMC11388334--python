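"""Configuration dataclasses for the synthetic world, the surrogate and the pipeline.

All depths are metres, positive downward from the soil surface (depth 0 =
water table at the surface).  Water deficits are mm of July precipitation
minus potential evapotranspiration (negative = deficit).  Yields are t/ha.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

@dataclass(frozen=True)
class GWEffectParams:
    """Parameters of the injected groundwater-yield effect.

    The effect is piecewise smooth in depth-to-water ``d``:

    * a linear waterlogging penalty ``-penalty_slope * (d_low - d)`` for
      ``d < d_low``;
    * a raised-cosine subsidy bump on ``[d_low, d_high]`` peaking at
      ``d_opt`` with amplitude ``s_max`` (zero value and zero slope at both
      zone edges);
    * exactly zero for ``d >= d_high`` (free drainage).

    In very dry Julys (deficit < -150 mm) the bump amplitude is multiplied
    by ``drought_amplifier``; wet Julys never worsen the penalty
    (``wet_penalty_amplifier`` is fixed at 1).  ``direct_share`` is the
    fraction of the subsidy delivered by direct root uptake; the remainder
    is routed through the capillary soil-moisture channel (see
    :mod:`gwyield.synthetic_world`).
    """

    d_low: float = 1.1
    d_opt: float = 1.5
    d_high: float = 2.5
    s_max: float = 0.37
    penalty_slope: float = 0.45
    drought_amplifier: float = 2.0
    wet_penalty_amplifier: float = 1.0
    direct_share: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 < self.d_low < self.d_opt < self.d_high):
            raise ValueError(
                f"require 0 < d_low < d_opt < d_high, got "
                f"({self.d_low}, {self.d_opt}, {self.d_high})"
            )
        if self.s_max < 0:
            raise ValueError("s_max must be non-negative")
        if self.penalty_slope < 0:
            raise ValueError("penalty_slope must be non-negative")
        if self.drought_amplifier < 1.0:
            raise ValueError(
                "drought_amplifier < 1 rejected: the groundwater subsidy "
                "must not shrink under drought"
            )
        if not (0.0 <= self.direct_share <= 1.0):
            raise ValueError("direct_share must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic grid-cell-year world.

    The defaults are the study conditions every downstream recovery test
    runs under: site mean depths uniform on ``wt_mean_range`` so the depth
    axis covers penalty, subsidy and free-drainage regimes; a July water
    deficit distribution placing mass in all four weather classes (roughly
    60% of cell-years drier than -50 mm and 9% drier than -150 mm); and the
    paper-scale groundwater effect of :class:`GWEffectParams`.
    """

    n_cells: int = 500
    n_years: int = 20
    seed: int = 0

    # water table
    wt_mean_range: tuple[float, float] = (0.3, 6.0)
    wt_ar1: float = 0.45
    wt_innovation_sd: float = 0.30
    wt_weather_coupling: float = 0.5  # m deeper per 100 mm of deficit anomaly
    wt_month_sd: float = 0.35  # month-specific depth variation around July
    min_depth: float = 0.05
    tile_frac: float = 0.30
    tile_depth: float = 1.0

    # weather
    deficit_mean: float = -65.0
    deficit_sd: float = 65.0
    deficit_site_sd: float = 25.0  # persistent site dryness (drives VPD terciles)
    deficit_year_sd: float = 45.0  # regional year effect
    vpd_mean: float = 1.10
    vpd_sd: float = 0.25

    # soils and plant-available soil moisture (mm in the top 1 m)
    soil_awc_mean: float = 230.0
    soil_awc_sd: float = 40.0
    sm_mean: float = 70.0
    sm_deficit_slope: float = 0.35  # mm soil moisture per mm deficit anomaly
    sm_awc_slope: float = 0.08
    sm_noise_sd: float = 35.0
    capillary_boost_median: float = 0.30  # target median relative boost within reach
    capillary_noise_sd: float = 0.50  # lognormal sigma of record-level capillary variation

    # yield
    base_yield: float = 11.0
    yield_awc_slope: float = 0.004  # t/ha per mm AWC
    yield_sm_slope: float = 0.004  # t/ha per mm soil moisture (null-capillary worlds)
    stress_linear: float = 1.2  # t/ha per 100 mm of deficit beyond -50
    stress_quadratic: float = 0.4  # t/ha per (100 mm)^2
    noise_sd: float = 0.25
    gw_effect: GWEffectParams = field(default_factory=GWEffectParams)

    # pixel grain (several noisy yield replicates sharing a cell's groundwater)
    pixels_per_cell: int = 3
    pixel_yield_noise_sd: float = 0.75
    pixel_depth_sd: float = 0.35  # true pixel depth deviation around the cell value

    # accounting
    area_per_cell: float = 2000.0  # ha of maize per cell
    price_default: float = 150.0  # $/t
    price_series: tuple[float, ...] | None = None  # optional, one price per year

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_years <= 0:
            raise ValueError("n_cells and n_years must be positive")
        if not (0.0 <= self.wt_ar1 < 1.0):
            raise ValueError("wt_ar1 must lie in [0, 1)")
        lo, hi = self.wt_mean_range
        if not (0.0 < lo < hi):
            raise ValueError("wt_mean_range must satisfy 0 < lo < hi")
        if not (0.0 <= self.tile_frac <= 1.0):
            raise ValueError("tile_frac must lie in [0, 1]")
        if self.price_series is not None and len(self.price_series) != self.n_years:
            raise ValueError("price_series must have one entry per year")

    def prices(self) -> list[float]:
        if self.price_series is not None:
            return list(self.price_series)
        return [self.price_default] * self.n_years


@dataclass(frozen=True)
class SurrogateSpec:
    """Hyperparameters of the bagged-tree yield surrogate.

    Defaults follow the study's random forest: 100 trees, six candidate
    variables per split and a minimum terminal-node size of 10, evaluated
    on out-of-bag samples.
    """

    n_trees: int = 100
    m_try: int = 6
    min_node: int = 10
    predictors: tuple[str, ...] | None = None
    target: str = "yield_t_ha"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.m_try <= 0 or self.min_node <= 0:
            raise ValueError("n_trees, m_try and min_node must be positive")
        if self.predictors is not None and self.m_try > len(self.predictors):
            raise ValueError("m_try cannot exceed the number of predictors")


@dataclass(frozen=True)
class StageOptions:
    """Free parameters of the analysis stages, surfaced for auditability."""

    k_bins: int = 40
    # pipeline-level bootstrap size; bootstrap_ale itself defaults to 500
    # when called directly, but a full default pipeline run keeps B at 150
    # so the end-to-end command stays within a few minutes on one CPU
    n_boot: int = 150
    slope_tol: float = 0.05  # t/ha per m: plateau flatness threshold
    min_plateau_width: float = 0.8  # m
    r_grid: tuple[float, ...] = (0.9, 0.6, 0.3)
    effect_pcts: tuple[float, float, float] = (-0.01, 0.034, 0.078)  # penalty, subsidy, strong


def _coerce(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[SimConfig, SurrogateSpec, StageOptions]:
    """Read a TOML run configuration with [simulation]/[surrogate]/[stages] tables."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_raw = dict(raw.get("simulation", {}))
    if "gw_effect" in sim_raw:
        sim_raw["gw_effect"] = _coerce(GWEffectParams, sim_raw["gw_effect"])
    if "wt_mean_range" in sim_raw:
        sim_raw["wt_mean_range"] = tuple(sim_raw["wt_mean_range"])
    sim = _coerce(SimConfig, sim_raw)
    spec = _coerce(SurrogateSpec, raw.get("surrogate", {}))
    stages = _coerce(StageOptions, raw.get("stages", {}))
    return sim, spec, stages
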