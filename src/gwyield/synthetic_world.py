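"""Synthetic grid-cell-year world with a known, configurable groundwater-yield effect.

The generator emulates — statistically, not mechanistically — the structure
of a gridded crop-model/satellite-yield dataset: site-level mean
depth-to-water with AR(1) interannual anomalies that deepen in dry years,
a July water deficit spanning wet/normal/dry/very-dry weather, VPD coupled
to site dryness, soils, tile drainage that caps how shallow the water table
can get, two soil-moisture variants (top-down only vs. top-down plus
capillary), and maize yields carrying an injected groundwater effect whose
exact per-record value is recorded for oracle use.

Two observation grains are produced:

* ``grid`` — one record per cell-year (agreement, prevalence, accounting);
* ``pixel`` — several noisy yield replicates per cell-year that share the
  cell's *recorded* groundwater value while their yields respond to a
  latent pixel-level depth.  This built-in spatial mismatch is the raw
  material of the attenuation analysis.

Mechanism wiring.  The groundwater effect reaches yields through two
channels: direct root uptake and extra soil moisture from capillary rise.
The capillary increment ``sm_enhanced - sm_standard`` rises monotonically
as the water table shallows (zero beyond ``d_high``), with mean-one
lognormal record-level delivery noise, scaled so the median relative
moisture boost within reach matches ``capillary_boost_median``.  The yield
values capillary moisture at the same coefficient as top-down moisture,
and that coefficient is calibrated so the capillary channel's mean
contribution at the optimum depth is exactly ``1 - direct_share`` of the
subsidy there; the structural direct term is the remainder, keeping the
conditional-mean total effect equal to ``true_effect`` everywhere.  A
surrogate given ``sm_enhanced`` therefore absorbs the indirect channel and
its depth effect at the optimum shows only the direct share — the
covariate-swap contrast the mechanism module measures.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import GWEffectParams, SimConfig
from .metrics import VERY_DRY_BOUND, classify_weather

#: Covariates shared by every surrogate fit (besides a groundwater depth).
BASE_COVARIATES = [
    "deficit_july",
    "vpd",
    "soil_awc",
    "drainage_class",
    "tiled",
    "sm_standard",
]

#: Candidate groundwater periods offered to variable screening.
DEPTH_CANDIDATES = [
    "wt_depth_may",
    "wt_depth_jun",
    "wt_depth_jul",
    "wt_depth_aug",
    "wt_depth_annual",
]

TRUTH_COLUMNS = [
    "true_effect",
    "true_subsidy",
    "true_penalty",
    "true_direct",
    "true_indirect",
    "true_pixel_depth",
]


def subsidy_shape(depth, params: GWEffectParams):
    """Unit-amplitude raised-cosine subsidy bump over depth (no amplifier).

    Zero outside ``(d_low, d_high)``, 1 at ``d_opt``, with zero slope at
    both zone edges and at the optimum (piecewise cosine on either side of
    ``d_opt``, so the optimum need not sit mid-zone).
    """
    d = np.asarray(depth, dtype=float)
    shape = np.zeros_like(d)
    left = (d >= params.d_low) & (d <= params.d_opt)
    right = (d > params.d_opt) & (d < params.d_high)
    shape[left] = 0.5 * (
        1.0 - np.cos(np.pi * (d[left] - params.d_low) / (params.d_opt - params.d_low))
    )
    shape[right] = 0.5 * (
        1.0 + np.cos(np.pi * (d[right] - params.d_opt) / (params.d_high - params.d_opt))
    )
    return shape


def deficit_amplifier(deficit, params: GWEffectParams):
    """Bump amplitude multiplier: drought_amplifier in very dry Julys, else 1."""
    d = np.asarray(deficit, dtype=float)
    return np.where(d < VERY_DRY_BOUND, params.drought_amplifier, 1.0)


def true_effect(depth, deficit, params: GWEffectParams | None = None):
    """Injected groundwater-yield effect (t/ha) at a depth and July deficit.

    Piecewise: linear waterlogging penalty shallower than ``d_low``, a
    raised-cosine subsidy bump on ``[d_low, d_high]`` peaking at ``d_opt``
    with amplitude ``s_max`` (doubled by default in very dry Julys), and
    exactly zero at or beyond ``d_high`` (free drainage).  Total function:
    defined for every depth >= 0 and any deficit.
    """
    params = params or GWEffectParams()
    d = np.asarray(depth, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    defc = np.broadcast_to(np.atleast_1d(np.asarray(deficit, dtype=float)), d.shape)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    subsidy = params.s_max * deficit_amplifier(defc, params) * subsidy_shape(d, params)
    penalty = np.where(
        d < params.d_low,
        -params.penalty_slope * params.wet_penalty_amplifier * (params.d_low - d),
        0.0,
    )
    out = subsidy + penalty
    return float(out[0]) if scalar else out


def _decompose_effect(depth, deficit, params: GWEffectParams):
    """Return (subsidy, penalty, direct, indirect) arrays for given depths."""
    d = np.asarray(depth, dtype=float)
    subsidy = params.s_max * deficit_amplifier(deficit, params) * subsidy_shape(d, params)
    penalty = np.where(
        d < params.d_low,
        -params.penalty_slope * params.wet_penalty_amplifier * (params.d_low - d),
        0.0,
    )
    indirect = (1.0 - params.direct_share) * subsidy
    direct = params.direct_share * subsidy + penalty
    return subsidy, penalty, direct, indirect


def capillary_reach_shape(depth, params: GWEffectParams):
    """Relative capillary moisture supply: 1 at the surface, 0 at free drainage.

    Capillary rise feeds the root zone monotonically — the shallower the
    water table, the larger the moisture increment — vanishing at
    ``d_high`` where the fringe no longer reaches the root zone.
    """
    d = np.asarray(depth, dtype=float)
    return np.maximum(0.0, 1.0 - d / params.d_high)


def _capillary_increment(
    depth,
    sm_standard,
    params: GWEffectParams,
    target_median: float,
    noise: np.ndarray,
):
    """Soil-moisture increment carrying the indirect subsidy channel.

    ``increment = k * reach_shape(depth) * noise`` with mean-one lognormal
    record-level ``noise`` (capillary delivery varies with soil texture and
    antecedent moisture).  ``k`` is calibrated so the realized median of
    ``increment / sm_standard`` over records within capillary reach equals
    ``target_median``; the moisture-value coefficient ``gain`` is calibrated
    so that ``gain * k * reach_shape(d_opt)`` equals the indirect share of
    the subsidy at the optimum — the point where the mechanism split is
    defined.  Returns (increment, gain, k).
    """
    zeros = np.zeros_like(sm_standard)
    if params.s_max == 0 or params.direct_share >= 1.0 or target_median <= 0:
        return zeros, 0.0, 0.0
    shape = capillary_reach_shape(depth, params) * noise
    active = shape > 1e-12
    if not active.any():
        return zeros, 0.0, 0.0
    med = float(np.median(shape[active] / sm_standard[active]))
    k = target_median / med
    reach_opt = float(capillary_reach_shape(params.d_opt, params))
    gain = (1.0 - params.direct_share) * params.s_max / (k * reach_opt)
    return k * shape, gain, k


def simulate_world(config: SimConfig, grain: str = "grid") -> pd.DataFrame:
    """Generate the synthetic cell-year (or pixel-year) table.

    Returns a long-format DataFrame, one row per record, with the injected
    per-record truth in ``true_*`` columns (split off by the pipeline
    writers into a companion truth file).  Identical (config, seed) yields
    a bit-identical table.
    """
    if grain not in ("grid", "pixel"):
        raise ValueError("grain must be 'grid' or 'pixel'")
    p = config.gw_effect
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    nc, ny = config.n_cells, config.n_years

    resid_var = (
        config.deficit_sd**2 - config.deficit_site_sd**2 - config.deficit_year_sd**2
    )
    if resid_var <= 0:
        raise ValueError(
            "deficit_sd must exceed the site and year components in quadrature"
        )
    resid_sd = np.sqrt(resid_var)

    # --- sites ---------------------------------------------------------
    lo, hi = config.wt_mean_range
    wt_mean = rng.uniform(lo, hi, nc)
    z_site = rng.standard_normal(nc)  # persistent site dryness
    tiled = rng.random(nc) < config.tile_frac
    soil_awc = np.clip(
        rng.normal(config.soil_awc_mean, config.soil_awc_sd, nc), 120.0, 350.0
    )
    drainage = rng.integers(1, 8, nc)

    # --- weather (cell x year) ----------------------------------------
    year_eff = rng.normal(0.0, config.deficit_year_sd, ny)
    deficit = (
        config.deficit_mean
        - config.deficit_site_sd * z_site[:, None]
        + year_eff[None, :]
        + rng.normal(0.0, resid_sd, (nc, ny))
    )
    deficit_anom = deficit - config.deficit_mean
    # VPD: high on persistently dry sites and in dry years, plus noise.
    anom_sd = np.sqrt(config.deficit_year_sd**2 + resid_var)
    yearcell = deficit_anom + config.deficit_site_sd * z_site[:, None]
    vpd = config.vpd_mean + config.vpd_sd * (
        0.60 * z_site[:, None]
        - 0.55 * yearcell / anom_sd
        + 0.58 * rng.standard_normal((nc, ny))
    )
    vpd = np.clip(vpd, 0.2, None)

    # --- water table (cell x year) ------------------------------------
    ar, innov = config.wt_ar1, config.wt_innovation_sd
    anom = np.empty((nc, ny))
    anom[:, 0] = rng.normal(0.0, innov / np.sqrt(1.0 - ar**2), nc)
    for t in range(1, ny):
        anom[:, t] = ar * anom[:, t - 1] + rng.normal(0.0, innov, nc)
    depth_jul = (
        wt_mean[:, None]
        + anom
        - config.wt_weather_coupling * deficit_anom / 100.0
    )
    depth_jul = np.where(tiled[:, None], np.maximum(depth_jul, config.tile_depth), depth_jul)
    depth_jul = np.maximum(depth_jul, config.min_depth)

    def _month(offset):
        m = depth_jul + offset + rng.normal(0.0, config.wt_month_sd, (nc, ny))
        m = np.where(tiled[:, None], np.maximum(m, config.tile_depth), m)
        return np.maximum(m, config.min_depth)

    depth_may = _month(-0.35)
    depth_jun = _month(-0.15)
    depth_aug = _month(+0.10)
    depth_ann = np.maximum(
        (depth_may + depth_jun + depth_jul + depth_aug) / 4.0
        - 0.10
        + rng.normal(0.0, 0.10, (nc, ny)),
        config.min_depth,
    )

    # --- soil moisture -------------------------------------------------
    sm_standard = np.clip(
        config.sm_mean
        + config.sm_deficit_slope * deficit_anom
        + config.sm_awc_slope * (soil_awc[:, None] - config.soil_awc_mean)
        + rng.normal(0.0, config.sm_noise_sd, (nc, ny)),
        40.0,
        None,
    )

    # --- grain-specific latent depth -----------------------------------
    if grain == "pixel":
        npx = config.pixels_per_cell
        shape3 = (nc, ny, npx)
        pixel_depth = depth_jul[:, :, None] + rng.normal(0.0, config.pixel_depth_sd, shape3)
        pixel_depth = np.where(
            tiled[:, None, None], np.maximum(pixel_depth, config.tile_depth), pixel_depth
        )
        pixel_depth = np.maximum(pixel_depth, config.min_depth)
        eff_depth = pixel_depth
        eff_deficit = np.broadcast_to(deficit[:, :, None], shape3)
        eff_sm = np.broadcast_to(sm_standard[:, :, None], shape3)
        noise_sd = config.pixel_yield_noise_sd
    else:
        eff_depth = depth_jul
        eff_deficit = deficit
        eff_sm = sm_standard
        noise_sd = config.noise_sd

    subsidy, penalty, direct, indirect = _decompose_effect(eff_depth, eff_deficit, p)
    sig = config.capillary_noise_sd
    if sig > 0:
        u = np.exp(rng.normal(-0.5 * sig**2, sig, eff_depth.shape))
    else:
        u = np.ones_like(eff_depth)
    dsm, cap_gain, cap_k = _capillary_increment(
        eff_depth, eff_sm, p, config.capillary_boost_median, u
    )
    if cap_gain > 0:
        # Indirect channel: the realized yield value of the capillary
        # moisture increment.  The structural direct part is whatever of
        # the total effect the capillary channel does not deliver on
        # average, so the conditional-mean total stays subsidy + penalty
        # exactly; at d_opt the split is (direct_share, 1 - direct_share).
        indirect = cap_gain * dsm
        direct = subsidy + penalty - cap_gain * cap_k * capillary_reach_shape(eff_depth, p)
    sm_enhanced = eff_sm + dsm
    # One moisture-value coefficient for both channels: the yield responds to
    # *effective* moisture (top-down + capillary) at a single rate, which is
    # what lets the soil-moisture covariate swap identify the direct share.
    # When the capillary channel is active that rate is the calibrated gain
    # (indirect term == gain * increment == indirect subsidy share exactly);
    # otherwise the configured slope applies.
    sm_slope = cap_gain if cap_gain > 0 else config.yield_sm_slope

    stress = np.maximum(0.0, -(eff_deficit + 50.0)) / 100.0
    awc_b = soil_awc[:, None] if grain == "grid" else soil_awc[:, None, None]
    drn_b = drainage[:, None] if grain == "grid" else drainage[:, None, None]
    base = (
        config.base_yield
        + config.yield_awc_slope * (awc_b - config.soil_awc_mean)
        + sm_slope * (eff_sm - config.sm_mean)
        + 0.05 * (drn_b - 4)
        - config.stress_linear * stress
        - config.stress_quadratic * stress**2
    )
    effect = direct + indirect  # == subsidy + penalty exactly
    yld = np.maximum(base + effect + rng.normal(0.0, noise_sd, eff_depth.shape), 0.1)

    prices = np.asarray(config.prices())

    # --- assemble ------------------------------------------------------
    if grain == "grid":
        cell_id = np.repeat(np.arange(nc), ny)
        year = np.tile(np.arange(ny), nc)
        flat = lambda a: np.asarray(a).reshape(-1)  # noqa: E731
        pixel_id = np.zeros(nc * ny, dtype=int)
        area = config.area_per_cell
        true_pixel_depth = flat(depth_jul)
        rec = {
            "wt_depth_may": flat(depth_may),
            "wt_depth_jun": flat(depth_jun),
            "wt_depth_jul": flat(depth_jul),
            "wt_depth_aug": flat(depth_aug),
            "wt_depth_annual": flat(depth_ann),
            "deficit_july": flat(deficit),
            "vpd": flat(vpd),
            "sm_standard": flat(sm_standard),
            "sm_enhanced": flat(sm_enhanced),
            "yield_t_ha": flat(yld),
            "true_subsidy": flat(subsidy),
            "true_penalty": flat(penalty),
            "true_direct": flat(direct),
            "true_indirect": flat(indirect),
        }
    else:
        npx = config.pixels_per_cell
        cell_id = np.repeat(np.arange(nc), ny * npx)
        year = np.tile(np.repeat(np.arange(ny), npx), nc)
        pixel_id = cell_id * npx + np.tile(np.arange(npx), nc * ny)
        area = config.area_per_cell / npx
        flat = lambda a: np.asarray(a).reshape(-1)  # noqa: E731
        bcast = lambda a: np.broadcast_to(  # noqa: E731
            np.asarray(a)[:, :, None], (nc, ny, npx)
        ).reshape(-1)
        true_pixel_depth = flat(eff_depth)
        rec = {
            "wt_depth_may": bcast(depth_may),
            "wt_depth_jun": bcast(depth_jun),
            "wt_depth_jul": bcast(depth_jul),
            "wt_depth_aug": bcast(depth_aug),
            "wt_depth_annual": bcast(depth_ann),
            "deficit_july": bcast(deficit),
            "vpd": bcast(vpd),
            "sm_standard": bcast(sm_standard),
            "sm_enhanced": flat(sm_enhanced),
            "yield_t_ha": flat(yld),
            "true_subsidy": flat(subsidy),
            "true_penalty": flat(penalty),
            "true_direct": flat(direct),
            "true_indirect": flat(indirect),
        }

    df = pd.DataFrame(
        {
            "cell_id": cell_id,
            "pixel_id": pixel_id,
            "year": year,
            "tiled": np.repeat(tiled, len(cell_id) // nc).astype(int),
            "soil_awc": np.repeat(soil_awc, len(cell_id) // nc),
            "drainage_class": np.repeat(drainage, len(cell_id) // nc),
            **rec,
        }
    )
    df["true_effect"] = df["true_direct"] + df["true_indirect"]
    df["true_pixel_depth"] = true_pixel_depth
    df["weather_class"] = [w.value for w in classify_weather(df["deficit_july"].to_numpy())]
    df["price_usd_t"] = prices[df["year"].to_numpy()]
    df["area_ha"] = area
    df["production_t"] = df["yield_t_ha"] * df["area_ha"]
    df.attrs["gw_effect"] = asdict(p)
    df.attrs["capillary_gain"] = cap_gain
    df.attrs["grain"] = grain
    df.attrs["seed"] = config.seed
    return df


def split_truth(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a simulated table into (observables, truth) for serialization."""
    keys = ["cell_id", "pixel_id", "year"]
    truth = df[keys + [c for c in TRUTH_COLUMNS if c in df.columns]].copy()
    data = df.drop(columns=[c for c in TRUTH_COLUMNS if c in df.columns])
    return data, truth
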