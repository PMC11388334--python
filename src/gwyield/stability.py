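"""Yield-stability analysis: CV against mean groundwater depth, by VPD tercile.

Each sample location's interannual yield variability (CV, percent) is
related to its long-run mean July depth-to-water with the same surrogate +
ALE machinery used for yields.  Locations are stratified into terciles of
their mean vapor pressure deficit: where atmospheric demand is high, the
buffering value of groundwater access should be largest.  Nothing in the
generator encodes CV — any depth-CV relationship is emergent, arising only
because the subsidy offsets dry-year losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ale import ALECurve, compute_ale
from .config import StageOptions, SurrogateSpec
from .surrogate import fit_surrogate

logger = logging.getLogger(__name__)

LOCATION_COVARIATES = ["mean_depth", "mean_vpd", "soil_awc", "drainage_class", "tiled"]


@dataclass
class StabilityResult:
    """Per-location table, overall CV curve and per-tercile curves."""

    locations: pd.DataFrame
    curve_all: ALECurve
    curves_by_tercile: dict[str, ALECurve] = field(default_factory=dict)
    n_dropped: int = 0

    def cv_gap(self, shallow: float = 1.0, deep: float = 3.5,
               tercile: str | None = None, window: float = 0.6) -> float:
        """CV(deep) - CV(shallow); positive = shallower is more stable.

        Each endpoint is the curve averaged over a depth window centred on
        it, which damps single-bin noise in the CV response.
        """
        curve = self.curve_all if tercile is None else self.curves_by_tercile[tercile]

        def level(d):
            pts = np.linspace(d - window / 2, d + window / 2, 7)
            return float(np.mean(curve.evaluate(pts)))

        return level(deep) - level(shallow)


def location_table(pixel_data: pd.DataFrame, min_years: int = 5,
                   depth_col: str = "wt_depth_jul") -> tuple[pd.DataFrame, int]:
    """Collapse pixel-year records to one row per location.

    A location's depth is its mean July depth over maize years; its CV the
    interannual coefficient of variation of yields.  Locations with fewer
    than ``min_years`` records (or an undefined CV) are dropped.
    """
    loc_key = "pixel_id" if "pixel_id" in pixel_data.columns else "cell_id"
    grp = pixel_data.groupby(loc_key)
    agg = pd.DataFrame(
        {
            "n_years": grp["yield_t_ha"].size(),
            "mean_y": grp["yield_t_ha"].mean(),
            "sd_y": grp["yield_t_ha"].std(ddof=1),  # sample SD, as in the CV metric
            "mean_depth": grp[depth_col].mean(),
            "mean_vpd": grp["vpd"].mean(),
            "soil_awc": grp["soil_awc"].first(),
            "drainage_class": grp["drainage_class"].first(),
            "tiled": grp["tiled"].first(),
        }
    )
    ok = (agg["n_years"] >= min_years) & (agg["mean_y"] > 0) & agg["sd_y"].notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("location_table: %d locations dropped", dropped)
    agg = agg[ok]
    locs = pd.DataFrame(
        {
            "location": agg.index.to_numpy(),
            "cv": (agg["sd_y"] / agg["mean_y"] * 100.0).to_numpy(),
            "mean_depth": agg["mean_depth"].to_numpy(),
            "mean_vpd": agg["mean_vpd"].to_numpy(),
            "soil_awc": agg["soil_awc"].to_numpy(),
            "drainage_class": agg["drainage_class"].to_numpy(),
            "tiled": agg["tiled"].to_numpy().astype(int),
            "n_years": agg["n_years"].to_numpy(),
        }
    )
    return locs, dropped


def assign_vpd_terciles(locations: pd.DataFrame) -> pd.Series:
    """Tercile labels (low/mid/high) from location-mean VPD.

    Group sizes differ by at most 2; ties at the boundaries are broken by
    location id for determinism.
    """
    order = locations.sort_values(["mean_vpd", "location"]).index.to_numpy()
    labels = pd.Series(index=locations.index, dtype=object)
    for name, chunk in zip(("low", "mid", "high"), np.array_split(order, 3)):
        labels.loc[chunk] = name
    return labels


def stability_analysis(
    pixel_data: pd.DataFrame,
    spec: SurrogateSpec | None = None,
    options: StageOptions | None = None,
    min_years: int = 5,
    depth_col: str = "wt_depth_jul",
) -> StabilityResult:
    """CV response to mean groundwater depth, overall and per VPD tercile."""
    spec = spec or SurrogateSpec()
    options = options or StageOptions()
    locs, dropped = location_table(pixel_data, min_years=min_years, depth_col=depth_col)
    if len(locs) < 30:
        raise ValueError("too few locations for a stability analysis")
    locs = locs.copy()
    locs["vpd_tercile"] = assign_vpd_terciles(locs)

    cv_spec = replace(
        spec,
        predictors=tuple(LOCATION_COVARIATES),
        target="cv",
        m_try=min(spec.m_try, len(LOCATION_COVARIATES)),
    )
    fit = fit_surrogate(locs, cv_spec)
    # CV curves use coarser bins than yield curves: location tables are
    # small and the response is a broad trend, not a sharp bump
    k = min(options.k_bins // 2, max(2, len(locs) // 20))
    curve_all = compute_ale(fit.predict, locs, "mean_depth", k)

    curves = {}
    for name in ("low", "mid", "high"):
        sub = locs[locs["vpd_tercile"] == name]
        sfit = fit_surrogate(sub, cv_spec)
        curves[name] = compute_ale(
            sfit.predict, sub, "mean_depth", min(k, max(2, len(sub) // 10))
        )
    return StabilityResult(locs, curve_all, curves, dropped)
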