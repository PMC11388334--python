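"""Prevalence tallies and monetary accounting of groundwater yield impacts.

A cell-year offers a *subsidy* only when groundwater access (July depth
inside the subsidy zone) coincides with a yield-limiting water deficit;
*penalty* conditions are July depths shallower than the penalty threshold.
Tallies count these conditions per cell and regionally; the monetary
report prices them with per-condition effect percentages applied to
realized production value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zones import ZoneReport

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ["penalty", "access", "dry", "very_dry", "subsidy", "strong_subsidy"]


@dataclass
class PrevalenceTally:
    per_cell: pd.DataFrame  # one row per cell: counts of condition years
    fractions: dict  # regional fractions of cell-years per condition
    annual_extent: pd.Series  # fraction of cells with a subsidy, per year
    mean_subsidy_frequency: float  # mean per-cell fraction of subsidy years
    thresholds: dict = field(default_factory=dict)


@dataclass
class MonetaryReport:
    annual: pd.DataFrame  # per-year subsidy/penalty dollars
    total_subsidy_usd: float
    total_penalty_usd: float
    net_usd: float
    effect_pcts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_subsidy_usd": self.total_subsidy_usd,
            "total_penalty_usd": self.total_penalty_usd,
            "net_usd": self.net_usd,
            "effect_pcts": self.effect_pcts,
            "annual": self.annual.to_dict(orient="list"),
        }


def flag_conditions(
    data: pd.DataFrame,
    zones: ZoneReport | None = None,
    penalty_threshold: float | None = None,
    subsidy_low: float | None = None,
    subsidy_high: float | None = None,
    dry_threshold: float = -50.0,
    very_dry_threshold: float = -150.0,
    depth_col: str = "wt_depth_jul",
    deficit_col: str = "deficit_july",
) -> pd.DataFrame:
    """Append boolean penalty/access/dry/very_dry/subsidy/strong_subsidy columns.

    Zone thresholds come from a delineated ZoneReport, or must be supplied
    explicitly.  Zone membership uses the closed interval
    ``[subsidy_low, subsidy_high]``; penalty is strictly shallower than the
    penalty threshold, so a cell-year is never both.  Rows with missing
    depth or deficit are rejected (count logged).
    """
    if zones is not None and zones.subsidy_detected:
        subsidy_low = zones.subsidy_low if subsidy_low is None else subsidy_low
        subsidy_high = zones.subsidy_high if subsidy_high is None else subsidy_high
        penalty_threshold = (
            zones.penalty_threshold if penalty_threshold is None else penalty_threshold
        )
    if subsidy_low is None or subsidy_high is None or penalty_threshold is None:
        raise ValueError(
            "no detected zone: supply penalty_threshold, subsidy_low and subsidy_high"
        )

    depth = data[depth_col].to_numpy(dtype=float)
    deficit = data[deficit_col].to_numpy(dtype=float)
    ok = np.isfinite(depth) & np.isfinite(deficit)
    if (~ok).any():
        logger.info("flag_conditions: %d rows with missing depth/deficit rejected",
                    int((~ok).sum()))
    out = data.loc[ok].copy()
    depth, deficit = depth[ok], deficit[ok]
    out["penalty"] = depth < penalty_threshold
    out["access"] = (depth >= subsidy_low) & (depth <= subsidy_high)
    out["dry"] = deficit < dry_threshold
    out["very_dry"] = deficit < very_dry_threshold
    out["subsidy"] = out["access"] & out["dry"]
    out["strong_subsidy"] = out["access"] & out["very_dry"]
    out.attrs["thresholds"] = {
        "penalty_threshold": float(penalty_threshold),
        "subsidy_low": float(subsidy_low),
        "subsidy_high": float(subsidy_high),
        "dry_threshold": float(dry_threshold),
        "very_dry_threshold": float(very_dry_threshold),
    }
    return out


def tally(flagged: pd.DataFrame) -> PrevalenceTally:
    """Exact per-cell counts and regional fractions of condition years."""
    missing = [c for c in FLAG_COLUMNS if c not in flagged.columns]
    if missing:
        raise KeyError(f"flagged table lacks columns: {missing}")
    per_cell = (
        flagged.groupby("cell_id")[FLAG_COLUMNS].sum().astype(int)
        .rename(columns={c: f"{c}_years" for c in FLAG_COLUMNS})
    )
    per_cell["n_years"] = flagged.groupby("cell_id").size()
    n = len(flagged)
    fractions = {c: float(flagged[c].sum()) / n for c in FLAG_COLUMNS}
    annual_extent = flagged.groupby("year")["subsidy"].mean()
    mean_freq = float(
        (per_cell["subsidy_years"] / per_cell["n_years"]).mean()
    )
    return PrevalenceTally(
        per_cell=per_cell,
        fractions=fractions,
        annual_extent=annual_extent,
        mean_subsidy_frequency=mean_freq,
        thresholds=dict(flagged.attrs.get("thresholds", {})),
    )


def monetary_impact(
    flagged: pd.DataFrame,
    effect_pcts: tuple[float, float, float] = (-0.01, 0.034, 0.078),
    production_col: str = "production_t",
    price_col: str = "price_usd_t",
) -> MonetaryReport:
    """Dollar value of subsidies and penalties over all cell-years.

    ``effect_pcts`` are (penalty, subsidy, strong_subsidy) fractions of
    realized production value.  A strong-subsidy (very dry) cell-year uses
    the stronger rate *instead of* the plain subsidy rate, never both.
    Penalties are reported as positive costs.
    """
    penalty_pct, subsidy_pct, strong_pct = effect_pcts
    prod = flagged[production_col].to_numpy(dtype=float)
    price = flagged[price_col].to_numpy(dtype=float)
    if np.any(prod < 0) or np.any(price < 0):
        raise ValueError("negative production or price rejected")
    value = prod * price
    sub_rate = np.where(
        flagged["strong_subsidy"], strong_pct, np.where(flagged["subsidy"], subsidy_pct, 0.0)
    )
    pen_rate = np.where(flagged["penalty"], abs(penalty_pct), 0.0)
    df = pd.DataFrame(
        {
            "year": flagged["year"].to_numpy(),
            "subsidy_usd": value * sub_rate,
            "penalty_usd": value * pen_rate,
        }
    )
    annual = df.groupby("year").sum()
    total_sub = float(annual["subsidy_usd"].sum())
    total_pen = float(annual["penalty_usd"].sum())
    return MonetaryReport(
        annual=annual.reset_index(),
        total_subsidy_usd=total_sub,
        total_penalty_usd=total_pen,
        net_usd=total_sub - total_pen,
        effect_pcts={
            "penalty_pct": penalty_pct,
            "subsidy_pct": subsidy_pct,
            "strong_subsidy_pct": strong_pct,
        },
    )
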