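"""Delineate subsidy/penalty zones from an ALE curve over July depth-to-water.

The yield-effect curve is read the way the study reads its plots: a flat
terminal plateau at deep water tables is the free-drainage baseline; the
effect maximum shallower than the plateau is the optimum; the subsidy zone
runs from the shallow baseline crossing to the plateau onset; depths
shallower than that crossing are the waterlogging penalty zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ale import ALECurve, compute_ale
from .config import SurrogateSpec
from .metrics import CLASS_ORDER
from .surrogate import fit_surrogate

logger = logging.getLogger(__name__)


@dataclass
class ZoneReport:
    """Headline quantities read off a yield-effect curve over depth.

    Depths in metres, effects in t/ha; percentage magnitudes are t/ha
    magnitudes divided by ``mean_yield`` times 100.
    """

    baseline_found: bool = False
    subsidy_detected: bool = False
    baseline_effect: float = float("nan")
    d_free: float = float("nan")
    d_opt: float = float("nan")
    subsidy_low: float = float("nan")
    subsidy_high: float = float("nan")
    penalty_threshold: float = float("nan")
    max_subsidy: float = float("nan")
    max_subsidy_pct: float = float("nan")
    max_subsidy_ci: tuple[float, float] | None = None
    penalty_at_mean_depth: float = float("nan")
    penalty_at_mean_depth_pct: float = float("nan")
    mean_penalty_depth: float = float("nan")
    mean_yield: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return out


def _terminal_plateau(curve: ALECurve, slope_tol: float, smooth_window: int = 3) -> int | None:
    """Index of the shallowest edge of the terminal flat segment, or None.

    Slopes are measured on a lightly smoothed copy of the curve (moving
    average over ``smooth_window`` edges) so single-bin estimation noise
    does not break an otherwise flat plateau; the effect values themselves
    are never smoothed.
    """
    eff = curve.effect
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        eff = np.convolve(np.pad(eff, pad, mode="edge"), kernel, mode="valid")
    slopes = np.diff(eff) / np.diff(curve.edges)
    j = len(slopes)
    while j > 0 and abs(slopes[j - 1]) <= slope_tol:
        j -= 1
    if j == len(slopes):  # even the deepest bin is sloped
        return None
    return j


def _weighted_bin_mean(curve: ALECurve, lo_edge: int, hi_edge: int) -> float:
    """Count-weighted mean of bin-midpoint effects over edges [lo_edge, hi_edge]."""
    mids = (curve.effect[lo_edge:hi_edge] + curve.effect[lo_edge + 1 : hi_edge + 1]) / 2.0
    w = curve.counts[lo_edge:hi_edge]
    return float(np.sum(mids * w) / np.sum(w))


def delineate(
    curve: ALECurve,
    mean_yield: float = float("nan"),
    slope_tol: float = 0.05,
    min_plateau_width: float = 0.8,
    depths: np.ndarray | None = None,
    baseline_region: float | None = None,
    smooth_window: int = 3,
) -> ZoneReport:
    """Turn a depth ALE curve into a ZoneReport.

    Scans from the deep end for the longest terminal segment whose
    per-edge slopes all stay within ``slope_tol`` (t/ha per m); if it is at
    least ``min_plateau_width`` wide it becomes the free-drainage plateau
    and its count-weighted mean effect the baseline.  ``baseline_region``
    (a depth) forces the baseline to be computed over all edges at least
    that deep — the fallback used when a noisy curve has lost its plateau
    and an externally delineated free-drainage onset is trusted instead.
    The optimum is the effect argmax shallower than the plateau; the
    subsidy-zone shallow bound is the baseline crossing nearest the
    optimum (linear interpolation between edges); the penalty is the
    effect shortfall below the baseline for shallower depths, quantified
    at the mean observed depth within the penalty zone when ``depths`` are
    supplied (bin-count weighted mids otherwise).
    """
    if len(curve.edges) < 10:
        raise ValueError("curve too coarse: need at least 10 edges")
    rep = ZoneReport(mean_yield=mean_yield)

    j0 = _terminal_plateau(curve, slope_tol, smooth_window)
    if j0 is not None and curve.edges[-1] - curve.edges[j0] >= min_plateau_width:
        rep.baseline_found = True
        rep.d_free = float(curve.edges[j0])
        rep.baseline_effect = _weighted_bin_mean(curve, j0, len(curve.edges) - 1)
    elif baseline_region is not None:
        j0 = int(np.searchsorted(curve.edges, baseline_region, side="left"))
        j0 = min(j0, len(curve.edges) - 2)
        rep.baseline_found = False
        rep.flags.append("no free-drainage baseline; external baseline region used")
        rep.d_free = float(curve.edges[j0])
        rep.baseline_effect = _weighted_bin_mean(curve, j0, len(curve.edges) - 1)
    else:
        rep.flags.append("no free-drainage baseline")
        return rep

    if j0 == 0:
        rep.flags.append("plateau spans the whole curve; no subsidy detected")
        return rep

    # optimum over edges shallower than the plateau onset, with a 3-point
    # parabolic refinement: the curve is only sampled at bin edges, so the
    # raw argmax underestimates a peak falling between edges
    search = np.arange(0, j0 + 1)
    i_opt = int(search[np.argmax(curve.effect[search])])
    d_opt, peak = float(curve.edges[i_opt]), float(curve.effect[i_opt])
    if 1 <= i_opt <= len(curve.edges) - 2:
        x = curve.edges[i_opt - 1 : i_opt + 2]
        y = curve.effect[i_opt - 1 : i_opt + 2]
        a, b, c = np.polyfit(x - x[1], y, 2)
        if a < 0:  # concave: vertex is the refined peak
            v = float(np.clip(-b / (2 * a), x[0] - x[1], x[2] - x[1]))
            d_opt, peak = float(x[1] + v), float(a * v**2 + b * v + c)
    rep.d_opt = d_opt
    rep.max_subsidy = float(peak - rep.baseline_effect)
    rep.max_subsidy_pct = rep.max_subsidy / mean_yield * 100.0
    if curve.band_low is not None:
        rep.max_subsidy_ci = (
            float(curve.band_low[i_opt] - rep.baseline_effect),
            float(curve.band_high[i_opt] - rep.baseline_effect),
        )

    significant = True
    if curve.band_low is not None:
        # conservative call: the lower envelope at the optimum must clear
        # the *upper* envelope of the baseline (count-weighted over the
        # plateau), guarding against argmax selection on a noisy curve
        up = curve.band_high
        mids = (up[j0:-1] + up[j0 + 1 :]) / 2.0
        w = curve.counts[j0:]
        baseline_up = float(np.sum(mids * w) / np.sum(w))
        significant = float(curve.band_low[i_opt]) > baseline_up
    if rep.max_subsidy <= 0.0 or not significant:
        rep.flags.append("no subsidy detected")
        rep.max_subsidy = max(rep.max_subsidy, 0.0)
        rep.max_subsidy_pct = rep.max_subsidy / mean_yield * 100.0
        return rep

    rep.subsidy_detected = True
    rep.subsidy_high = rep.d_free

    # shallow crossing of the baseline, nearest the optimum
    rel = curve.effect - rep.baseline_effect
    low = float(curve.edges[0])
    for i in range(i_opt, 0, -1):
        if rel[i - 1] <= 0.0 < rel[i]:
            frac = rel[i] / (rel[i] - rel[i - 1])
            low = float(curve.edges[i] + frac * (curve.edges[i - 1] - curve.edges[i]))
            break
    else:
        rep.flags.append("subsidy zone extends to the shallow data edge")
    rep.subsidy_low = low
    rep.penalty_threshold = low

    # penalty magnitude at the mean observed depth within the penalty zone
    if depths is not None:
        depths = np.asarray(depths, dtype=float)
        inzone = depths[depths < low]
        mean_depth = float(inzone.mean()) if inzone.size else float("nan")
    else:
        mids = (curve.edges[:-1] + curve.edges[1:]) / 2.0
        sel = mids < low
        if sel.any():
            mean_depth = float(
                np.sum(mids[sel] * curve.counts[sel]) / np.sum(curve.counts[sel])
            )
        else:
            mean_depth = float("nan")
    rep.mean_penalty_depth = mean_depth
    if np.isfinite(mean_depth):
        rep.penalty_at_mean_depth = float(
            rep.baseline_effect - curve.evaluate(mean_depth)
        )
        rep.penalty_at_mean_depth_pct = rep.penalty_at_mean_depth / mean_yield * 100.0
    return rep


def stratified_effects(
    data: pd.DataFrame,
    spec: SurrogateSpec,
    depth_col: str = "wt_depth_jul",
    strata_col: str = "weather_class",
    k_bins: int = 40,
    slope_tol: float = 0.05,
    min_plateau_width: float = 0.8,
    min_n: int = 500,
    classes: list[str] | None = None,
    all_pair: tuple[ALECurve, ZoneReport] | None = None,
) -> dict[str, tuple[ALECurve, ZoneReport]]:
    """Per-stratum ALE curves and zone reports, plus the all-sample pair.

    The surrogate is refitted within each stratum (weather class by
    default).  Stratum curves are delineated against the all-sample
    free-drainage region so the very-dry : all max-subsidy ratio compares
    like with like; strata with fewer than ``min_n`` rows are skipped with
    a warning.  ``classes`` restricts which strata are fitted; a
    previously computed all-sample (curve, report) pair can be passed in
    to avoid refitting it.
    """
    out: dict[str, tuple[ALECurve, ZoneReport]] = {}
    if all_pair is not None:
        curve, all_rep = all_pair
        fit = None
    else:
        fit = fit_surrogate(data, spec)
        curve = compute_ale(fit.predict, data, depth_col, k_bins)
        mean_yield = float(data[spec.target].mean())
        all_rep = delineate(
            curve, mean_yield, slope_tol, min_plateau_width,
            depths=data[depth_col].to_numpy(),
        )
    out["all"] = (curve, all_rep)
    region = all_rep.d_free if np.isfinite(all_rep.d_free) else None

    order = [c for c in CLASS_ORDER if c in data[strata_col].unique()]
    if classes is not None:
        order = [c for c in order if c in classes]
    for cls in order:
        sub = data[data[strata_col] == cls]
        if len(sub) < min_n:
            logger.warning("stratum %s skipped (n=%d < %d)", cls, len(sub), min_n)
            continue
        preds = tuple(fit.predictors) if fit is not None else spec.predictors
        sfit = fit_surrogate(sub, replace(spec, predictors=preds))
        scurve = compute_ale(sfit.predict, sub, depth_col, k_bins)
        srep = delineate(
            scurve,
            float(sub[spec.target].mean()),
            slope_tol,
            min_plateau_width,
            depths=sub[depth_col].to_numpy(),
            baseline_region=region,
        )
        out[cls] = (scurve, srep)
    return out
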