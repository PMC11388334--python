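"""Statsmodels-style entry point: GroundwaterYieldModel / GroundwaterYieldResults.

The model wraps a cell-year (or pixel-year) yield table; ``fit`` screens
the groundwater period (optionally), fits the bagged-tree surrogate,
computes the ALE yield-response curve over July depth-to-water (optionally
with a cluster-bootstrap band) and delineates the subsidy/penalty zones.
The Results object carries the estimates, their uncertainties and
diagnostics, and exposes the follow-up analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from . import metrics
from .ale import ALECurve, bootstrap_ale, compute_ale
from .config import SimConfig, StageOptions, SurrogateSpec
from .surrogate import FittedSurrogate, fit_surrogate, screen_groundwater_period
from .synthetic_world import BASE_COVARIATES, simulate_world
from .zones import ZoneReport, delineate, stratified_effects


class GroundwaterYieldModel:
    """Yield-response model of groundwater depth for one observation table.

    Parameters
    ----------
    data : DataFrame
        Long-format records; must contain the target, the depth column and
        the covariates.
    depth_col : str
        Groundwater depth predictor the response curve is computed over
        (July depth by default; screening can override it).
    predictors : sequence of str, optional
        Covariate panel.  Defaults to the standard panel (July deficit,
        VPD, soils, tile status, top-down soil moisture) plus ``depth_col``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        depth_col: str = "wt_depth_jul",
        target: str = "yield_t_ha",
        predictors: list[str] | None = None,
        surrogate_spec: SurrogateSpec | None = None,
        options: StageOptions | None = None,
    ) -> None:
        self.data = data
        self.depth_col = depth_col
        self.target = target
        self.options = options or StageOptions()
        if predictors is None:
            predictors = [c for c in BASE_COVARIATES if c in data.columns] + [depth_col]
        self.predictors = list(predictors)
        spec = surrogate_spec or SurrogateSpec()
        self.surrogate_spec = replace(
            spec,
            predictors=tuple(self.predictors),
            target=target,
            m_try=min(spec.m_try, len(self.predictors)),
        )

    @classmethod
    def from_simulation(
        cls, config: SimConfig, grain: str = "grid", **kwargs
    ) -> "GroundwaterYieldModel":
        return cls(simulate_world(config, grain=grain), **kwargs)

    def fit(
        self,
        screen: bool = False,
        n_boot: int = 0,
        seed: int | None = None,
    ) -> "GroundwaterYieldResults":
        """Fit the surrogate and derive the depth response curve and zones.

        ``screen=True`` runs greedy forward selection over the monthly and
        annual depth columns first and uses the first selected period as
        the response variable.  ``n_boot > 0`` adds a cluster-bootstrap
        band to the curve (and a CI to the max-subsidy scalar).
        """
        spec = self.surrogate_spec
        if seed is not None:
            spec = replace(spec, seed=seed)
        depth_col = self.depth_col
        predictors = list(self.predictors)
        selected: list[str] = []
        if screen:
            selected = screen_groundwater_period(self.data, spec=replace(spec, predictors=None), seed=spec.seed)
            if selected:
                depth_col = selected[0]
                base = [c for c in predictors if c not in set(selected) | {self.depth_col, depth_col}]
                predictors = base + selected
            spec = replace(spec, predictors=tuple(predictors), m_try=min(spec.m_try, len(predictors)))

        fitted = fit_surrogate(self.data, spec)
        if n_boot > 0:
            factory = lambda d: fit_surrogate(d, spec).predict  # noqa: E731
            curve = bootstrap_ale(
                factory, self.data, depth_col,
                k_bins=self.options.k_bins, n_boot=n_boot, seed=spec.seed,
            )
        else:
            curve = compute_ale(fitted.predict, self.data, depth_col, self.options.k_bins)
        mean_yield = float(self.data[self.target].mean())
        zones = delineate(
            curve,
            mean_yield,
            slope_tol=self.options.slope_tol,
            min_plateau_width=self.options.min_plateau_width,
            depths=self.data[depth_col].to_numpy(),
        )
        return GroundwaterYieldResults(
            model=self,
            surrogate=fitted,
            depth_col=depth_col,
            depth_curve=curve,
            zones=zones,
            selected_periods=selected,
            mean_yield=mean_yield,
        )


@dataclass
class GroundwaterYieldResults:
    """Fit results: surrogate diagnostics, response curve and zone report."""

    model: GroundwaterYieldModel
    surrogate: FittedSurrogate
    depth_col: str
    depth_curve: ALECurve
    zones: ZoneReport
    selected_periods: list[str] = field(default_factory=list)
    mean_yield: float = float("nan")

    @property
    def oob_r2(self) -> float:
        return self.surrogate.oob_r2

    @property
    def oob_mse(self) -> float:
        return self.surrogate.oob_mse

    def ale(self, feature: str, k_bins: int | None = None) -> ALECurve:
        """ALE curve of the fitted surrogate along any predictor."""
        return compute_ale(
            self.surrogate.predict,
            self.model.data,
            feature,
            k_bins or self.model.options.k_bins,
        )

    def stratified_effects(self, min_n: int = 500) -> dict[str, tuple[ALECurve, ZoneReport]]:
        """Refit and delineate within July water-deficit classes."""
        return stratified_effects(
            self.model.data,
            self.surrogate.spec,
            depth_col=self.depth_col,
            k_bins=self.model.options.k_bins,
            slope_tol=self.model.options.slope_tol,
            min_plateau_width=self.model.options.min_plateau_width,
            min_n=min_n,
        )

    def agreement(self, observed: str | None = None, by_class: bool = True) -> pd.DataFrame:
        """R²/RMSE of surrogate predictions against the target, by weather class."""
        data = self.model.data
        obs = data[observed or self.model.target].to_numpy(dtype=float)
        pred = self.surrogate.predict(data)
        wc = data["weather_class"] if by_class and "weather_class" in data.columns else None
        return metrics.agreement(obs, pred, weather_class=wc)

    def summary(self) -> str:
        z = self.zones
        lines = [
            "Groundwater yield response — surrogate + ALE fit",
            "=" * 52,
            f"observations:        {len(self.model.data):>10d}",
            f"depth variable:      {self.depth_col:>10s}",
            f"screened periods:    {', '.join(self.selected_periods) or '(none)'}",
            f"OOB R2:              {self.oob_r2:10.3f}",
            f"OOB MSE (t/ha)^2:    {self.oob_mse:10.3f}",
            f"mean yield (t/ha):   {self.mean_yield:10.2f}",
            "-" * 52,
            f"free-drainage onset d_free (m):  {z.d_free:8.2f}",
            f"baseline effect (t/ha):          {z.baseline_effect:8.3f}",
            f"optimum depth d_opt (m):         {z.d_opt:8.2f}",
            f"subsidy zone (m):                [{z.subsidy_low:.2f}, {z.subsidy_high:.2f}]",
            f"max subsidy (t/ha):              {z.max_subsidy:8.3f}",
            f"max subsidy (% of mean yield):   {z.max_subsidy_pct:8.2f}",
        ]
        if z.max_subsidy_ci is not None:
            lines.append(
                f"max subsidy 95% CI (t/ha):       [{z.max_subsidy_ci[0]:.3f}, {z.max_subsidy_ci[1]:.3f}]"
            )
        lines += [
            f"penalty threshold (m):           {z.penalty_threshold:8.2f}",
            f"penalty at mean zone depth (%):  {z.penalty_at_mean_depth_pct:8.2f}",
            f"subsidy detected:                {str(z.subsidy_detected):>8s}",
        ]
        if z.flags:
            lines.append("flags: " + "; ".join(z.flags))
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_zone

        return plot_zone(self.depth_curve, self.zones, ax=ax)
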