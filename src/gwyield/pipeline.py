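"""Reproducible end-to-end pipeline: simulate -> evaluate -> fit -> ale -> zones
-> attenuate -> mechanism -> stability -> prevalence -> report.

Every stage writes its artifacts (CSV/Parquet/JSON) into a run directory
together with a manifest recording the resolved configuration, the master
seed, per-stage child seeds and content hashes, so a run is fully
auditable and identical (config, seed) pairs produce byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import pixel_attenuation, run_attenuation_experiment
from .config import SimConfig, StageOptions, SurrogateSpec, load_config
from .mechanism import capillary_boost_summary, mechanism_split
from .metrics import agreement
from .model import GroundwaterYieldModel
from .prevalence import flag_conditions, monetary_impact, tally
from .stability import stability_analysis
from .synthetic_world import simulate_world, split_truth
from .zones import stratified_effects

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "evaluate", "fit", "ale", "zones",
    "attenuate", "mechanism", "stability", "prevalence", "report",
]


def _child_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=master, spawn_key=(k,)).generate_state(1)[0] % 2**31)


class PipelineRun:
    """One run directory bound to a resolved configuration."""

    def __init__(
        self,
        out_dir: str | Path,
        sim: SimConfig | None = None,
        spec: SurrogateSpec | None = None,
        stages: StageOptions | None = None,
        seed: int | None = None,
    ) -> None:
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.sim = sim or SimConfig()
        if seed is not None:
            self.sim = replace(self.sim, seed=seed)
        master = self.sim.seed
        self.seeds = {s: _child_seed(master, k) for k, s in enumerate(STAGES)}
        self.spec = replace(spec or SurrogateSpec(), seed=self.seeds["fit"])
        self.stages = stages or StageOptions()
        self._grid = None
        self._pixel = None
        self._results = None

    @classmethod
    def from_config_file(cls, path: str | Path, out_dir: str | Path,
                         seed: int | None = None) -> "PipelineRun":
        sim, spec, stages = load_config(path)
        return cls(out_dir, sim, spec, stages, seed=seed)

    # --- shared state ---------------------------------------------------
    def grid(self) -> pd.DataFrame:
        if self._grid is None:
            path = self.out / "grid.parquet"
            if path.exists():
                self._grid = pd.read_parquet(path)
            else:
                self.simulate()
        return self._grid

    def pixel(self) -> pd.DataFrame:
        if self._pixel is None:
            path = self.out / "pixel.parquet"
            if path.exists():
                self._pixel = pd.read_parquet(path)
            else:
                self.simulate()
        return self._pixel

    def results(self):
        if self._results is None:
            model = GroundwaterYieldModel(
                self.grid(), surrogate_spec=self.spec, options=self.stages
            )
            self._results = model.fit(
                screen=True, n_boot=self.stages.n_boot, seed=self.seeds["fit"]
            )
        return self._results

    # --- stages ----------------------------------------------------------
    def simulate(self) -> None:
        sim = replace(self.sim, seed=self.seeds["simulate"])
        grid = simulate_world(sim, grain="grid")
        pixel = simulate_world(sim, grain="pixel")
        for name, df in (("grid", grid), ("pixel", pixel)):
            data, truth = split_truth(df)
            data.to_csv(self.out / f"{name}.csv", index=False)
            data.to_parquet(self.out / f"{name}.parquet", index=False)
            truth.to_csv(self.out / f"{name}_truth.csv", index=False)
        with open(self.out / "truth_params.json", "w") as fh:
            json.dump(
                {"gw_effect": grid.attrs["gw_effect"],
                 "capillary_gain": grid.attrs["capillary_gain"]},
                fh, indent=2, sort_keys=True,
            )
        self._grid, self._pixel = grid, pixel

    def evaluate(self) -> None:
        # agreement between grid-average yields and pixel-mean yields per
        # cell-year, overall and by weather class
        grid = self.grid()
        px = (
            self.pixel().groupby(["cell_id", "year"])["yield_t_ha"].mean().rename("pixel_mean")
        )
        merged = grid.merge(px, on=["cell_id", "year"])
        table = agreement(
            merged["pixel_mean"], merged["yield_t_ha"], weather_class=merged["weather_class"]
        )
        table.to_csv(self.out / "agreement.csv", index=False)

    def fit(self) -> None:
        res = self.results()
        manifest = {
            "hyperparameters": {
                "n_trees": res.surrogate.spec.n_trees,
                "m_try": res.surrogate.spec.m_try,
                "min_node": res.surrogate.spec.min_node,
            },
            "predictors": list(res.surrogate.predictors),
            "selected_periods": res.selected_periods,
            "seed": self.seeds["fit"],
            "oob_r2": res.oob_r2,
            "oob_mse": res.oob_mse,
        }
        with open(self.out / "model_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def ale(self) -> None:
        res = self.results()
        res.depth_curve.to_frame().to_csv(self.out / "ale_depth.csv", index=False)

    def zones(self) -> None:
        res = self.results()
        with open(self.out / "zones.json", "w") as fh:
            json.dump(res.zones.to_dict(), fh, indent=2, sort_keys=True)
        strata = res.stratified_effects(min_n=200)
        rows = []
        for name, (curve, rep) in strata.items():
            rows.append({"stratum": name, "n": curve.n, "max_subsidy": rep.max_subsidy,
                         "d_opt": rep.d_opt, "subsidy_low": rep.subsidy_low,
                         "subsidy_high": rep.subsidy_high,
                         "detected": rep.subsidy_detected})
            curve.to_frame().to_csv(self.out / f"ale_depth_{name}.csv", index=False)
        pd.DataFrame(rows).to_csv(self.out / "strata_zones.csv", index=False)

    def attenuate(self) -> None:
        results = run_attenuation_experiment(
            self.grid(), self.spec, self.stages,
            r_grid=self.stages.r_grid, seed=self.seeds["attenuate"],
        )
        rows = [r.to_dict() | {"grain": "grid"} for r in results]
        try:
            px = pixel_attenuation(self.pixel(), self.spec, self.stages)
            rows.append(px.to_dict() | {"grain": "pixel"})
        except RuntimeError as exc:
            logger.warning("pixel attenuation skipped: %s", exc)
        pd.DataFrame(rows).to_csv(self.out / "attenuation.csv", index=False)

    def mechanism(self) -> None:
        split = mechanism_split(self.grid(), self.spec, self.stages)
        boost = capillary_boost_summary(self.grid())
        with open(self.out / "mechanism.json", "w") as fh:
            json.dump({"split": split, "capillary_boost": boost}, fh,
                      indent=2, sort_keys=True)

    def stability(self) -> None:
        res = stability_analysis(self.pixel(), self.spec, self.stages)
        res.locations.to_csv(self.out / "stability_locations.csv", index=False)
        gaps = {
            "overall": res.cv_gap(),
            **{t: res.cv_gap(tercile=t) for t in res.curves_by_tercile},
        }
        with open(self.out / "stability.json", "w") as fh:
            json.dump(gaps, fh, indent=2, sort_keys=True)

    def prevalence(self) -> None:
        res = self.results()
        flagged = flag_conditions(self.grid(), zones=res.zones)
        t = tally(flagged)
        t.per_cell.to_csv(self.out / "prevalence_per_cell.csv")
        money = monetary_impact(flagged, effect_pcts=self.stages.effect_pcts)
        money.annual.to_csv(self.out / "monetary_annual.csv", index=False)
        with open(self.out / "prevalence.json", "w") as fh:
            json.dump(
                {"fractions": t.fractions,
                 "mean_subsidy_frequency": t.mean_subsidy_frequency,
                 "annual_extent": {int(k): float(v) for k, v in t.annual_extent.items()},
                 "thresholds": t.thresholds,
                 "monetary": money.to_dict()},
                fh, indent=2, sort_keys=True,
            )

    def report(self) -> None:
        os.environ.setdefault("MPLBACKEND", "Agg")
        res = self.results()
        lines = ["# Groundwater yield analysis report", "", "## Model fit", "",
                 "```", res.summary(), "```", ""]
        for name, title in [
            ("agreement.csv", "## Agreement by weather class"),
            ("attenuation.csv", "## Attenuation experiment"),
            ("strata_zones.csv", "## Deficit-stratified effects"),
        ]:
            p = self.out / name
            if p.exists():
                table = pd.read_csv(p).to_string(index=False)
                lines += [title, "", "```", table, "```", ""]
        for name, title in [
            ("mechanism.json", "## Mechanism split"),
            ("stability.json", "## Stability (CV gap, deep minus shallow)"),
            ("prevalence.json", "## Prevalence and monetary impact"),
        ]:
            p = self.out / name
            if p.exists():
                lines += [title, "", "```json", p.read_text().strip(), "```", ""]
        (self.out / "report.md").write_text("\n".join(lines))
        try:
            import matplotlib.pyplot as plt

            from .plotting import plot_zone

            ax = plot_zone(res.depth_curve, res.zones)
            ax.figure.savefig(self.out / "zones.png", dpi=120)
            plt.close(ax.figure)
        except Exception as exc:  # plotting must never fail the run
            logger.warning("figure generation skipped: %s", exc)

    def write_manifest(self) -> None:
        artifacts = {}
        for p in sorted(self.out.iterdir()):
            if p.name in ("manifest.json",) or p.suffix == ".png":
                continue
            artifacts[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest = {
            "package_version": __version__,
            "simulation": _jsonable(asdict(self.sim)),
            "surrogate": _jsonable(asdict(self.spec)),
            "stages": _jsonable(asdict(self.stages)),
            "master_seed": self.sim.seed,
            "stage_seeds": self.seeds,
            "defaults_log": {
                "k_bins": self.stages.k_bins,
                "n_boot": self.stages.n_boot,
                "slope_tol": self.stages.slope_tol,
                "min_plateau_width": self.stages.min_plateau_width,
                "class_boundaries_mm": [0.0, -50.0, -150.0],
                "boundary_convention": "0 and -50 -> normal; -150 -> dry; zone bounds closed",
            },
            "artifacts": artifacts,
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def run(self, stages: list[str] | None = None) -> Path:
        for name in stages or STAGES:
            try:
                getattr(self, name)()
            except Exception as exc:
                self.write_manifest()
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        self.write_manifest()
        return self.out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config_path: str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the full pipeline from a TOML config; returns the run directory."""
    run = PipelineRun.from_config_file(config_path, out_dir, seed=seed)
    return run.run()
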