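"""Bagged-tree yield surrogate and groundwater-period screening.

The surrogate is a random forest with the study hyperparameters (100
trees, six candidate variables per split, terminal nodes of at least 10
samples) evaluated on out-of-bag samples.  The ensemble itself comes from
scikit-learn; everything around it — the OOB contract, seeding,
screening — is defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import SurrogateSpec
from .synthetic_world import BASE_COVARIATES, DEPTH_CANDIDATES

logger = logging.getLogger(__name__)


@dataclass
class FittedSurrogate:
    """An opaque predict function plus out-of-bag diagnostics."""

    model: RandomForestRegressor
    predictors: list[str]
    target: str
    spec: SurrogateSpec
    oob_r2: float
    oob_mse: float

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.model.predict(data[self.predictors].to_numpy(dtype=float))

    def __call__(self, data: pd.DataFrame) -> np.ndarray:
        return self.predict(data)


def fit_surrogate(data: pd.DataFrame, spec: SurrogateSpec) -> FittedSurrogate:
    """Fit the bagged-tree surrogate; deterministic under a fixed seed.

    OOB R² follows the variance-explained convention
    ``1 - MSE_oob / var(y)``; OOB MSE is the mean squared out-of-bag
    residual.
    """
    predictors = list(spec.predictors) if spec.predictors else _default_predictors(data)
    missing = [c for c in predictors + [spec.target] if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    if len(data) < 2 * spec.min_node:
        raise ValueError(f"need at least {2 * spec.min_node} rows to fit")
    X = data[predictors].to_numpy(dtype=float)
    y = data[spec.target].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in predictors/target")

    # min_node follows the R randomForest "nodesize" semantics the field's
    # reference implementation uses: a node with <= min_node cases becomes
    # terminal (verified empirically: leaves can be far smaller than
    # nodesize), i.e. a split threshold rather than a leaf minimum.
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=min(spec.m_try, len(predictors)),
        min_samples_split=spec.min_node + 1,
        min_samples_leaf=1,
        oob_score=True,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    oob_pred = model.oob_prediction_
    oob_mse = float(np.mean((y - oob_pred) ** 2))
    oob_r2 = float(1.0 - oob_mse / np.var(y)) if np.var(y) > 0 else float("nan")
    return FittedSurrogate(model, predictors, spec.target, spec, oob_r2, oob_mse)


def _default_predictors(data: pd.DataFrame) -> list[str]:
    cols = [c for c in BASE_COVARIATES if c in data.columns]
    if "wt_depth_jul" in data.columns:
        cols.append("wt_depth_jul")
    return cols


def screen_groundwater_period(
    data: pd.DataFrame,
    candidates: list[str] | None = None,
    base_covariates: list[str] | None = None,
    spec: SurrogateSpec | None = None,
    val_frac: float = 0.3,
    min_improvement: float = 0.02,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection of the relevant groundwater period(s).

    Candidate monthly/annual depth columns are added one at a time to the
    base covariate set; a candidate is kept only if it lowers held-out MSE
    by more than ``min_improvement`` (relative; the default sits above the
    hold-out MSE noise floor at typical sizes, so chance selections in
    effect-free data are rare while a real groundwater period clears it
    easily).  The hold-out split is by cell so repeated years of one cell
    never straddle it.  Returns the selected columns in selection order
    (possibly empty).
    """
    candidates = list(candidates) if candidates is not None else list(DEPTH_CANDIDATES)
    base = list(base_covariates) if base_covariates is not None else [
        c for c in BASE_COVARIATES if c in data.columns
    ]
    spec = spec or SurrogateSpec()
    rng = np.random.default_rng(seed)
    cells = data["cell_id"].unique() if "cell_id" in data.columns else None
    if cells is not None and len(cells) > 3:
        val_cells = rng.choice(cells, size=max(1, int(len(cells) * val_frac)), replace=False)
        val_mask = data["cell_id"].isin(val_cells).to_numpy()
    else:
        val_mask = rng.random(len(data)) < val_frac
    train, val = data[~val_mask], data[val_mask]

    def _val_mse(cols: list[str]) -> float:
        fit = fit_surrogate(train, replace(spec, predictors=tuple(cols), seed=spec.seed))
        resid = val[spec.target].to_numpy(dtype=float) - fit.predict(val)
        return float(np.mean(resid**2))

    current = _val_mse(base)
    selected: list[str] = []
    remaining = [c for c in candidates if c in data.columns]
    while remaining:
        scores = {c: _val_mse(base + selected + [c]) for c in remaining}
        best = min(scores, key=scores.get)
        if scores[best] < current * (1.0 - min_improvement):
            selected.append(best)
            remaining.remove(best)
            current = scores[best]
            logger.info("screening selected %s (val MSE %.4f)", best, current)
        else:
            break
    return selected
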