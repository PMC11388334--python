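"""First-order accumulated local effects (ALE) with cluster-bootstrap bands.

ALE discretizes the data along one predictor into quantile bins, measures
the local prediction change across each bin with the *other* covariates
held at their observed values, accumulates those per-bin means by a
cumulative sum, and centers the curve at the mean model prediction.
Because the local differences are taken within bins — i.e. conditionally
on the observed covariate combinations — the estimate stays meaningful
under strongly correlated predictors, which is why it is used here instead
of partial dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ALECurve:
    """A centered first-order ALE curve over one predictor.

    ``effect`` holds K+1 values (t/ha for yield responses), one per bin
    edge, relative to the mean model prediction; ``counts`` the K per-bin
    sample counts.  The count-weighted mean of the bin-interpolated effect
    is zero by construction.
    """

    edges: np.ndarray
    effect: np.ndarray
    counts: np.ndarray
    feature_name: str
    center: float
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.edges.ndim != 1 or len(self.edges) != len(self.effect):
            raise ValueError("edges and effect must be 1-D and equally long")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def evaluate(self, x) -> np.ndarray:
        """Piecewise-linear interpolation of the effect at arbitrary x."""
        return np.interp(np.asarray(x, dtype=float), self.edges, self.effect)

    def shifted(self, delta: float) -> "ALECurve":
        return ALECurve(
            self.edges.copy(),
            self.effect + delta,
            self.counts.copy(),
            self.feature_name,
            self.center - delta,
            None if self.band_low is None else self.band_low + delta,
            None if self.band_high is None else self.band_high + delta,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "edge": self.edges,
                "effect": self.effect,
                "count": np.append(self.counts, 0),
            }
        )
        if self.band_low is not None:
            out["band_low"] = self.band_low
            out["band_high"] = self.band_high
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_name: str = "") -> "ALECurve":
        band_low = df["band_low"].to_numpy() if "band_low" in df else None
        band_high = df["band_high"].to_numpy() if "band_high" in df else None
        return cls(
            df["edge"].to_numpy(),
            df["effect"].to_numpy(),
            df["count"].to_numpy()[:-1],
            feature_name,
            center=float("nan"),
            band_low=band_low,
            band_high=band_high,
        )


def _quantile_edges(x: np.ndarray, k_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0.0, 1.0, k_bins + 1))
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        logger.warning(
            "%d duplicate quantile edges merged (heavy ties)", len(edges) - len(uniq)
        )
    if len(uniq) < 2:
        raise ValueError("feature is constant; ALE undefined")
    return uniq


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # bin j covers (edges[j], edges[j+1]]; bin 0 additionally includes edges[0]
    return np.clip(np.searchsorted(edges, x, side="left") - 1, 0, len(edges) - 2)


def compute_ale(
    predict: Callable[[pd.DataFrame], np.ndarray],
    data: pd.DataFrame,
    feature: str,
    k_bins: int = 40,
) -> ALECurve:
    """First-order ALE of a black-box model along one numeric feature.

    Bins are sample quantiles of the feature (duplicates merged, empty
    bins pooled into their deeper neighbour).  For every observation in
    bin j the local effect is ``predict(x with feature := upper edge) -
    predict(x with feature := lower edge)``; per-bin means are accumulated
    by cumulative sum and the curve is centered by subtracting the
    count-weighted average of bin-midpoint effects.
    """
    if feature not in data.columns:
        raise KeyError(f"feature {feature!r} not in data")
    if k_bins < 2:
        raise ValueError("k_bins must be at least 2")
    if len(data) < k_bins:
        raise ValueError("need at least k_bins rows")
    x = data[feature].to_numpy(dtype=float)
    edges = _quantile_edges(x, k_bins)

    # merge empty bins (can only arise with pathological edge sets)
    while True:
        idx = _bin_index(x, edges)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        if np.all(counts > 0) or len(edges) <= 2:
            break
        j = int(np.argmin(counts))
        drop = j + 1 if j + 1 < len(edges) - 1 else j
        logger.warning("merging empty ALE bin %d", j)
        edges = np.delete(edges, drop)

    k = len(edges) - 1
    lo = data.copy()
    hi = data.copy()
    lo[feature] = edges[idx]
    hi[feature] = edges[idx + 1]
    local = np.asarray(predict(hi), dtype=float) - np.asarray(predict(lo), dtype=float)
    sums = np.bincount(idx, weights=local, minlength=k)
    mean_local = sums / counts

    g = np.concatenate([[0.0], np.cumsum(mean_local)])
    center = float(np.sum(counts * (g[:-1] + g[1:]) / 2.0) / counts.sum())
    return ALECurve(edges, g - center, counts, feature, center)


def bootstrap_ale(
    predict_factory: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    data: pd.DataFrame,
    feature: str,
    k_bins: int = 40,
    n_boot: int = 500,
    seed: int = 0,
    cluster_col: str = "cell_id",
    alpha: float = 0.05,
) -> ALECurve:
    """ALE curve with a percentile bootstrap envelope.

    ``predict_factory`` refits the surrogate on a resampled table and
    returns its predict function.  The resampling unit is the cluster
    (grid cell), not the row, so within-cell dependence is respected.
    Resamples whose refit fails are dropped with a warning; more than 10%
    drops is an error.  The envelope is evaluated on the point curve's
    edges by linear interpolation.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    point = compute_ale(predict_factory(data), data, feature, k_bins)
    rng = np.random.default_rng(seed)
    if cluster_col is not None and cluster_col in data.columns:
        groups = {c: g for c, g in data.groupby(cluster_col)}
        clusters = np.array(sorted(groups))
    else:
        groups = None
        clusters = np.arange(len(data))

    curves = []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.choice(clusters, size=len(clusters), replace=True)
        if groups is not None:
            sample = pd.concat([groups[c] for c in pick], ignore_index=True)
        else:
            sample = data.iloc[pick].reset_index(drop=True)
        try:
            cur = compute_ale(predict_factory(sample), sample, feature, k_bins)
        except Exception as exc:  # refit failure on a degenerate resample
            dropped += 1
            logger.warning("bootstrap resample dropped: %s", exc)
            continue
        curves.append(np.interp(point.edges, cur.edges, cur.effect))
    if dropped > 0.1 * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap resamples failed")

    mat = np.vstack(curves)
    # anchor the envelope to the point estimate so it always contains it
    point.band_low = np.minimum(np.percentile(mat, 100 * alpha / 2, axis=0), point.effect)
    point.band_high = np.maximum(
        np.percentile(mat, 100 * (1 - alpha / 2), axis=0), point.effect
    )
    return point
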