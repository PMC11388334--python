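"""Plot helpers: ALE curves with rug ticks, shaded zones, experiment overlays."""

from __future__ import annotations

import numpy as np

from .ale import ALECurve
from .zones import ZoneReport


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_ale(curve: ALECurve, ax=None, color="k", label=None, rug=True):
    ax = _ax(ax)
    ax.plot(curve.edges, curve.effect, color=color, label=label)
    if curve.band_low is not None:
        ax.fill_between(curve.edges, curve.band_low, curve.band_high,
                        color=color, alpha=0.2, linewidth=0)
    if rug:
        # one tick per bin, opacity scaled by the bin count
        mids = (curve.edges[:-1] + curve.edges[1:]) / 2
        y0 = float(np.min(curve.effect))
        w = curve.counts / curve.counts.max()
        for m, wi in zip(mids, w):
            ax.plot([m], [y0], "|", color="gray", alpha=0.15 + 0.6 * wi, markersize=5)
    ax.axhline(0.0, color="gray", linestyle=":", linewidth=0.8)
    ax.set_xlabel(curve.feature_name)
    ax.set_ylabel("effect (relative to mean prediction)")
    return ax


def plot_zone(curve: ALECurve, report: ZoneReport, ax=None):
    ax = plot_ale(curve, ax=ax, rug=False)
    if np.isfinite(report.baseline_effect):
        ax.axhline(report.baseline_effect, color="red", linestyle="--",
                   linewidth=1, label="free-drainage baseline")
    if report.subsidy_detected:
        ax.axvspan(report.subsidy_low, report.subsidy_high, color="tab:blue",
                   alpha=0.15, label="subsidy zone")
        ax.axvline(report.d_opt, color="tab:blue", linestyle=":", linewidth=0.8)
    ax.legend(fontsize=8)
    return ax


def plot_overlay(curves: dict[str, ALECurve], ax=None):
    """Overlay several ALE curves (e.g. clean vs. noisy, or weather strata)."""
    ax = _ax(ax)
    colors = ["k", "gray", "tab:orange", "tab:blue", "tab:green", "tab:red"]
    for (name, curve), color in zip(curves.items(), colors):
        plot_ale(curve, ax=ax, color=color, label=name, rug=False)
    ax.legend(fontsize=8)
    return ax
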