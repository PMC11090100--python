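"""Cosmetic renderers: fingerprint radar plots and per-center forest plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .fingerprints import CenterEffect, FingerprintResult

__all__ = ["fingerprint_radar", "forest_plot"]


def fingerprint_radar(result: FingerprintResult, attr: str = "t",
                      ax=None):
    """Radar (spider) plot of one-or-more seeds' fingerprints over the ROIs."""
    mat = result.matrix(attr)
    n = mat.shape[1]
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"},
                             figsize=(6, 6))
    for seed in mat.index:
        vals = mat.loc[seed].to_numpy()
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]],
                label=seed, linewidth=1.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(mat.columns, fontsize=7)
    ax.set_title(f"covariance fingerprint ({attr})")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    return ax


def forest_plot(effects: Sequence[CenterEffect], pooled_g: float | None = None,
                ax=None):
    """Forest plot of per-center Hedges g* with 95% confidence intervals."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * len(effects) + 1.5))
    ys = np.arange(len(effects))[::-1]
    for y, eff in zip(ys, effects):
        lo, hi = eff.g - 1.96 * eff.se, eff.g + 1.96 * eff.se
        ax.plot([lo, hi], [y, y], color="0.3")
        ax.plot(eff.g, y, "s", color="C0",
                markersize=4 + 6 * (eff.n_scz + eff.n_hc) ** 0.25 / 4)
    ax.set_yticks(ys)
    ax.set_yticklabels([str(e.center) for e in effects], fontsize=8)
    ax.axvline(0.0, color="0.7", linestyle="--", linewidth=0.8)
    if pooled_g is not None:
        ax.axvline(pooled_g, color="C3", linewidth=0.8)
    ax.set_xlabel("Hedges g*")
    return ax
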