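"""Small matplotlib helpers for the standard figures of a phenotyping study:
scaled group-mean profiles, per-phenotype survival curves and the
intervention-risk heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_phenotype_profiles(scaled_means: pd.DataFrame, ax=None):
    """Bar panel of per-feature group means scaled to [-1, 1]."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    scaled_means.T.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel("group mean (scaled to [-1, 1])")
    ax.set_ylim(-1.1, 1.1)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.legend(title="phenotype", fontsize=8)
    return ax


def plot_survival(contrast, ax=None):
    """Step plot of the per-phenotype Kaplan-Meier curves at one horizon."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in contrast.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(label))
    ax.set_xlabel("days")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {contrast.logrank_p:.2g}")
    return ax


def plot_risk_grid(grid: pd.DataFrame, ax=None):
    """Heatmap of horizon mortality risk by (lower, upper) fluid range."""
    finite = grid[np.isfinite(grid["lower"]) & np.isfinite(grid["upper"])]
    pivot = finite.pivot(index="lower", columns="upper", values="risk")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns], rotation=45)
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("upper bound (mL/day)")
    ax.set_ylabel("lower bound (mL/day)")
    plt.colorbar(im, ax=ax, label="risk of in-hospital death")
    return ax
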