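"""Quick-look plots for niche annotations and density trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .grid import SpotGrid
from .trajectories import TrajectorySet

__all__ = ["plot_niche", "plot_trajectory_clusters"]

_NICHE_COLORS = {
    "rich": "#b2182b",
    "neighbor": "#ef8a62",
    "outside": "#d9d9d9",
    "excluded": "#2166ac",
}


def plot_niche(grid: SpotGrid, annotation: pd.DataFrame, ax=None):
    """Scatter the spot grid coloured by niche class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ann = annotation.set_index("spot_id") if "spot_id" in annotation.columns else annotation
    merged = grid.spots.join(ann["niche_class"], on="spot_id")
    for cls, color in _NICHE_COLORS.items():
        sub = merged[merged["niche_class"] == cls]
        ax.scatter(sub["x"], sub["y"], s=8, c=color, label=cls, linewidths=0)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.legend(markerscale=2, fontsize=8)
    return ax


def plot_trajectory_clusters(traj: TrajectorySet, ax=None):
    """Per-cluster mean trajectories (bold) over individual gene curves."""
    if traj.cluster is None:
        raise ValueError("cluster the trajectories first")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("tab10")
    for i, (cl, mean_row) in enumerate(traj.cluster_means().iterrows()):
        color = cmap(i % 10)
        members = traj.predictions[traj.cluster == cl]
        for row in members:
            ax.plot(traj.grid, row, color=color, alpha=0.15, lw=0.6)
        ax.plot(traj.grid, mean_row, color=color, lw=2.2, label=f"cluster {cl}")
    ax.set_xlabel("Aβ density (0-255)")
    ax.set_ylabel("standardized expression")
    ax.legend(fontsize=8)
    return ax
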