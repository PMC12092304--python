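"""LOESS trajectories of gene expression along amyloid density.

Each gene's normalized expression is regressed on spot-level amyloid
intensity with a local linear (degree 1) tricube-weighted fit over the
span-fraction nearest neighbours — the classic LOESS smoother with span
0.75 and no robustness iterations. Predictions on an even density grid
are z-standardized per gene and hierarchically clustered (complete
linkage on Euclidean distances) to expose shared nonlinear response
shapes, e.g. programs peaking in amyloid-rich spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["TrajectorySet", "loess_predict", "fit_density_trajectories", "cluster_trajectories"]


@dataclass
class TrajectorySet:
    """Standardized LOESS predictions on a shared density grid."""

    genes: list
    grid: np.ndarray
    predictions: np.ndarray  # genes x grid, z-scored per gene (or all-zero)
    cluster: np.ndarray | None = None
    group: str = ""
    linkage: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.predictions, index=self.genes, columns=self.grid)
        if self.cluster is not None:
            df.insert(0, "cluster", self.cluster)
        return df

    def cluster_means(self) -> pd.DataFrame:
        if self.cluster is None:
            raise ValueError("trajectories are not clustered yet")
        df = pd.DataFrame(self.predictions, index=self.cluster, columns=self.grid)
        return df.groupby(level=0).mean()


def loess_predict(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
) -> np.ndarray:
    """Local linear regression with tricube weights (LOESS, degree 1).

    For each evaluation point the span-fraction nearest neighbours in x
    receive tricube weights on their scaled distance and a weighted line is
    fitted; the prediction is the line's value at the point. Exactly linear
    data are reproduced to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(int(np.ceil(span * n)), 2)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for j, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[j] = ys[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xw = xs[idx]
        sw = w.sum()
        xbar = (w * xw).sum() / sw
        ybar = (w * ys[idx]).sum() / sw
        sxx = (w * (xw - xbar) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xbar**2):
            out[j] = ybar
        else:
            slope = (w * (xw - xbar) * (ys[idx] - ybar)).sum() / sxx
            out[j] = ybar + slope * (x0 - xbar)
    return out


def fit_density_trajectories(
    expr: pd.DataFrame,
    density: pd.Series,
    span: float = 0.75,
    grid_size: int = 100,
    group: str = "",
) -> TrajectorySet:
    """Fit per-gene LOESS trajectories of expression against amyloid density.

    ``expr`` is genes x spots (normalized expression); ``density`` holds the
    per-spot amyloid intensity (0-255). Spots with non-finite density are
    dropped. Predictions are evaluated on ``grid_size`` evenly spaced
    density values spanning the observed range, then z-standardized per
    gene across the grid; genes with (near-)zero prediction variance map to
    the all-zero row.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    density = density.reindex(expr.columns)
    ok = np.isfinite(density.to_numpy(dtype=float))
    n_ok = int(ok.sum())
    n_min = max(10, int(np.ceil(span * 4)))
    if n_ok < n_min:
        raise ValueError(f"need at least {n_min} spots with finite density, got {n_ok}")
    x = density.to_numpy(dtype=float)[ok]
    E = expr.to_numpy(dtype=float)[:, ok]
    grid = np.linspace(x.min(), x.max(), grid_size)
    preds = np.empty((len(expr), grid_size))
    for i, y in enumerate(E):
        preds[i] = loess_predict(x, y, grid, span=span)
    sd = preds.std(axis=1)
    mean = preds.mean(axis=1)
    z = np.zeros_like(preds)
    nz = sd > 1e-12
    z[nz] = (preds[nz] - mean[nz, None]) / sd[nz, None]
    return TrajectorySet(genes=list(expr.index), grid=grid, predictions=z, group=group)


def cluster_trajectories(
    traj: TrajectorySet, k: int | None = None, cut_height: float | None = None
) -> TrajectorySet:
    """Hierarchically cluster standardized trajectories (complete linkage).

    Cuts the dendrogram at ``k`` clusters or at ``cut_height``; labels are
    renumbered 1..K in order of descending cluster size.
    """
    n = len(traj.genes)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if (k is None) == (cut_height is None):
        raise ValueError("give exactly one of k or cut_height")
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    d = pdist(traj.predictions, metric="euclidean")
    Z = hierarchy.linkage(d, method="complete")
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = np.array([remap[v] for v in labels])
    return TrajectorySet(
        genes=traj.genes,
        grid=traj.grid,
        predictions=traj.predictions,
        cluster=labels,
        group=traj.group,
        linkage=Z,
    )
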