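"""Cell-type clusters, cell-states, and cell-density landscapes.

Cell types are inferred by t-SNE on highly variable genes followed by
density-based clustering (DBSCAN); cells not assigned to any cluster
are "peripheral" (reserved label 0).  Crossing cluster labels with
potency states yields the cell-state contingency table, where a
(potency state, cluster) pair qualifies as a cell-state when it holds
at least ``min_cells`` cells.  Per-potency-state kernel-density
surfaces over a shared embedding extent make the densities of
different states directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

PERIPHERAL = 0  # reserved cluster label for unclustered (noise) cells

__all__ = [
    "PERIPHERAL",
    "Embedding",
    "CellStateTable",
    "DensityGrid",
    "embed_cells",
    "cluster_embedding",
    "cell_state_table",
    "density_surface",
]


@dataclass
class Embedding:
    """2-D embedding with the parameters that produced it."""

    coords: np.ndarray           # n_cells x 2
    params: dict = field(default_factory=dict)


def embed_cells(
    expr_hvg,
    initial_dims: int = 30,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> Embedding:
    """t-SNE embedding of cells (PCA to ``initial_dims`` first).

    ``expr_hvg`` is a genes x cells matrix (DataFrame or container with
    ``values``); cells become rows internally.  Deterministic given the
    seed.  Requires at least ``3 * perplexity`` cells.
    """
    X = _cells_by_features(expr_hvg)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"need at least {int(np.ceil(3 * perplexity))} cells for "
            f"perplexity {perplexity}, got {n}"
        )
    ndim = int(min(initial_dims, X.shape[1], n))
    if X.shape[1] > ndim:
        X = PCA(n_components=ndim, random_state=seed).fit_transform(X)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    return Embedding(
        coords=np.asarray(coords, float),
        params={
            "method": "tsne",
            "initial_dims": initial_dims,
            "perplexity": perplexity,
            "max_iter": max_iter,
            "seed": seed,
        },
    )


def _cells_by_features(expr) -> np.ndarray:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(float).T
    if hasattr(expr, "values") and hasattr(expr, "gene_ids"):
        return np.asarray(expr.values, float).T
    return np.asarray(expr, float)


def cluster_embedding(
    coords: np.ndarray, eps: float = 5.0, min_pts: int = 15
) -> np.ndarray:
    """Density-based clustering of embedding coordinates.

    Returns integer labels: clusters are numbered 1, 2, ... by
    descending size (ties broken by cluster centroid, which is
    invariant to input order) and noise points receive the peripheral
    label 0.  Note ``eps`` is in embedding units, so its meaning
    depends on the embedding's scale.
    """
    coords = np.asarray(coords, float)
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    labels = np.zeros(len(raw), dtype=int)
    clusters = [c for c in np.unique(raw) if c != -1]

    def sort_key(c):
        mask = raw == c
        cx, cy = coords[mask].mean(axis=0)
        return (-int(mask.sum()), cx, cy)

    for new, c in enumerate(sorted(clusters, key=sort_key), start=1):
        labels[raw == c] = new
    return labels


@dataclass
class CellStateTable:
    """Contingency table of potency states x clusters.

    ``counts`` rows are potency states, columns are cluster labels
    (peripheral column included); ``qualifies`` marks pairs holding at
    least ``min_cells`` cells.  Peripheral cells are tabulated but
    never qualify as cell-states.
    """

    counts: pd.DataFrame
    qualifies: pd.DataFrame
    min_cells: int

    @property
    def cell_states(self) -> list[tuple[int, int]]:
        """(potency state, cluster) pairs that qualify as cell-states."""
        out = []
        for s in self.qualifies.index:
            for c in self.qualifies.columns:
                if self.qualifies.loc[s, c]:
                    out.append((s, c))
        return out


def cell_state_table(
    cluster_labels, potency_labels, min_cells: int = 5
) -> CellStateTable:
    """Cross-tabulate cluster and potency-state labels into cell-states."""
    cluster_labels = np.asarray(cluster_labels)
    potency_labels = np.asarray(potency_labels)
    if len(cluster_labels) != len(potency_labels):
        raise ValueError("cluster and potency label vectors differ in length")
    states = np.unique(potency_labels)
    clusters = np.unique(cluster_labels)
    counts = pd.DataFrame(0, index=states, columns=clusters)
    for s, c in zip(potency_labels, cluster_labels):
        counts.loc[s, c] += 1
    qualifies = counts >= min_cells
    if PERIPHERAL in qualifies.columns:
        qualifies[PERIPHERAL] = False
    counts.index.name = "potency_state"
    counts.columns.name = "cluster"
    return CellStateTable(counts=counts, qualifies=qualifies, min_cells=min_cells)


@dataclass
class DensityGrid:
    """2-D kernel density estimate on a regular grid.

    ``grid[i, j]`` is the density at ``(x[i], y[j])``; the grid is
    normalized so that its Riemann sum over the extent equals 1.
    """

    grid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bandwidth: tuple[float, float]
    n_cells: int

    @property
    def peak(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.grid), self.grid.shape)
        return float(self.x[i]), float(self.y[j])

    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.grid.sum() * dx * dy)


def density_surface(
    coords: np.ndarray,
    mask=None,
    grid_size: int = 100,
    bandwidth: str | tuple[float, float] = "scott",
    extent=None,
) -> DensityGrid:
    """Gaussian kernel density surface for a subset of cells.

    The grid always covers the bounding box of *all* cells (or an
    explicit ``extent`` of ``(xmin, xmax, ymin, ymax)``), so surfaces
    computed for different subsets share an extent and are directly
    comparable.  Bandwidths follow Scott's rule per axis on the subset
    (``sigma * n**(-1/6)``); a degenerate axis (zero spread) falls back
    to 1% of the extent range.  The product-kernel estimate is
    renormalized to integrate to 1 over the extent.
    """
    coords = np.asarray(coords, float)
    if mask is None:
        mask = np.ones(len(coords), dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype != bool:
        idx = np.zeros(len(coords), dtype=bool)
        idx[np.asarray(mask, int)] = True
        mask = idx
    pts = coords[mask]
    if len(pts) < 2:
        raise ValueError("need at least 2 cells in the subset for a density surface")

    if extent is None:
        xmin, xmax = coords[:, 0].min(), coords[:, 0].max()
        ymin, ymax = coords[:, 1].min(), coords[:, 1].max()
    else:
        xmin, xmax, ymin, ymax = extent
    # guard against a flat extent
    if xmax <= xmin:
        xmin, xmax = xmin - 0.5, xmax + 0.5
    if ymax <= ymin:
        ymin, ymax = ymin - 0.5, ymax + 0.5

    n = len(pts)
    if bandwidth == "scott":
        factor = n ** (-1.0 / 6.0)
        hx = pts[:, 0].std(ddof=1) * factor
        hy = pts[:, 1].std(ddof=1) * factor
    else:
        hx, hy = bandwidth
    if not hx > 0:
        hx = 0.01 * (xmax - xmin)
    if not hy > 0:
        hy = 0.01 * (ymax - ymin)

    gx = np.linspace(xmin, xmax, grid_size)
    gy = np.linspace(ymin, ymax, grid_size)
    # product Gaussian kernel, evaluated as two (grid x points) matrices
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    grid = kx @ ky.T / n
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    total = grid.sum() * dx * dy
    if total <= 0:
        raise ValueError("density surface is identically zero on the extent")
    grid = grid / total
    return DensityGrid(grid=grid, x=gx, y=gy, bandwidth=(float(hx), float(hy)), n_cells=n)


def plot_density_surface(grid: DensityGrid, path, title: str = "") -> None:
    """Render a density grid as a 3-D surface PNG (elevation = density)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    gx, gy = np.meshgrid(grid.x, grid.y, indexing="ij")
    ax.plot_surface(gx, gy, grid.grid, cmap="magma", linewidth=0, antialiased=True)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_zlabel("cell density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
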