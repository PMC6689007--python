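"""Root selection, diffusion maps, and diffusion pseudotime.

The highest-potency cell (maximal normalized entropy rate) serves as
an unbiased root for lineage inference.  A diffusion map is built from
a symmetric k-nearest-neighbour graph with a locally adaptive Gaussian
kernel and density normalization (alpha = 1), and diffusion pseudotime
(DPT) is the spectral distance

    dpt(i, j)^2 = sum_l ( lambda_l / (1 - lambda_l) )^2
                  ( psi_l(i) - psi_l(j) )^2

over the retained nontrivial eigenpairs of the diffusion operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DiffusionResult",
    "TipResult",
    "select_root",
    "diffusion_map",
    "diffusion_pseudotime",
    "find_tips",
]

_DENSE_MAX = 2000  # dense eigensolver below this many cells


@dataclass
class DiffusionResult:
    """Diffusion components of a cell population.

    ``eigenvalues`` are the nontrivial operator eigenvalues in
    descending order (all < 1); ``components`` the matching diffusion
    components (cells x n_dcs), scaled so the excluded trivial
    component is constant 1.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    k: int
    bandwidths: np.ndarray
    root_index: int | None = None
    dpt: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.components.shape[0]


def select_root(sr) -> int:
    """Index of the highest-potency cell (argmax SR, first on ties)."""
    if hasattr(sr, "srn"):
        sr = sr.srn
    sr = np.asarray(sr, dtype=float)
    if sr.size == 0:
        raise ValueError("empty SR vector")
    return int(np.argmax(sr))


def _as_cells_by_features(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(float).T
    if hasattr(data, "values") and hasattr(data, "gene_ids"):
        return np.asarray(data.values, float).T
    return np.asarray(data, float)


def diffusion_map(
    data,
    k: int = 30,
    n_dcs: int = 10,
    kernel: str = "knn",
    sigma: float | None = None,
) -> DiffusionResult:
    """Diffusion map of a cell population.

    Parameters
    ----------
    data
        Genes x cells expression (DataFrame/container) or an explicit
        cells x features array (e.g. embedding coordinates).
    k
        Neighbourhood size for the symmetric kNN graph; the per-cell
        kernel bandwidth is the median distance to the cell's k nearest
        neighbours.
    n_dcs
        Number of nontrivial diffusion components to retain.

    With ``kernel="knn"`` (default) the kernel is
    ``K_ij = exp(-d_ij^2 / (2 s_i s_j))`` on the symmetrized kNN graph
    with adaptive per-cell bandwidths ``s_i``.  With ``kernel="dense"``
    a fixed-bandwidth Gaussian kernel over all pairs is used (``sigma``
    defaults to the median adaptive bandwidth); the dense variant's
    density normalization makes its spectrum exactly invariant to
    duplication of cells (sampling-measure invariance), which the
    kNN-truncated kernel only satisfies approximately.  In both cases
    the kernel is density-normalized by its row sums (alpha = 1) and
    the row-stochastic operator is eigendecomposed through its
    symmetric conjugate.  The trivial constant component
    (eigenvalue 1) is dropped.
    """
    X = _as_cells_by_features(data)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    n_dcs = int(min(n_dcs, n - 2))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    bw = np.median(dist, axis=1)
    # duplicated points can give zero bandwidth; fall back to the
    # smallest positive scale in the dataset
    positive = bw[bw > 0]
    fallback = positive.min() if positive.size else 1.0
    bw = np.where(bw > 0, bw, fallback)

    if kernel == "dense":
        s = float(sigma) if sigma is not None else float(np.median(bw))
        from scipy.spatial.distance import cdist

        D2 = cdist(X, X, "sqeuclidean")
        K = sp.csr_matrix(np.exp(-D2 / (2.0 * s * s)))
    elif kernel == "knn":
        rows = np.repeat(np.arange(n), k)
        cols = idx.ravel()
        d2 = (dist.ravel()) ** 2
        W = sp.coo_matrix((d2, (rows, cols)), shape=(n, n)).tocsr()
        # symmetrize the kNN graph (union of neighbourhoods)
        W = W.maximum(W.T)
        W = W.tocoo()
        kvals = np.exp(-W.data / (2.0 * bw[W.row] * bw[W.col]))
        K = sp.coo_matrix((kvals, (W.row, W.col)), shape=(n, n)).tocsr()
        # distances of zero (duplicates) vanish from the sparse pattern;
        # restore them with kernel value 1
        zero_pairs = _duplicate_pairs(dist, idx)
        if zero_pairs:
            zi, zj = zip(*zero_pairs)
            Z = sp.coo_matrix((np.ones(len(zi)), (zi, zj)), shape=(n, n)).tocsr()
            Z = Z.maximum(Z.T)
            K = K.maximum(Z)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    # alpha = 1 density normalization removes sampling-density effects
    q = np.asarray(K.sum(axis=1)).ravel()
    Dq = sp.diags(1.0 / q)
    K1 = (Dq @ K @ Dq).tocsr()

    d = np.asarray(K1.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(d)
    S = (sp.diags(d_isqrt) @ K1 @ sp.diags(d_isqrt)).tocsr()

    if n <= _DENSE_MAX:
        w, V = np.linalg.eigh(S.toarray())
        w, V = w[::-1], V[:, ::-1]
    else:
        v0 = np.ones(n) / np.sqrt(n)
        w, V = spla.eigsh(S, k=n_dcs + 1, which="LA", v0=v0)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]

    w = w[: n_dcs + 1]
    V = V[:, : n_dcs + 1]
    # psi_l = phi_l / phi_0 makes the trivial component exactly constant 1
    phi0 = V[:, 0]
    if phi0.sum() < 0:
        phi0 = -phi0
        V = V.copy()
        V[:, 0] = phi0
    psi = V / phi0[:, None]
    # deterministic sign: largest-magnitude entry of each component positive
    for l in range(1, psi.shape[1]):
        j = np.argmax(np.abs(psi[:, l]))
        if psi[j, l] < 0:
            psi[:, l] = -psi[:, l]

    eigenvalues = np.clip(w[1:], None, 1.0 - 1e-12)
    return DiffusionResult(
        eigenvalues=eigenvalues,
        components=psi[:, 1:],
        k=k,
        bandwidths=bw,
    )


def _duplicate_pairs(dist: np.ndarray, idx: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    zi, zj = np.nonzero(dist == 0)
    for i, jcol in zip(zi, zj):
        pairs.append((int(i), int(idx[i, jcol])))
    return pairs


def diffusion_pseudotime(dmap: DiffusionResult, root: int) -> np.ndarray:
    """Diffusion pseudotime of every cell relative to a root cell.

    dpt(i) is the DPT distance between cell i and the root in the
    truncated eigenspace; dpt(root) = 0 and the underlying pairwise
    form is a symmetric metric.
    """
    n = dmap.n_cells
    if not 0 <= root < n:
        raise ValueError(f"root index {root} out of range for {n} cells")
    lam = dmap.eigenvalues
    scale = lam / (1.0 - lam)
    diff = dmap.components - dmap.components[root][None, :]
    dpt = np.sqrt(np.sum((scale[None, :] * diff) ** 2, axis=1))
    dpt[root] = 0.0
    return dpt


@dataclass
class TipResult:
    """Terminal cells of the pseudotime ordering."""

    global_tip: int
    cluster_tips: dict = field(default_factory=dict)


def find_tips(dpt, cluster_labels=None) -> TipResult:
    """Global and per-cluster pseudotime maxima (ties to smallest index).

    Cluster label 0 (peripheral) is skipped for per-cluster tips.
    """
    dpt = np.asarray(dpt, float)
    global_tip = int(np.argmax(dpt))
    tips = {}
    if cluster_labels is not None:
        cluster_labels = np.asarray(cluster_labels)
        for c in np.unique(cluster_labels):
            if c == 0:
                continue
            members = np.flatnonzero(cluster_labels == c)
            tips[int(c)] = int(members[np.argmax(dpt[members])])
    return TipResult(global_tip=global_tip, cluster_tips=tips)
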