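"""Signaling entropy rate of expression-weighted random walks.

A cell's normalized expression profile ``x`` (strictly positive, aligned
to the network's genes) weights the edges of the interaction network,
``w_ij ~ x_i x_j``.  Row-normalizing the weights yields the stochastic
matrix

    P_ij = x_j / (Ax)_i        for j a neighbour of i,

whose entropy rate under its stationary distribution,

    Sr = - sum_i pi_i sum_j P_ij ln P_ij,
    pi_i = x_i (Ax)_i / (x^T A x),

measures how promiscuously signaling flux spreads over the network.
The topological maximum ``maxSr = ln(lambda)`` — attained by the
maximal-entropy random walk built from the dominant eigenpair
``A v = lambda v`` — normalizes Sr to ``SR = Sr / maxSr`` in (0, 1],
a per-cell differentiation-potency estimate.

Natural logarithms are used for Sr and maxSr throughout (SR itself is
base-invariant); the logit transform of SR uses base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import GeneNetwork, intersect_with_genes

__all__ = [
    "SRProfile",
    "dominant_eigenpair",
    "max_entropy_rate",
    "transition_matrix",
    "stationary_distribution",
    "entropy_rate",
    "normalized_sr",
    "sr_profile",
]

_DENSE_EIG_MAX = 500  # below this, use a dense solver (exact, deterministic)


@dataclass
class SRProfile:
    """Per-cell entropy-rate summary.

    Attributes
    ----------
    cell_ids : array of cell identifiers
    sr : per-cell entropy rate Sr (nats)
    max_sr : topological maximum entropy rate (nats), one scalar
    srn : normalized entropy rate SR = Sr / maxSr, in (0, 1]
    logit_sr : log2(SR / (1 - SR)); +inf where SR == 1
    n_genes_used : number of network genes the profile was computed over
    """

    cell_ids: np.ndarray
    sr: np.ndarray
    max_sr: float
    srn: np.ndarray
    logit_sr: np.ndarray
    n_genes_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "Sr": self.sr,
                "maxSr": self.max_sr,
                "SR": self.srn,
                "logitSR": self.logit_sr,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SRProfile":
        return cls(
            cell_ids=df["cell_id"].to_numpy(),
            sr=df["Sr"].to_numpy(float),
            max_sr=float(df["maxSr"].iloc[0]),
            srn=df["SR"].to_numpy(float),
            logit_sr=df["logitSR"].to_numpy(float),
        )


def _require_connected(net: GeneNetwork) -> None:
    if net.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")
    if not net.is_connected():
        raise ValueError(
            "network is disconnected; extract the largest connected "
            "component first (largest_connected_component)"
        )


def dominant_eigenpair(net: GeneNetwork) -> tuple[float, np.ndarray]:
    """Dominant (Perron) eigenpair of the adjacency matrix.

    Returns ``(lambda, v)`` with ``A v = lambda v``, ``lambda`` the
    largest eigenvalue, ``v`` entrywise positive and unit 2-norm.
    Small networks use a dense symmetric eigensolver; larger ones a
    sparse Lanczos solver seeded with the all-ones vector so results
    are run-to-run identical.
    """
    _require_connected(net)
    A = net.adjacency
    n = net.n_nodes
    if n <= _DENSE_EIG_MAX:
        w, V = np.linalg.eigh(A.toarray())
        lam = float(w[-1])
        v = V[:, -1]
    else:
        v0 = np.ones(n) / np.sqrt(n)
        w, V = spla.eigsh(A, k=1, which="LA", v0=v0, tol=1e-12)
        lam = float(w[0])
        v = V[:, 0]
    if v.sum() < 0:
        v = -v
    if np.any(v <= 0):
        # Perron vector of a connected graph is strictly positive; tiny
        # negative round-off can appear in the Lanczos path
        if np.min(v) < -1e-8 * np.max(v):
            raise ValueError("dominant eigenvector not positive; is the network connected?")
        v = np.clip(v, np.finfo(float).tiny, None)
    v = v / np.linalg.norm(v)
    resid = np.max(np.abs(A @ v - lam * v))
    if resid > 1e-10 * lam:
        raise RuntimeError(f"eigenpair residual {resid:.2e} exceeds tolerance")
    return lam, v


def max_entropy_rate(net: GeneNetwork) -> tuple[float, sp.csr_matrix]:
    """Maximum entropy rate compatible with the network topology.

    The maximal-entropy random walk has transition matrix
    ``P_ij = A_ij v_j / (lambda v_i)`` (the dominant eigenpair is the
    unique row-normalizing choice) and entropy rate ``ln(lambda)``
    under its stationary measure ``pi_i = v_i**2``.

    Returns ``(max_sr, P_max)``.
    """
    lam, v = dominant_eigenpair(net)
    D_inv = sp.diags(1.0 / (lam * v))
    P = (D_inv @ net.adjacency @ sp.diags(v)).tocsr()
    return float(np.log(lam)), P


def _check_expression(x: np.ndarray, net: GeneNetwork) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != net.n_nodes:
        raise ValueError(
            f"expression vector length {x.shape[0]} does not match "
            f"network size {net.n_nodes}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("expression values must be strictly positive and finite")
    return x


def transition_matrix(x: np.ndarray, net: GeneNetwork) -> sp.csr_matrix:
    """Expression-weighted random-walk transition matrix.

    ``P_ij = x_j / (Ax)_i`` for neighbours j of i, zero elsewhere; every
    row sums to one and the sparsity pattern equals the adjacency's.
    Invariant under global rescaling of ``x``.
    """
    _require_connected(net)
    x = _check_expression(x, net)
    z = net.adjacency @ x
    P = (sp.diags(1.0 / z) @ net.adjacency @ sp.diags(x)).tocsr()
    return P


def stationary_distribution(x: np.ndarray, net: GeneNetwork) -> np.ndarray:
    """Stationary distribution of the expression-weighted walk.

    Closed form ``pi_i = x_i (Ax)_i / (x^T A x)``; satisfies
    ``pi P = pi`` and detailed balance ``pi_i P_ij = pi_j P_ji``.
    """
    _require_connected(net)
    x = _check_expression(x, net)
    z = net.adjacency @ x
    pi = x * z
    return pi / pi.sum()


def entropy_rate(x: np.ndarray, net: GeneNetwork) -> float:
    """Entropy rate Sr (nats) of the expression-weighted walk.

    Computed in the algebraically equivalent matvec form

        Sr = - (1/s) sum_i x_i [ (A (x ln x))_i - z_i ln z_i ],
        z = A x,  s = x^T z,

    which involves only nonzero kernel entries, so the 0*log(0) := 0
    convention is structural.
    """
    _require_connected(net)
    x = _check_expression(x, net)
    A = net.adjacency
    z = A @ x
    w = A @ (x * np.log(x))
    s = float(x @ z)
    return float(-(x @ (w - z * np.log(z))) / s)


def normalized_sr(x: np.ndarray, net: GeneNetwork, max_sr: float) -> float:
    """Normalized entropy rate SR = Sr / maxSr, in (0, 1]."""
    if max_sr <= 0:
        raise ValueError("max_sr must be positive (network with >= 2 nodes)")
    return entropy_rate(x, net) / max_sr


def _logit2(srn: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(srn) - np.log2(1.0 - srn)


def sr_profile(expr, net: GeneNetwork, align: bool = True) -> SRProfile:
    """Per-cell normalized entropy rates for an expression matrix.

    Parameters
    ----------
    expr
        Genes x cells matrix: a ``pandas.DataFrame`` (index = gene ids,
        columns = cell ids) or any object with ``values``, ``gene_ids``
        and ``cell_ids`` attributes.
    net
        Interaction network.  When ``align`` is true the network is
        first intersected with the matrix's genes and reduced to its
        largest connected component.
    align
        Set to False when ``expr`` rows already match ``net.gene_ids``
        exactly.

    Every cell is processed independently (the result does not depend
    on cell order or chunking); ``maxSr`` is computed once from the
    topology.

    Raises
    ------
    ValueError
        If any retained expression entry is nonpositive (the message
        names the first offending cell and gene).
    """
    if isinstance(expr, pd.DataFrame):
        gene_ids = np.asarray(expr.index, dtype=object)
        cell_ids = np.asarray(expr.columns, dtype=object)
        values = expr.to_numpy(dtype=float)
    else:
        gene_ids = np.asarray(expr.gene_ids, dtype=object)
        cell_ids = np.asarray(expr.cell_ids, dtype=object)
        values = np.asarray(expr.values, dtype=float)

    if align:
        net = intersect_with_genes(net, gene_ids)
        order = {g: i for i, g in enumerate(gene_ids)}
        rows = np.array([order[g] for g in net.gene_ids])
        X = values[rows, :]
    else:
        if not np.array_equal(gene_ids, net.gene_ids):
            raise ValueError("expression genes do not match network genes; use align=True")
        _require_connected(net)
        X = values

    bad = np.argwhere(~(X > 0) | ~np.isfinite(X))
    if bad.size:
        g, c = bad[0]
        raise ValueError(
            f"nonpositive expression for gene {net.gene_ids[g]!r} in cell "
            f"{cell_ids[c]!r}; entropy rates require strictly positive input"
        )

    lam, _v = dominant_eigenpair(net)
    max_sr = float(np.log(lam))

    A = net.adjacency
    Z = A @ X                      # (Ax) per cell
    W = A @ (X * np.log(X))        # A (x ln x) per cell
    s = np.einsum("gc,gc->c", X, Z)
    sr = -np.einsum("gc,gc->c", X, W - Z * np.log(Z)) / s
    srn = sr / max_sr
    # SR = 1 is attainable (walk equals the maximal-entropy walk); round-off
    # can overshoot by a few ulp, which would break the (0, 1] contract
    overshoot = (srn > 1.0) & (srn <= 1.0 + 1e-9)
    srn[overshoot] = 1.0
    sr[overshoot] = max_sr
    return SRProfile(
        cell_ids=cell_ids,
        sr=sr,
        max_sr=max_sr,
        srn=srn,
        logit_sr=_logit2(srn),
        n_genes_used=net.n_nodes,
    )
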