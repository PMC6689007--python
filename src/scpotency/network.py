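"""Undirected gene-interaction networks.

The entropy-rate machinery operates on an unweighted, undirected
protein--protein interaction (PPI) network whose nodes are gene
identifiers.  The network is stored as a symmetric binary sparse
adjacency matrix with a zero diagonal, nodes ordered lexicographically
by gene id so that all downstream results are independent of input
order.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GeneNetwork",
    "read_edge_list",
    "largest_connected_component",
    "intersect_with_genes",
]

# tokens recognised as a header line in an edge-list file
_HEADER_TOKENS = {
    "gene1", "gene2", "genea", "geneb", "from", "to", "source", "target",
    "node1", "node2", "protein1", "protein2",
}


@dataclass
class GeneNetwork:
    """An undirected, unweighted gene network.

    Parameters
    ----------
    gene_ids
        Ordered array of node identifiers (one per row/column of
        ``adjacency``).
    adjacency
        Symmetric binary CSR matrix with zero diagonal; ``A[i, j] = 1``
        iff genes *i* and *j* interact.
    """

    gene_ids: np.ndarray
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if not sp.issparse(self.adjacency):
            self.adjacency = sp.csr_matrix(np.asarray(self.adjacency, dtype=float))
        self.adjacency = self.adjacency.tocsr().astype(float)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} gene ids"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def validate(self) -> None:
        """Raise ``ValueError`` if the structural invariants are violated."""
        A = self.adjacency
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if A.nnz and not np.all(np.isin(A.data, [1.0])):
            raise ValueError("adjacency entries must be 0 or 1")
        if len(np.unique(self.gene_ids)) != self.n_nodes:
            raise ValueError("duplicate gene ids")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def network_from_edges(
    edges: Iterable[tuple[str, str]],
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from an iterable of undirected edges.

    Self-loops are dropped, duplicate/reversed edges are merged, and
    nodes are ordered lexicographically.
    """
    pairs = set()
    nodes = set()
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
        if a == b:
            continue
        pairs.add((a, b) if a < b else (b, a))
    gene_ids = np.array(sorted(nodes), dtype=object)
    index = {g: i for i, g in enumerate(gene_ids)}
    if pairs:
        i = np.array([index[a] for a, b in pairs] + [index[b] for a, b in pairs])
        j = np.array([index[b] for a, b in pairs] + [index[a] for a, b in pairs])
        data = np.ones(len(i), dtype=float)
        A = sp.coo_matrix((data, (i, j)), shape=(len(gene_ids),) * 2).tocsr()
    else:
        A = sp.csr_matrix((len(gene_ids),) * 2)
    return GeneNetwork(gene_ids=gene_ids, adjacency=A)


def read_edge_list(path: str | Path, undirected: bool = True) -> GeneNetwork:
    """Read a two-column (tab/space-delimited) edge list into a network.

    A single header line is tolerated when its tokens look like column
    names (``gene1``, ``source`` ...).  Edges are symmetrized (the file
    order of the two columns is irrelevant), duplicates are merged and
    self-loops removed.  Gzip-compressed files are read transparently.

    Raises
    ------
    ValueError
        On an empty file, a line without exactly two nonempty
        identifiers (the message names the offending line number), or
        ``undirected=False`` (directed networks are unsupported).
    """
    if not undirected:
        raise ValueError("directed networks are not supported")
    edges: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.replace(",", "\t").split()
            if lineno == 1 and len(tokens) >= 2 and all(
                t.lower() in _HEADER_TOKENS for t in tokens[:2]
            ):
                continue
            if len(tokens) != 2 or not tokens[0] or not tokens[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected two nonempty gene "
                    f"identifiers, got {line!r}"
                )
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return network_from_edges(edges)


def largest_connected_component(net: GeneNetwork) -> GeneNetwork:
    """Restrict a network to its largest connected component.

    Ties in component size are broken in favour of the component
    containing the lexicographically smallest gene id (which, because
    nodes are sorted, is the component with the smallest node index).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    n_comp, labels = connected_components(net.adjacency, directed=False)
    if n_comp == 1:
        return net
    sizes = np.bincount(labels, minlength=n_comp)
    best_size = sizes.max()
    # among max-size components, the one whose smallest member index is
    # smallest; gene_ids are lexicographically sorted, so this is the
    # component holding the smallest gene id
    candidates = np.flatnonzero(sizes == best_size)
    first_member = np.array([np.argmax(labels == c) for c in candidates])
    keep_label = candidates[np.argmin(first_member)]
    mask = labels == keep_label
    idx = np.flatnonzero(mask)
    A = net.adjacency[np.ix_(idx, idx)].tocsr()
    return GeneNetwork(gene_ids=net.gene_ids[idx], adjacency=A)


def intersect_with_genes(
    net: GeneNetwork, gene_ids: Sequence[str] | set[str]
) -> GeneNetwork:
    """Induced subgraph on ``gene_ids``, reduced to its largest component.

    This is the alignment step applied before computing entropy rates on
    expression data: the network is restricted to measured genes, then
    to the largest connected component (the Perron--Frobenius eigenpair
    is only well-defined on a connected graph).

    Raises
    ------
    ValueError
        If the intersection is empty or the resulting component has
        fewer than two nodes.
    """
    wanted = set(gene_ids)
    mask = np.array([g in wanted for g in net.gene_ids])
    if not mask.any():
        raise ValueError("no overlap between network genes and supplied gene ids")
    idx = np.flatnonzero(mask)
    sub = GeneNetwork(
        gene_ids=net.gene_ids[idx],
        adjacency=net.adjacency[np.ix_(idx, idx)].tocsr(),
    )
    sub = largest_connected_component(sub)
    if sub.n_nodes < 2:
        raise ValueError(
            "intersection with the network leaves a component of fewer than "
            "2 connected genes; the entropy rate is undefined"
        )
    return sub
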