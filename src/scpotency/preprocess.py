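"""Quality control and normalization of single-cell expression matrices.

Implements the droplet (UMI/read-count) recipe — cells kept when they
detect at least ``min_genes`` genes and their mitochondrial read
fraction is strictly below ``max_mito``; mitochondrial genes removed;
library-size normalization to the maximum per-cell total with a 1.1
pseudocount on the log2 scale — and the plate (FPKM) recipe,
``log2(FPKM + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedExpressionMatrix",
    "QCReport",
    "qc_filter",
    "normalize_library",
    "normalize_fpkm",
    "select_hvg",
    "mito_flags_from_prefix",
]

PSEUDOCOUNT = 1.1  # library-size normalization pseudocount


@dataclass
class CountMatrix:
    """Genes x cells matrix of nonnegative integer read/UMI counts."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito_flags: np.ndarray  # boolean per gene

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        g, c = self.counts.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValueError("id lists do not match count matrix dimensions")
        if len(self.mito_flags) != g:
            raise ValueError("mito_flags length does not match gene count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedExpressionMatrix:
    """Genes x cells log2-scale normalized expression."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        g, c = self.values.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValueError("id lists do not match matrix dimensions")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "NormalizedExpressionMatrix":
        return cls(
            values=df.to_numpy(float),
            gene_ids=np.asarray(df.index, dtype=object),
            cell_ids=np.asarray(df.columns, dtype=object),
            provenance=provenance,
        )

    def subset_genes(self, gene_ids) -> "NormalizedExpressionMatrix":
        wanted = list(gene_ids)
        order = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([order[g] for g in wanted])
        return NormalizedExpressionMatrix(
            values=self.values[rows, :],
            gene_ids=np.asarray(wanted, dtype=object),
            cell_ids=self.cell_ids,
            provenance=self.provenance,
        )


@dataclass
class QCReport:
    """Per-cell quality metrics and keep/drop decisions."""

    table: pd.DataFrame  # cell_id, genes_detected, mito_fraction, kept
    min_genes: int
    max_mito: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mito_flags_from_prefix(gene_ids, prefix: str = "MT-") -> np.ndarray:
    """Flag mitochondrial genes by identifier prefix (case-insensitive)."""
    p = prefix.upper()
    return np.array([str(g).upper().startswith(p) for g in gene_ids])


def qc_filter(
    cm: CountMatrix, min_genes: int = 1000, max_mito: float = 0.05
) -> tuple[CountMatrix, QCReport]:
    """Keep cells detecting >= ``min_genes`` genes with mitochondrial
    read fraction strictly < ``max_mito``.

    Boundary semantics follow the stated rules exactly: a cell at
    exactly ``min_genes`` is kept; a cell at exactly ``max_mito`` is
    removed.  Genes are untouched at this step.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be nonnegative")
    if not 0.0 <= max_mito <= 1.0:
        raise ValueError("max_mito must lie in [0, 1]")
    genes_detected = (cm.counts > 0).sum(axis=0)
    totals = cm.counts.sum(axis=0)
    mito_counts = cm.counts[cm.mito_flags, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    kept = (genes_detected >= min_genes) & (mito_fraction < max_mito)
    report = QCReport(
        table=pd.DataFrame(
            {
                "cell_id": cm.cell_ids,
                "genes_detected": genes_detected,
                "mito_fraction": mito_fraction,
                "kept": kept,
            }
        ),
        min_genes=min_genes,
        max_mito=max_mito,
    )
    filtered = CountMatrix(
        counts=cm.counts[:, kept],
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids[kept],
        mito_flags=cm.mito_flags,
    )
    return filtered, report


def normalize_library(cm: CountMatrix) -> NormalizedExpressionMatrix:
    """Library-size normalization with a log2 pseudocount of 1.1.

    Mitochondrial genes are dropped first; per-cell totals ``TRC_c``
    and their maximum ``maxC`` are recomputed on the reduced matrix;
    then

        LSC_gc = log2( RCM_gc * maxC / TRC_c + 1.1 ).

    Output is strictly positive (minimum ``log2(1.1)``), and the
    back-transformed per-cell sums all equal ``maxC`` exactly (library
    sizes are equalized).
    """
    keep = ~cm.mito_flags
    counts = cm.counts[keep, :].astype(float)
    trc = counts.sum(axis=0)
    zero = np.flatnonzero(trc <= 0)
    if zero.size:
        names = ", ".join(map(str, cm.cell_ids[zero][:10]))
        raise ValueError(
            f"{zero.size} cell(s) have zero non-mitochondrial counts: {names}"
        )
    max_c = trc.max()
    values = np.log2(counts * (max_c / trc)[None, :] + PSEUDOCOUNT)
    return NormalizedExpressionMatrix(
        values=values,
        gene_ids=cm.gene_ids[keep],
        cell_ids=cm.cell_ids,
        provenance=f"library-size log2 pseudocount {PSEUDOCOUNT}; maxC={max_c:g}",
    )


def normalize_fpkm(fpkm: pd.DataFrame) -> NormalizedExpressionMatrix:
    """``log2(FPKM + 1)`` normalization of a genes x cells FPKM matrix."""
    values = fpkm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("FPKM values must be nonnegative")
    return NormalizedExpressionMatrix(
        values=np.log2(values + 1.0),
        gene_ids=np.asarray(fpkm.index, dtype=object),
        cell_ids=np.asarray(fpkm.columns, dtype=object),
        provenance="log2(FPKM + 1)",
    )


def select_hvg(
    expr: NormalizedExpressionMatrix | pd.DataFrame,
    mean_thresh: float = 1.0,
    sd_thresh: float = 1.0,
) -> list:
    """Highly variable/expressed genes: mean > ``mean_thresh`` and
    sample standard deviation (n-1 denominator) > ``sd_thresh``,
    both strict."""
    if isinstance(expr, pd.DataFrame):
        values = expr.to_numpy(float)
        gene_ids = np.asarray(expr.index, dtype=object)
    else:
        values, gene_ids = expr.values, expr.gene_ids
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cells to estimate dispersion")
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    mask = (means > mean_thresh) & (sds > sd_thresh)
    return list(gene_ids[mask])
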