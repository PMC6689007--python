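"""Readers for expression matrices and gene sets.

Expression comes either as a 10X-style MatrixMarket triplet directory
(``matrix.mtx`` + ``genes.tsv``/``features.tsv`` + ``barcodes.tsv``)
or a dense TSV/CSV with genes as rows; both are gzip-transparent.
Gene sets come as GMT or one-gene-per-line text; signed signatures as
two-column (gene, sign) TSV.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .preprocess import CountMatrix, mito_flags_from_prefix
from .signatures import SignedSignature

__all__ = [
    "read_expression",
    "read_counts",
    "read_gene_set",
    "read_gmt",
    "read_signed_signature",
]


def _find(dirpath: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dirpath / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dirpath}")


def _read_ids(path: Path, column: int = 0) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, min(column, df.shape[1] - 1)].astype(str).to_numpy(dtype=object)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells matrix (MTX triplet directory or dense table).

    A directory is interpreted as a 10X-style triplet; a file as a
    dense TSV/CSV (delimiter inferred from the extension) with gene ids
    in the first column and cell ids in the header.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, ("matrix.mtx",))
        genes = _find(path, ("genes.tsv", "features.tsv"))
        barcodes = _find(path, ("barcodes.tsv",))
        mat = scipy.io.mmread(str(mtx)).toarray()
        gene_ids = _read_ids(genes, column=1) if _two_columns(genes) else _read_ids(genes)
        cell_ids = _read_ids(barcodes)
        return pd.DataFrame(mat, index=gene_ids, columns=cell_ids)
    sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _two_columns(path: Path) -> bool:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    return len(first.rstrip("\n").split("\t")) >= 2


def read_counts(path: str | Path, mito: str = "MT-") -> CountMatrix:
    """Read a count matrix; ``mito`` is a gene-id prefix or a path to a
    one-gene-per-line file of mitochondrial gene ids."""
    df = read_expression(path)
    if Path(mito).exists():
        mito_genes = set(read_gene_set(mito))
        flags = np.array([g in mito_genes for g in df.index])
    else:
        flags = mito_flags_from_prefix(df.index, prefix=mito)
    return CountMatrix(
        counts=df.to_numpy(),
        gene_ids=np.asarray(df.index, dtype=object),
        cell_ids=np.asarray(df.columns, dtype=object),
        mito_flags=flags,
    )


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line (blank lines ignored)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets = {}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: malformed GMT record")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_signed_signature(path: str | Path) -> SignedSignature:
    """Two-column TSV (gene, sign in {+1, -1}); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if not str(df.iloc[0, 1]).lstrip("+-").isdigit():
        df = df.iloc[1:]
    return SignedSignature(
        genes=df.iloc[:, 0].astype(str).to_numpy(dtype=object),
        signs=df.iloc[:, 1].astype(int).to_numpy(),
    )
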