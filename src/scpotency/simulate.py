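"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and seed, so
regeneration is bit-identical.  The generators emulate the structural
assumptions of the potency model — a cell's expression interpolating
between a focused, module-restricted profile (low potency / low
network entropy) and a flat profile (high potency / high entropy) —
plus a Y-shaped bifurcation geometry for trajectory inference and
overdispersed droplet-style counts for the QC/normalization
boundaries.  The noise models are chosen for testability, not
biological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneNetwork, network_from_edges
from .preprocess import CountMatrix, NormalizedExpressionMatrix

__all__ = [
    "FixtureBundle",
    "simulate_network",
    "simulate_potency_population",
    "simulate_bifurcation",
    "simulate_counts_10x",
]


@dataclass
class FixtureBundle:
    """A simulated dataset bundled with its ground truth.

    ``ground_truth`` is a per-cell DataFrame (indexed by cell id) whose
    columns depend on the generator: potency parameter ``t``, cluster /
    branch labels, arclength pseudotime.
    """

    network: GeneNetwork | None
    expression: NormalizedExpressionMatrix | None
    counts: CountMatrix | None
    ground_truth: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.network is not None:
            rows, cols = self.network.adjacency.nonzero()
            edges = [
                (self.network.gene_ids[i], self.network.gene_ids[j])
                for i, j in zip(rows, cols)
                if i < j
            ]
            pd.DataFrame(edges).to_csv(
                outdir / "network.tsv", sep="\t", header=False, index=False
            )
        if self.expression is not None:
            self.expression.to_frame().to_csv(outdir / "expression.tsv", sep="\t")
        if self.counts is not None:
            self.counts.to_frame().to_csv(outdir / "counts.tsv", sep="\t")
            pd.DataFrame(
                {"gene_id": self.counts.gene_ids, "mito": self.counts.mito_flags}
            ).to_csv(outdir / "mito_flags.tsv", sep="\t", index=False)
        self.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        manifest = {"seed": self.seed, "params": self.params}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "FixtureBundle":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        network = None
        if (outdir / "network.tsv").exists():
            from .network import read_edge_list

            network = read_edge_list(outdir / "network.tsv")
        expression = None
        if (outdir / "expression.tsv").exists():
            df = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
            expression = NormalizedExpressionMatrix.from_frame(df, provenance="loaded")
        counts = None
        if (outdir / "counts.tsv").exists():
            df = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col=0)
            flags = pd.read_csv(outdir / "mito_flags.tsv", sep="\t")
            counts = CountMatrix(
                counts=df.to_numpy(),
                gene_ids=np.asarray(df.index, dtype=object),
                cell_ids=np.asarray(df.columns, dtype=object),
                mito_flags=flags["mito"].to_numpy(bool),
            )
        gt = pd.read_csv(outdir / "ground_truth.tsv", sep="\t", index_col=0)
        return cls(
            network=network,
            expression=expression,
            counts=counts,
            ground_truth=gt,
            seed=manifest["seed"],
            params=manifest["params"],
        )


def _gene_names(n: int, prefix: str = "g") -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(n)], dtype=object)


def simulate_network(
    n_genes: int = 100,
    model: str = "erdos_renyi",
    density: float | int = 0.08,
    seed: int = 0,
    max_retries: int = 100,
) -> GeneNetwork:
    """Random connected undirected network over synthetic gene ids.

    ``model`` is ``erdos_renyi`` (``density`` = edge probability) or
    ``preferential_attachment`` (``density`` = edges per new node).
    Disconnected draws are resampled (bounded retries).
    """
    if n_genes < 10:
        raise ValueError("n_genes must be at least 10")
    names = _gene_names(n_genes)
    for attempt in range(max_retries):
        s = seed + 1000 * attempt
        if model == "erdos_renyi":
            g = nx.gnp_random_graph(n_genes, float(density), seed=s)
        elif model == "preferential_attachment":
            g = nx.barabasi_albert_graph(n_genes, int(density), seed=s)
        else:
            raise ValueError(f"unknown network model {model!r}")
        if g.number_of_edges() and nx.is_connected(g):
            edges = [(names[a], names[b]) for a, b in g.edges()]
            return network_from_edges(edges)
    raise RuntimeError(
        f"could not draw a connected {model} network in {max_retries} tries"
    )


def _state_means(n_states: int, separation: float) -> np.ndarray:
    return (np.arange(n_states) - (n_states - 1) / 2.0) * separation


def simulate_potency_population(
    net: GeneNetwork,
    n_cells: int = 200,
    n_states: int = 3,
    separation: float = 4.0,
    noise_sd: float = 0.1,
    module_frac: float = 0.1,
    seed: int = 1,
) -> FixtureBundle:
    """Cell population with a planted potency gradient on a network.

    Each cell draws a latent logit-potency from an ``n_states``-component
    Gaussian mixture (unit-sd components, means ``separation`` apart) and
    maps it to ``t = 1/(1+exp(-y))`` in [0, 1].  Expression interpolates
    between a cluster-specific module profile (mass concentrated on a
    random ~``module_frac`` subset of genes; low entropy) at t = 0 and a
    flat profile (maximal entropy) at t = 1, with multiplicative
    lognormal noise — so larger t spreads network flux more evenly and
    yields a higher entropy rate.

    Ground-truth columns: ``t``, ``logit_t``, ``state`` (1-based mixture
    component, ascending mean), ``cluster``.
    """
    if n_states < 2:
        raise ValueError("n_states must be at least 2")
    rng = np.random.default_rng(seed)
    n_genes = net.n_nodes
    cell_ids = np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object)

    means = _state_means(n_states, separation)
    state = rng.integers(0, n_states, size=n_cells)
    y = rng.normal(means[state], 1.0)
    t = 1.0 / (1.0 + np.exp(-y))

    n_clusters = n_states
    cluster = rng.integers(0, n_clusters, size=n_cells)
    module_size = max(2, int(round(module_frac * n_genes)))
    profiles = np.full((n_clusters, n_genes), 0.05)
    for c in range(n_clusters):
        module = rng.choice(n_genes, size=module_size, replace=False)
        profiles[c, module] = 1.0
    profiles /= profiles.sum(axis=1, keepdims=True)
    flat = np.full(n_genes, 1.0 / n_genes)

    base = (1.0 - t)[None, :] * profiles[cluster].T + t[None, :] * flat[:, None]
    noise = np.exp(noise_sd * rng.standard_normal((n_genes, n_cells)))
    values = base * noise
    values *= 1000.0 / values.sum(axis=0, keepdims=True)

    expr = NormalizedExpressionMatrix(
        values=values,
        gene_ids=net.gene_ids,
        cell_ids=cell_ids,
        provenance="simulate_potency_population",
    )
    gt = pd.DataFrame(
        {"t": t, "logit_t": y, "state": state + 1, "cluster": cluster + 1},
        index=cell_ids,
    )
    return FixtureBundle(
        network=net,
        expression=expr,
        counts=None,
        ground_truth=gt,
        seed=seed,
        params={
            "n_cells": n_cells,
            "n_states": n_states,
            "separation": separation,
            "noise_sd": noise_sd,
            "module_frac": module_frac,
        },
    )


def simulate_bifurcation(
    n_cells: int = 300,
    branch_lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 0.05,
    n_genes: int = 60,
    module_frac: float = 0.15,
    seed: int = 0,
    network: GeneNetwork | None = None,
) -> FixtureBundle:
    """Y-shaped bifurcation: a stem splitting into two branches.

    Cells sit at uniform arclength positions along a latent Y graph
    (stem, branch A, branch B, lengths per ``branch_lengths``).  In
    gene space the stem tip is a flat (maximal-entropy) profile; branch
    A and B endpoints are distinct module-restricted profiles; cells
    interpolate linearly along their segment, with multiplicative
    lognormal noise (``noise_sd = 0`` puts cells exactly on three line
    segments).  Potency therefore decreases away from the stem tip, so
    the planted root is the cell at arclength 0.

    Ground-truth columns: ``branch`` (stem/A/B), ``arclength`` (from the
    stem tip), ``cluster`` (1 = stem, 2 = A, 3 = B).
    """
    rng = np.random.default_rng(seed)
    if network is not None:
        n_genes = network.n_nodes
        gene_ids = network.gene_ids
    else:
        gene_ids = _gene_names(n_genes)
    cell_ids = np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object)

    ls, la, lb = branch_lengths
    total = ls + la + lb
    # endpoints in profile space; with a network, the stem tip sits at
    # the Perron profile (the exact maximal-entropy walk, SR = 1), so
    # the planted root is the strictly most potent cell
    if network is not None:
        from .entropy import dominant_eigenpair

        _, v = dominant_eigenpair(network)
        flat = v / v.sum()
    else:
        flat = np.full(n_genes, 1.0 / n_genes)
    module_size = max(2, int(round(module_frac * n_genes)))
    idx = rng.permutation(n_genes)
    mod_a, mod_b = idx[:module_size], idx[module_size : 2 * module_size]
    prof_a = np.full(n_genes, 0.05)
    prof_a[mod_a] = 1.0
    prof_a /= prof_a.sum()
    prof_b = np.full(n_genes, 0.05)
    prof_b[mod_b] = 1.0
    prof_b /= prof_b.sum()
    fork = 0.5 * (prof_a + prof_b)

    # each cell picks a segment with probability proportional to its
    # length, then a uniform position along that segment
    seg = rng.choice(3, size=n_cells, p=np.array([ls, la, lb]) / total)
    u = rng.uniform(0.0, 1.0, size=n_cells)
    seg[0], u[0] = 0, 0.0  # plant the root exactly at the stem tip
    branch = np.array(["stem", "A", "B"], dtype=object)[seg]
    arc = np.where(seg == 0, u * ls, ls + u * np.where(seg == 1, la, lb))
    starts = np.stack([flat, fork, fork])      # segment start profiles
    ends = np.stack([fork, prof_a, prof_b])    # segment end profiles
    base = ((1 - u)[:, None] * starts[seg] + u[:, None] * ends[seg]).T

    noise = np.exp(noise_sd * rng.standard_normal((n_genes, n_cells)))
    noise[:, 0] = 1.0  # root cell is noise-free: SR exactly maximal
    values = base * noise
    values *= 1000.0 / values.sum(axis=0, keepdims=True)

    expr = NormalizedExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        provenance="simulate_bifurcation",
    )
    cluster = np.where(branch == "stem", 1, np.where(branch == "A", 2, 3))
    gt = pd.DataFrame(
        {"branch": branch, "arclength": arc, "cluster": cluster},
        index=cell_ids,
    )
    return FixtureBundle(
        network=network,
        expression=expr,
        counts=None,
        ground_truth=gt,
        seed=seed,
        params={
            "n_cells": n_cells,
            "branch_lengths": list(branch_lengths),
            "noise_sd": noise_sd,
            "n_genes": int(n_genes),
            "module_frac": module_frac,
        },
    )


def simulate_counts_10x(
    n_genes: int = 500,
    n_cells: int = 100,
    mito_fraction_range: tuple[float, float] = (0.0, 0.1),
    dropout: float = 0.5,
    mean_count: float = 5.0,
    nb_dispersion: float = 0.5,
    boundary_min_genes: int | None = None,
    boundary_mito: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Droplet-style count matrix with planted QC boundary cells.

    Counts are negative-binomial with Bernoulli dropout; 5% of genes
    are designated mitochondrial (``MT-`` prefix) and each cell's mito
    load is drawn from ``mito_fraction_range``.  Two boundary cells are
    planted deterministically: cell 0 detects exactly
    ``boundary_min_genes`` genes (default: half the genes) with zero
    mitochondrial counts, and cell 1 has a mitochondrial fraction of
    exactly ``boundary_mito`` — exercising the inclusive gene-count and
    exclusive mito-fraction QC rules.
    """
    lo, hi = mito_fraction_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_mito = max(1, n_genes // 20)
    gene_ids = np.concatenate(
        [
            np.array([f"MT-{i}" for i in range(n_mito)], dtype=object),
            _gene_names(n_genes - n_mito),
        ]
    )
    mito_flags = np.array([g.startswith("MT-") for g in gene_ids])

    r = 1.0 / nb_dispersion
    p = r / (r + mean_count)
    counts = rng.negative_binomial(r, p, size=(n_genes, n_cells))
    keep = rng.random((n_genes, n_cells)) >= dropout
    counts = counts * keep

    # scale mito counts to a per-cell target fraction
    target = rng.uniform(lo, hi, size=n_cells)
    nonmito_tot = counts[~mito_flags, :].sum(axis=0)
    mito_target = (target / np.maximum(1 - target, 1e-9) * nonmito_tot).astype(int)
    counts[mito_flags, :] = 0
    for c in range(n_cells):
        if mito_target[c] > 0:
            alloc = rng.multinomial(mito_target[c], np.full(n_mito, 1 / n_mito))
            counts[:n_mito, c] = alloc

    if boundary_min_genes is None:
        boundary_min_genes = n_genes // 2
    if boundary_min_genes > (~mito_flags).sum():
        raise ValueError("boundary_min_genes exceeds the number of non-mito genes")
    # cell 0: exactly boundary_min_genes detected genes, no mito reads
    counts[:, 0] = 0
    nonmito_idx = np.flatnonzero(~mito_flags)
    counts[nonmito_idx[:boundary_min_genes], 0] = 1
    # cell 1: mito fraction exactly boundary_mito (rational fraction)
    frac = float(boundary_mito)
    denom = 1
    while abs(frac * denom - round(frac * denom)) > 1e-9 and denom < 10**6:
        denom *= 10
    mito_units = int(round(frac * denom))
    counts[:, 1] = 0
    counts[0, 1] = mito_units
    counts[nonmito_idx[: denom - mito_units], 1] = 1

    return CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object),
        mito_flags=mito_flags,
    )
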