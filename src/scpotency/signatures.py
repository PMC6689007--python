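"""Potency-associated differential expression and signature statistics.

Covers: per-gene linear models of expression on potency (optionally
adjusted for cell-cycle scores, optionally dropout-restricted),
cell-cycle phase scores as mean z-scores over phase gene sets, signed
signature construction (top up- and downregulated genes) and scoring
(Pearson correlation of the +/-1 signature with a profile), rank-based
gene-set enrichment with a Monte-Carlo null on the ranking, a
Monte-Carlo mean-difference test against random same-size gene sets,
and Fisher/hypergeometric overlap enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SignedSignature",
    "GseaResult",
    "de_vs_potency",
    "cell_cycle_scores",
    "build_signed_signature",
    "signature_score",
    "gsea_mc",
    "mc_mean_diff_test",
    "overlap_enrichment",
]


def _expr_frame(expr) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    return pd.DataFrame(
        np.asarray(expr.values, float), index=expr.gene_ids, columns=expr.cell_ids
    )


def _ols_t(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on X (first column after the intercept is the regressor
    of interest); returns (beta, t, two-sided p) for that coefficient."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or n <= p:
        return np.nan, np.nan, np.nan
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    if s2 <= 0:
        return np.nan, np.nan, np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * XtX_inv[1, 1])
    t = beta[1] / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(t), float(pval)


def de_vs_potency(
    expr,
    response,
    covariates=None,
    drop_zeros: bool = False,
    min_cells: int = 10,
    zero_value: float | None = None,
) -> pd.DataFrame:
    """Per-gene linear model of expression on a potency estimate or group.

    Parameters
    ----------
    expr
        Genes x cells normalized expression.
    response
        Per-cell regressor: a continuous potency estimate (e.g. SR) or
        a binary group indicator.
    covariates
        Optional per-cell score vectors (e.g. cell-cycle scores), shape
        (n_cells,) each, included as additional regressors.
    drop_zeros
        When true, each gene's model is fitted only on cells where the
        gene is expressed — values above the dropout floor.  Intended
        for within-cluster contrasts where dropout confounds small
        differences.
    min_cells
        Genes with fewer usable cells are reported with missing
        statistics and excluded from the multiple-testing count.
    zero_value
        The normalized value representing a zero count (the dropout
        floor).  Defaults to the matrix-wide minimum.

    Returns a DataFrame indexed by gene with columns ``estimate``,
    ``t``, ``p``, ``p_bonf`` (min(1, p * n_tested)) and
    ``n_cells_used``.  Permutation of cell order leaves all statistics
    unchanged.
    """
    frame = _expr_frame(expr)
    values = frame.to_numpy(float)
    response = np.asarray(response, float).ravel()
    if response.shape[0] != values.shape[1]:
        raise ValueError("response length does not match cell count")
    if np.ptp(response) == 0:
        raise ValueError("response is constant; the model is unidentifiable")
    cov = None
    if covariates is not None:
        cov = np.column_stack([np.asarray(c, float).ravel() for c in covariates])
        if cov.shape[0] != response.shape[0]:
            raise ValueError("covariate length does not match cell count")
    if zero_value is None:
        zero_value = float(values.min())

    n_genes = values.shape[0]
    est = np.full(n_genes, np.nan)
    tstat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    used = np.zeros(n_genes, dtype=int)
    for g in range(n_genes):
        y = values[g]
        if drop_zeros:
            mask = y > zero_value + 1e-12
        else:
            mask = np.ones_like(y, dtype=bool)
        m = int(mask.sum())
        used[g] = m
        if m < min_cells:
            continue
        r = response[mask]
        if np.ptp(r) == 0 or np.ptp(y[mask]) == 0:
            continue
        cols = [np.ones(m), r]
        if cov is not None:
            cols.extend(cov[mask].T)
        est[g], tstat[g], pval[g] = _ols_t(y[mask], np.column_stack(cols))

    tested = np.isfinite(pval)
    n_tested = int(tested.sum())
    p_bonf = np.where(tested, np.minimum(1.0, pval * n_tested), np.nan)
    return pd.DataFrame(
        {
            "estimate": est,
            "t": tstat,
            "p": pval,
            "p_bonf": p_bonf,
            "n_cells_used": used,
        },
        index=frame.index,
    )


def cell_cycle_scores(expr, g1s_genes, g2m_genes) -> pd.DataFrame:
    """Cell-cycle phase scores: per-cell mean z-score over phase genes.

    Each signature gene present in the matrix is z-scored across cells;
    a cell's phase score is the mean z over the usable (nonzero
    variance) genes of that signature.  Returns a DataFrame with
    columns ``g1s`` and ``g2m`` indexed by cell id.
    """
    frame = _expr_frame(expr)
    out = {}
    for name, genes in (("g1s", g1s_genes), ("g2m", g2m_genes)):
        present = [g for g in genes if g in frame.index]
        sub = frame.loc[present].to_numpy(float) if present else np.empty((0, frame.shape[1]))
        sds = sub.std(axis=1, ddof=1) if len(sub) else np.array([])
        usable = sds > 0
        dropped = len(present) - int(usable.sum())
        if dropped:
            logger.info("cell_cycle_scores: dropped %d zero-variance %s genes", dropped, name)
        if not usable.any():
            raise ValueError(f"no usable genes for the {name} signature")
        z = (sub[usable] - sub[usable].mean(axis=1, keepdims=True)) / sds[usable][:, None]
        out[name] = z.mean(axis=0)
    return pd.DataFrame(out, index=frame.columns)


@dataclass
class SignedSignature:
    """Gene signature with per-gene sign (+1 up, -1 down)."""

    genes: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.signs = np.asarray(self.signs, dtype=int)
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if not np.all(np.isin(self.signs, [-1, 1])):
            raise ValueError("signs must be +1 or -1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "sign": self.signs})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignedSignature":
        return cls(genes=df.iloc[:, 0].to_numpy(), signs=df.iloc[:, 1].to_numpy())


def build_signed_signature(
    de: pd.DataFrame, n_up: int = 72, n_dn: int = 72, alpha: float = 0.05
) -> SignedSignature:
    """Signed signature from a DE table: top up- and downregulated genes.

    Significant genes (Bonferroni-adjusted p < ``alpha``) are split by
    the sign of the t-statistic; the ``n_up`` largest-t positives and
    ``n_dn`` most-negative-t genes form the signature (ties in t broken
    by gene id).  If fewer significant genes are available than
    requested, all of them are used with a logged warning.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    sig = de[(de["p_bonf"] < alpha) & np.isfinite(de["t"])]
    # deterministic ordering: by t, gene id breaking ties
    ups = sig[sig["t"] > 0]
    ups = ups.loc[sorted(ups.index, key=lambda g: (-ups.loc[g, "t"], str(g)))]
    dns = sig[sig["t"] < 0]
    dns = dns.loc[sorted(dns.index, key=lambda g: (dns.loc[g, "t"], str(g)))]
    if len(ups) < n_up or len(dns) < n_dn:
        logger.warning(
            "requested %d up / %d down genes but only %d / %d significant",
            n_up, n_dn, len(ups), len(dns),
        )
    up_genes = list(ups.index[:n_up])
    dn_genes = list(dns.index[:n_dn])
    genes = np.array(up_genes + dn_genes, dtype=object)
    signs = np.array([1] * len(up_genes) + [-1] * len(dn_genes))
    return SignedSignature(genes=genes, signs=signs)


def signature_score(profile, sig: SignedSignature) -> float:
    """Signed-signature score of one expression profile.

    The Pearson correlation between the signature's +/-1 vector and the
    profile, restricted to shared genes (missing genes are dropped with
    a logged count).  Invariant to positive affine transforms of the
    profile; lies in [-1, 1].
    """
    if isinstance(profile, pd.Series):
        prof = profile
    elif isinstance(profile, dict):
        prof = pd.Series(profile)
    else:
        raise TypeError("profile must be a pandas Series or dict of gene -> value")
    present = [i for i, g in enumerate(sig.genes) if g in prof.index]
    missing = len(sig.genes) - len(present)
    if missing:
        logger.info("signature_score: %d signature genes missing from profile", missing)
    if len(present) < 3:
        raise ValueError("fewer than 3 signature genes present in the profile")
    x = sig.signs[present].astype(float)
    y = prof.loc[sig.genes[present]].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("profile is constant on the signature genes")
    if np.ptp(x) == 0:
        raise ValueError("signature has only one sign among shared genes")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class GseaResult:
    """Rank-based enrichment with a Monte-Carlo null on the ranking."""

    running_es: np.ndarray   # length N+1, starts and ends at 0
    es_max: float
    nes: float
    p: float
    n_mc: int
    null_mean: float
    null_sd: float


def _running_max_es(hit_positions: np.ndarray, n: int, m: int) -> tuple[np.ndarray, float]:
    # integer increments: +(N-m) at hits, -m at misses, scale 1/(m(N-m))
    steps = np.full(n, -m, dtype=np.int64)
    steps[hit_positions] = n - m
    csum = np.concatenate([[0], np.cumsum(steps)])
    running = csum / float(m * (n - m))
    return running, float(running.max())


def gsea_mc(ranking, gene_set, n_mc: int = 1000, seed: int = 0) -> GseaResult:
    """Unweighted (Kolmogorov-Smirnov type) GSEA with a Monte-Carlo null.

    The running enrichment statistic climbs by 1/m at each of the m set
    genes and falls by 1/(N-m) at each miss along the ranked list of N
    genes, so it starts and ends at exactly 0; the observed statistic
    is the maximum of the curve.  The null reshuffles the ranking
    uniformly ``n_mc`` times; NES is the observed maximum divided by
    the mean null maximum, and the p-value is the upper Gaussian tail
    under the null maxima's mean and standard deviation.
    """
    ranking = list(ranking)
    n = len(ranking)
    gene_set = set(gene_set)
    hits = np.array([g in gene_set for g in ranking])
    m = int(hits.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranking")
    if m == n:
        raise ValueError("gene set covers the entire ranking (no misses)")
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100")

    running, es_max = _running_max_es(np.flatnonzero(hits), n, m)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_mc)
    for b in range(n_mc):
        pos = rng.choice(n, size=m, replace=False)
        _, null_max[b] = _running_max_es(pos, n, m)
    null_mean = float(null_max.mean())
    null_sd = float(null_max.std(ddof=1))
    nes = es_max / null_mean
    p = float(stats.norm.sf(es_max, loc=null_mean, scale=null_sd))
    return GseaResult(
        running_es=running,
        es_max=es_max,
        nes=float(nes),
        p=p,
        n_mc=n_mc,
        null_mean=null_mean,
        null_sd=null_sd,
    )


def mc_mean_diff_test(
    stat_per_gene, gene_set, n_mc: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo test of a gene set's mean statistic vs random sets.

    ``stat_per_gene`` is a Series (index = gene ids) of per-gene
    statistics (e.g. mean expression differences).  The observed value
    is the mean over ``gene_set``; the null draws ``n_mc`` uniform
    same-size gene sets; the one-tailed p-value is (r + 1)/(n_mc + 1)
    with r the number of null means >= observed.
    """
    stat = pd.Series(stat_per_gene)
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in stat.index]
    if missing:
        raise ValueError(f"gene set members absent from the universe: {missing[:5]}")
    observed = float(stat.loc[gene_set].mean())
    values = stat.to_numpy(float)
    m = len(gene_set)
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for b in range(n_mc):
        null[b] = values[rng.choice(len(values), size=m, replace=False)].mean()
    r = int(np.sum(null >= observed))
    p = (r + 1) / (n_mc + 1)
    return observed, float(p)


def overlap_enrichment(
    set_a, set_b, universe_size: int
) -> tuple[float, float]:
    """Overlap enrichment of two gene sets within a universe.

    Returns the 2x2 odds ratio (Haldane-Anscombe 0.5 correction applied
    when any cell is zero) and the one-tailed hypergeometric
    (Fisher-type) p-value for at least the observed overlap.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValueError("universe smaller than the union of the two sets")
    a = len(set_a & set_b)
    b = len(set_a) - a
    c = len(set_b) - a
    d = universe_size - union
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    oddsratio = (aa * dd) / (bb * cc)
    p = float(stats.hypergeom.sf(a - 1, universe_size, len(set_a), len(set_b)))
    return float(oddsratio), p
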