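# Methods

## Model

### Signaling entropy rate

A cell's differentiation potency is estimated without markers, from
how promiscuously its transcriptome spreads signaling flux over a
protein–protein interaction (PPI) network. Let `A` be the symmetric
binary adjacency matrix of the network (no self-loops) and `x` the
cell's strictly positive normalized expression aligned to the network
genes. Edge weights are taken proportional to `x_i x_j`; row-normalizing
yields the stochastic matrix

    P_ij = x_j / (A x)_i        for j ∈ N(i), 0 otherwise.

This chain is reversible, with stationary distribution available in
closed form,

    π_i = x_i (A x)_i / (xᵀ A x),

satisfying `πP = π` and detailed balance `π_i P_ij = π_j P_ji`. The
signaling entropy rate is

    Sr(x) = − Σ_i π_i Σ_j P_ij ln P_ij   (nats).

Implementation note: `Sr` is evaluated in the algebraically equivalent
matvec form `Sr = −(1/xᵀAx) Σ_i x_i [(A(x∘ln x))_i − z_i ln z_i]`,
`z = Ax`, which needs two sparse matrix–matrix products for a whole
genes×cells matrix, touches only nonzero kernel entries (the
`0·log 0 := 0` convention is structural), and makes per-cell results
independent of cell order or chunking.

For a fixed topology the maximum entropy rate over all compatible
chains is attained by the maximal-entropy random walk
`P_ij = A_ij v_j/(λ v_i)`, where `(λ, v)` is the dominant (Perron)
eigenpair of `A`; its rate is `maxSr = ln λ` and its stationary
measure is `π_i = v_i²`. The normalization constant is necessarily
`λ` (the only value making the rows sum to one), so it is fixed, not
configurable. The normalized entropy rate

    SR = Sr / maxSr ∈ (0, 1]

is the per-cell potency estimate; `SR = 1` exactly when the weighted
walk coincides with the maximal-entropy walk (`x ∝ v`). `SR` is
invariant to global rescaling of `x` and to the logarithm base; `Sr`
and `maxSr` are reported in nats.

Validity requires a connected network, so expression matrices are
first intersected with the network's genes and reduced to the largest
connected component; components of fewer than two nodes are an error.
The eigenpair uses a dense symmetric solver below 500 nodes and a
Lanczos solver with a deterministic all-ones start vector above, with
residual checked against `1e-10·λ`. Nonpositive expression entries
are rejected (naming the cell and gene) rather than clipped: the
library normalization below guarantees positivity, so a nonpositive
value indicates a pipeline error upstream and silent repair would bias
`Sr`.

Floating-point overshoot of `SR` above 1 (a few ulp, occurring when a
cell sits exactly at the Perron profile) is clamped to 1; overshoot
beyond `1e-9` is not clamped, as it would indicate a real defect.

### Preprocessing

Droplet (UMI/read-count) data: cells are kept when they detect at
least `min_genes` genes (default 1000, inclusive) and their
mitochondrial read fraction is strictly below `max_mito` (default
0.05). Mitochondrial genes are identified by the `MT-` prefix or an
explicit flag file. After filtering, mitochondrial genes are dropped,
per-cell totals `TRC_c` and their maximum `maxC` recomputed, and

    LSC_gc = log2( RCM_gc · maxC / TRC_c + 1.1 ).

The 1.1 pseudocount keeps the matrix strictly positive (minimum
`log2 1.1 ≈ 0.1375`), as the entropy computation requires. The
transform equalizes library sizes exactly: for every cell,
`Σ_g (2^LSC − 1.1) = maxC`, which the tests verify to 1e-6 relative.

Plate (FPKM) data are normalized as `log2(FPKM + 1)`; zeros remain
zeros, so FPKM matrices feed the entropy computation only after adding
network-gene positivity (or are used for scoring/DE, which tolerates
zeros).

Highly variable/expressed genes (for embedding and trajectory) are
those with mean > 1 and sample standard deviation (n−1 denominator)
> 1 on the log scale, both strict. The thresholds are data-scale
conventions for this normalization, not tuned constants.

### Potency states

Because `SR ∈ (0,1)`, its base-2 logit `y = log2(SR/(1−SR))` is
unbounded and near-Gaussian within a potency state. A one-dimensional
Gaussian mixture is fitted to the population's `y` values for
`K = 1..k_max` (default 6) components and `K` chosen by minimizing
`BIC = −2 log L + p ln n` (the sign convention is fixed here; some
packages maximize the negated quantity). EM uses k-means
initialization with 10 seeded restarts, tolerance 1e-8 on the mean
log-likelihood, at most 500 iterations, and a variance floor of
`1e-8·var(y)` to prevent single-point collapse. The EM itself is a
small vectorized implementation (a 1-D mixture needs no general
covariance machinery), cross-checked in the tests against
scikit-learn's `GaussianMixture` on the same data. Components may
have unequal variances by default (`equal_variance=True` ties them);
the more general model is the default because nothing constrains state
spreads to be equal. States are relabeled PS1…PSK by ascending mean,
so PSK is the high-potency state. Posteriors are
`∝ weight_k · N(y; mean_k, sd_k)`; hard labels take the argmax with
ties to the lower state.

### Landscape

Cell types are inferred in a 2-D embedding: PCA to `initial_dims`
(default 30) followed by t-SNE (perplexity 30, 1000 iterations,
seeded; wrapped from scikit-learn, not reimplemented), then DBSCAN
with `eps = 5`, `min_pts = 15`. Noise points receive the reserved
peripheral label 0. Because `eps` is in embedding units its meaning
depends on the embedding's scale; the embedding step is therefore
pluggable — any cells×2 coordinates may be supplied directly.
Clusters are renumbered by descending size with ties broken by
centroid coordinates, which makes labels invariant to input order.

Crossing cluster labels with potency states gives the cell-state
contingency table; a (state, cluster) pair qualifies as a *cell-state*
when it holds at least `min_cells` cells (default 5 — a minimal
"sufficient representation" choice; the threshold is deliberately
exposed). Peripheral cells are tabulated in their own column but
never qualify.

Per-state density surfaces are Gaussian product-kernel KDEs on a
`grid_size²` lattice (default 100) spanning the bounding box of *all*
cells, so surfaces of different states share an extent and are
directly comparable. Bandwidths follow Scott's rule per axis on the
subset (`σ·n^(−1/6)`); a degenerate axis falls back to 1% of the
extent. The grid is renormalized to integrate to exactly 1 over the
extent (a Gaussian kernel leaks mass outside any finite box). The
KDE is hand-rolled (two small matrix products) because
`scipy.stats.gaussian_kde` rejects degenerate subsets (e.g. all cells
of a state at one embedding point), which must work here.

### Trajectory

The root is the cell of maximal `SR` (first index on ties). The
diffusion map follows a fixed recipe: symmetric kNN graph (default
`k = 30`); Gaussian kernel `K_ij = exp(−d_ij²/(2 s_i s_j))` with
per-cell bandwidth `s_i` = median distance to the cell's k nearest
neighbours; density normalization `K' = K/(q qᵀ)` with `q` the kernel
row sums (α = 1), removing sampling-density effects; row normalization
to a stochastic operator, eigendecomposed through its symmetric
conjugate. Components are scaled so the trivial constant component
(eigenvalue 1) is exactly 1 and dropped; the top `n_dcs` (default 10)
nontrivial eigenpairs are retained with deterministic sign (largest-
magnitude entry positive). Diffusion pseudotime is the spectral
closed form

    dpt(i, j)² = Σ_ℓ (λ_ℓ/(1−λ_ℓ))² (ψ_ℓ(i) − ψ_ℓ(j))²

over the retained eigenpairs — equivalent to the matrix-inversion
form in the truncated eigenspace. Tips are the global and per-cluster
pseudotime maxima; branch *assignment* is intentionally not
implemented.

A `kernel="dense"` mode (fixed bandwidth, all pairs) exists because
exact sampling-measure invariance — duplicating every cell leaves the
spectrum unchanged — holds only for a fixed kernel; the adaptive kNN
kernel satisfies it approximately (duplication shrinks kNN radii).
Diffusion maps are run on HVG expression by default, not on embedding
coordinates: the embedding already discards geometry that the
diffusion operator can use.

### Signature statistics

*Differential expression*: per-gene ordinary least squares of
normalized expression on the potency estimate (or a group indicator),
optionally adjusted for the two cell-cycle scores as covariates;
t and two-sided p from the potency coefficient; Bonferroni adjustment
`min(1, p·n_tested)` over the genes actually tested. With
`drop_zeros=True` each gene's model uses only cells where the gene is
expressed — values above the dropout floor, taken as the matrix-wide
minimum (`log2 1.1` for library-normalized data) — intended for
within-cluster contrasts where dropout confounds small differences;
genes with fewer than 10 usable cells are reported with missing
statistics.

*Cell-cycle scores*: each phase-signature gene present in the matrix
is z-scored across cells (zero-variance genes dropped with a logged
count); a cell's phase score is the mean z over usable genes.

*Signed signatures*: from a DE table, the `n_up` most positive-t and
`n_dn` most negative-t Bonferroni-significant genes (ties broken by
gene id), coded +1/−1. A sample's score is the Pearson correlation of
the ±1 vector with its expression over the shared signature genes —
bounded in [−1, 1], invariant to positive affine transforms of the
profile, and antisymmetric under sign flip.

*GSEA*: classic unweighted running statistic, +1/m at the m set genes
and −1/(N−m) at misses along the N-gene ranking. Increments are
accumulated as integers (+(N−m) and −m, scaled once by 1/(m(N−m))),
so the curve ends at exactly 0 and a fully top-loaded set attains
max ES exactly 1. The null reshuffles the ranking uniformly (default
1000 draws, seeded); NES is the observed maximum over the mean null
maximum, and the p-value the upper Gaussian tail at the null maxima's
mean and sd. Under random rankings NES has expectation 1 but a
per-replicate sd near 0.5, so calibration checks average hundreds of
replicates.

*Monte-Carlo mean-difference test*: observed mean statistic over a
gene set versus means of uniformly drawn same-size sets; one-tailed
`p = (r+1)/(n_mc+1)` — the +1 correction makes the p-value
super-uniform (conservative) under the null, which the tests verify
by one-sided Kolmogorov–Smirnov.

*Overlap enrichment*: 2×2 odds ratio with Haldane–Anscombe 0.5
correction when any cell is zero, and a one-tailed hypergeometric
(Fisher) p-value.

## Synthetic data

The generators produce the structures the model assumes, with ground
truth, so every stage is testable without downloads. They are pure
functions of (parameters, seed) — regeneration is bit-identical — and
their noise models are chosen for testability, not biological realism.

- `simulate_network`: connected Erdős–Rényi or preferential-attachment
  graphs over synthetic gene ids (resampled with bounded retries until
  connected).
- `simulate_potency_population` (defaults: 200 cells, 3 states,
  separation 4 sd, lognormal noise sd 0.1, module size 10% of genes):
  each cell draws a latent logit-potency from a Gaussian mixture and
  maps it to `t ∈ [0,1]`; expression interpolates from a
  cluster-specific module-restricted profile (entropy-poor) at `t = 0`
  to a flat profile (entropy-rich) at `t = 1`, with multiplicative
  lognormal noise. Higher `t` therefore yields higher `SR` by
  construction, and well-separated states produce separated clumps in
  logit-SR. The `t → SR` mapping is monotone but nonlinear, so a
  planted Gaussian state maps to a skewed logit-SR clump; at small
  population sizes (≲250 cells) BIC can split such a clump into two
  components, which is a property of the fixture's geometry, not of
  the mixture fitter — the end-to-end state-recovery checks use 300
  cells.
- `simulate_bifurcation`: cells at uniform arclength along a latent
  Y-graph (stem + two branches), mapped to gene space as three line
  segments between a maximal-entropy stem-tip profile and two distinct
  module profiles, with multiplicative lognormal noise (`noise_sd = 0`
  puts cells exactly on the segments). With a network, the stem tip
  is the network's Perron profile and the planted root cell (index 0)
  is noise-free, so its `SR` is exactly 1 and strictly maximal —
  root recovery is then a sharp test, not a statistical one.
- `simulate_counts_10x`: negative-binomial counts with Bernoulli
  dropout, designated `MT-` genes, and two deterministically planted
  boundary cells — one detecting exactly the gene-count threshold
  (must be kept) and one at exactly the mitochondrial-fraction
  threshold (must be removed).

What passing these tests does *not* show: real scRNA-seq has
batch effects, ambient RNA, doublets, non-lognormal overdispersion
and biologically structured dropout, none of which the generators
emulate. The tests validate the algorithmic contracts, not the
biological calibration of `SR` on any particular tissue.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately small scale —
networks of 40–100 genes, populations of 120–300 cells, 20–50 seeded
replicates per recovery claim, Monte-Carlo nulls of 100–200 draws —
sizes at which every recovery property is already stable while the
whole suite completes in a couple of minutes. All randomness flows
from explicit seeds (NumPy `default_rng`, seeded k-means/t-SNE,
deterministic eigensolver start vectors), so every reported number is
reproducible bit-for-bit.

## Known limitations

- The PPI network is user-supplied; no curated network ships with the
  package, and results depend on its quality and coverage.
- DBSCAN's `eps` is embedding-scale-dependent; with a different
  embedding method or scale it must be re-chosen.
- DPT uses the truncated eigenspace; with very few retained
  components, fine branch structure can be blurred.
- Branch assignment, doublet detection, batch correction, imputation
  and survival modeling are out of scope.
- The mixture model is one-dimensional by design; multimodal structure
  orthogonal to potency is invisible to it.
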