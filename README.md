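# scpotency

Marker-free estimation of single-cell differentiation potency from
**signaling entropy rates**, with potency-state inference,
cell-density landscapes, and diffusion-pseudotime trajectories.

## The problem

Identifying stem-like or progenitor states in scRNA-seq snapshots
usually relies on marker genes, which high dropout rates can render
unusable. This package instead scores each cell by how promiscuously
its transcriptome distributes signaling flux over a protein–protein
interaction (PPI) network: pluripotent cells express signaling
pathways broadly (high entropy), committed cells channel flux through
few pathways (low entropy). The potency estimate requires no markers,
orders cells along differentiation gradients, and gives an unbiased
root for lineage-trajectory inference. It is aimed at computational
biologists analysing droplet or plate scRNA-seq of heterogeneous
tissues.

## The model

For a cell with strictly positive normalized expression `x` aligned to
the nodes of an undirected PPI network with adjacency matrix `A`, edge
weights `w_ij ∝ x_i x_j` define the random walk

    P_ij = x_j / (Ax)_i ,     π_i = x_i (Ax)_i / (xᵀAx) ,

whose entropy rate `Sr = −Σ_i π_i Σ_j P_ij ln P_ij` is normalized by
the topology's maximum `maxSr = ln λ` (`λ` the largest eigenvalue of
`A`) to the potency score `SR = Sr/maxSr ∈ (0, 1]`. Across a cell
population, a Gaussian mixture on `y = log2(SR/(1−SR))` with BIC model
selection yields discrete potency states PS1…PSK; crossing states
with t-SNE + DBSCAN cell-type clusters yields cell-states and
per-state density landscapes; and the maximal-SR cell roots a
diffusion map whose pseudotime
`dpt(i)² = Σ_ℓ (λ_ℓ/(1−λ_ℓ))² (ψ_ℓ(i) − ψ_ℓ(root))²` orders cells
along lineages. Downstream statistics (potency-associated
differential expression, signed-signature scoring, rank-based GSEA
with a Monte-Carlo null, mean-difference and overlap tests) are
included. See `docs/methods.md` for the full account.

## Worked example

`examples/01_entropy_rate_basics.py` computes everything by hand on
the 3-node path `a–b–c` with expression `x = (1, 1, 2)`:

```
P =
 [[0.     1.     0.    ]
 [0.3333 0.     0.6667]
 [0.     1.     0.    ]]
pi = [0.1667 0.5    0.3333] (closed form x_i (Ax)_i / x'Ax)
Sr     = 0.318257 nats
maxSr  = 0.346574 nats (= ln sqrt(2), the path's top eigenvalue)
SR     = 0.91830
```

The walk leaves the end nodes deterministically, so only the middle
node contributes entropy: `Sr = ½·H(1/3, 2/3) ≈ 0.3183` nats, and
`SR < 1` because the doubled expression of gene `c` biases the walk
away from the maximal-entropy walk (uniform expression on this graph
gives `SR = 1` exactly).

`examples/02_potency_states.py` runs the population-level model on a
simulated 300-cell gradient over a random 100-gene network:

```
cells: 300, network genes: 100
SR range: [0.626, 0.976]
Spearman(SR, planted potency t) = 0.919
BIC selects K = 3 potency states
  PS1: mean logit-SR +0.97, sd 0.12, 97 cells
  PS2: mean logit-SR +2.85, sd 0.81, 93 cells
  PS3: mean logit-SR +5.13, sd 0.07, 110 cells
high-potency state: PS3 (110 cells)
```

SR recovers the planted potency ordering (ρ = 0.92) and BIC recovers
the three planted states; PS3 collects the cells whose expression
spreads network flux most evenly. The remaining examples cover the
landscape (`04`), the bifurcation trajectory (`03`) and the signature
statistics (`05`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
scpotency simulate --kind potency --n-cells 200 --n-genes 100 --seed 1 --out fixture/
scpotency sr --expr fixture/expression.tsv --net fixture/network.tsv --out sr.tsv
scpotency potency --sr sr.tsv --kmax 6 --seed 42 --out states.tsv
scpotency run --config config.yaml      # full pipeline from a config file
```

Subcommands: `sr`, `qcnorm`, `potency`, `landscape`, `trajectory`,
`simulate`, `run`, `de`, `score`, `gsea`, `mctest`. Exit codes for
`run`: 0 ok, 2 config error, 3 stage error.

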