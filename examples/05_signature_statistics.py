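"""Potency-associated differential expression and signature scoring.

Plants potency-responsive genes in a simulated matrix, recovers them
by per-gene linear models, builds a signed signature from the DE
table, scores profiles against it, and runs the rank-based enrichment
test with its Monte-Carlo null.
"""

import numpy as np
import pandas as pd

from scpotency import (
    build_signed_signature,
    de_vs_potency,
    gsea_mc,
    mc_mean_diff_test,
    signature_score,
)

rng = np.random.default_rng(5)
n_cells, n_genes, n_planted = 500, 60, 10
sr = rng.uniform(0.2, 0.9, n_cells)
values = rng.normal(0, 1, (n_genes, n_cells))
signs = np.array(([1, -1] * n_planted)[:n_planted])
for g in range(n_planted):
    values[g] += signs[g] * 2.0 * sr
genes = [f"g{i:03d}" for i in range(n_genes)]
expr = pd.DataFrame(values, index=genes, columns=[f"c{i}" for i in range(n_cells)])

de = de_vs_potency(expr, sr)
n_sig = int((de["p_bonf"] < 0.05).sum())
print(f"{n_sig} genes Bonferroni-significant "
      f"(planted: {n_planted}); top gene {de['t'].abs().idxmax()}")

sig = build_signed_signature(de, n_up=5, n_dn=5)
print("signature:", ", ".join(f"{g}({s:+d})" for g, s in zip(sig.genes, sig.signs)))

ideal = pd.Series({g: float(s) for g, s in zip(sig.genes, sig.signs)})
print(f"score on a perfectly matching profile: "
      f"{signature_score(ideal, sig):+.2f}; on its negation: "
      f"{signature_score(-ideal, sig):+.2f}")

ranking = list(de.sort_values('t', ascending=False).index)
up_planted = [genes[g] for g in range(n_planted) if signs[g] > 0]
res = gsea_mc(ranking, up_planted, n_mc=1000, seed=0)
print(f"\nGSEA of planted up-genes against the t-ranking: "
      f"max ES = {res.es_max:.3f}, NES = {res.nes:.2f}, p = {res.p:.2e}")

obs, p = mc_mean_diff_test(de["t"], up_planted, n_mc=9999, seed=0)
print(f"Monte-Carlo mean-t test: observed {obs:.2f}, p = {p:.1e}")
print("\nThe planted up-regulated genes concentrate at the top of the")
print("ranking, so the running enrichment climbs early and the nulls reject.")
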