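"""Root selection and diffusion pseudotime on a planted bifurcation.

Simulates a Y-shaped lineage (stem splitting into branches A and B)
whose stem tip is the maximally potent cell, selects the root by
maximal SR, and checks that diffusion pseudotime tracks the planted
arclength along each branch.
"""

import numpy as np
from scipy.stats import spearmanr

from scpotency import (
    diffusion_map,
    diffusion_pseudotime,
    find_tips,
    select_root,
    sr_profile,
)
from scpotency.simulate import simulate_bifurcation, simulate_network

net = simulate_network(n_genes=60, seed=3)
bundle = simulate_bifurcation(n_cells=300, seed=3, network=net)
gt = bundle.ground_truth

profile = sr_profile(bundle.expression, net, align=False)
root = select_root(profile)
print(f"root cell: index {root} (SR = {profile.srn[root]:.4f}; "
      f"planted stem tip is index 0)")

dmap = diffusion_map(bundle.expression, k=30, n_dcs=10)
print("leading diffusion eigenvalues:", np.round(dmap.eigenvalues[:4], 3))

dpt = diffusion_pseudotime(dmap, root)
for branch in ("stem", "A", "B"):
    mask = (gt["branch"] == branch).to_numpy()
    rho = spearmanr(dpt[mask], gt["arclength"][mask]).statistic
    print(f"branch {branch:<4} Spearman(DPT, arclength) = {rho:.3f}")

tips = find_tips(dpt, gt["cluster"].to_numpy())
for cluster, cell in tips.cluster_tips.items():
    print(f"cluster {cluster} tip: cell {cell} on planted branch "
          f"{gt['branch'].iloc[cell]!r}")
print("\nDPT distances increase away from the max-SR root along both")
print("branches; the per-cluster tips mark the two terminal fates.")
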