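"""Compare pseudotime distributions ("ridge" densities) between genotypes.

Pseudotime values come from the simulator's per-class Beta ground truth
with a deletion location shift; densities share one grid and bandwidth so
the curves are directly comparable, and a permutation KS test quantifies
the divergence.
"""

import numpy as np

from orgscope import trajectory
from orgscope.synthdata import ScSimConfig, simulate_counts

cfg = ScSimConfig(seed=4, n_cells_per_class_per_sample=150)
_, meta, _ = simulate_counts(cfg)

groups = {g: sub["pseudotime"].to_numpy() for g, sub in meta.groupby("genotype")}
curves = trajectory.density_curves(groups)
for name, curve in curves.items():
    mean_pt = groups[name].mean()
    print(f"{name}: n={len(groups[name])}, density integral={curve.integral:.4f}, mean pseudotime {mean_pt:.3f}")

res = trajectory.genotype_divergence(groups["control"], groups["deletion"], n_perm=500, seed=0)
print(f"KS statistic {res['statistic']:.3f}, permutation p = {res['p_value']:.4f}")
# The deletion density is shifted toward later pseudotime (the injected
# +0.08 location shift); a small permutation p says the genotype
# distributions of differentiation stage genuinely differ.
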