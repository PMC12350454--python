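"""Cross-correlation of residue motion and region summaries.

Generates block-correlated bead fluctuations (two rigidly coherent
regions, uncorrelated with each other), computes the residue-residue
dynamic cross-correlation matrix and summarizes the internal coherence
of each region — the comparison used to argue that an inhibitor
destabilizes cooperative motion in one variant but not the other.
"""

import numpy as np

from bindscape import build_toy_complex, dccm, fit_pca, region_correlation_summary, select
from bindscape.essential import smallest_k_for_variance, variance_explained
from bindscape.synthetic import ToySpec, simulate_block_correlated

spec = ToySpec(seed=7, n_frames=5000, rho_intra=0.9, rho_inter=0.0)
trajectory = simulate_block_correlated(spec)
topology, _, _ = build_toy_complex(spec)
protein = select(topology, "segment:protein")

mat = dccm(trajectory, topology, protein)
n = len(mat.residue_ids)
half = n // 2
region_a = mat.residue_ids[:half]
region_b = mat.residue_ids[half:]

mean_aa, pos_aa = region_correlation_summary(mat, region_a, region_a)
mean_bb, pos_bb = region_correlation_summary(mat, region_b, region_b)
mean_ab, pos_ab = region_correlation_summary(mat, region_a, region_b)
print(f"intra-region A mean correlation: {mean_aa:+.3f} "
      f"(target {spec.rho_intra})")
print(f"intra-region B mean correlation: {mean_bb:+.3f}")
print(f"cross-region mean correlation  : {mean_ab:+.3f} "
      f"(target {spec.rho_inter})")

model = fit_pca(trajectory, topology, mat.selection, align=False)
k = smallest_k_for_variance(model, 0.5)
print(f"modes needed for 50% variance  : {k} "
      f"({100 * variance_explained(model, k):.1f}% explained)")
filtered = dccm(trajectory, topology, protein, pc_subset=k, model=model)
print(f"PC-filtered intra-A mean       : "
      f"{region_correlation_summary(filtered, region_a, region_a)[0]:+.3f}")
# Intra-region means near 0.9 and a cross mean near zero recover the
# generator's truth; the PC filter keeps only the essential subspace, so
# its matrix emphasizes the coherent collective motion.
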