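"""Spearman matrix, FDR adjustment, and network deconvolution.

Deconvolution inverts the transitive-closure series G_obs = G + G^2 + ...
on the eigenvalues, damping correlation that flows through indirect paths.
The 3-gene chain below shows the effect: A-B and B-C are direct (0.5), the
A-C entry (0.25) is exactly their transitive product, and deconvolution
pushes A-C far below the direct edges.
"""

import numpy as np

import metagenet as mg

ds = mg.generate_dataset(mg.SyntheticSpec(n_clusters=3, genes_per_cluster=10,
                                          n_background_genes=10, seed=7))
rel = mg.relative_abundance(ds.abundance)
corr = mg.spearman_matrix(rel)
print(f"genes: {len(corr.genes)}; rho range "
      f"[{corr.rho.min():.2f}, {corr.rho[np.triu_indices(len(corr.genes), 1)].max():.2f}]")
print(f"gene pairs with q < 0.05: {(corr.q[np.triu_indices(len(corr.genes), 1)] < 0.05).sum()}")

chain = np.array([[0.0, 0.5, 0.25], [0.5, 0.0, 0.5], [0.25, 0.5, 0.0]])
direct = mg.deconvolve(chain, gamma=1.0, zero_diagonal=False)
print(f"chain A-B: observed 0.50 -> direct {direct[0, 1]:.3f}")
print(f"chain A-C: observed 0.25 -> direct {direct[0, 2]:.3f}  (indirect, suppressed)")

# The direct A-C score drops well below A-B: the deconvolved matrix keeps
# first-order dependencies and attenuates everything explained by paths.
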