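"""Generate the benchmark simulation, corrupt it, and recover the clusters.

Builds a 1000-peak x 300-cell matrix with three cell types (100 specific
peaks each), drops out 40% of the nonzero entries, sprinkles 10% noise,
trains the mixture-prior VAE in quick mode and clusters the 10 latent
features with K-means.
"""

import numpy as np

from atacmix import cluster as cl
from atacmix import gmvae
from atacmix import preprocess as pp
from atacmix.simulate import SimConfig, simulate

bundle = simulate(SimConfig(dropout_rate=0.4, noise_prob=0.1, seed=0))
print(f"reference: {bundle.reference.n_peaks} peaks x "
      f"{bundle.reference.n_cells} cells, "
      f"{(bundle.reference.dense() != 0).mean():.1%} nonzero")
print(f"dropout zeroed {bundle.dropout_mask.sum()} entries, "
      f"noise overwrote {bundle.noise_mask.sum()}")

binarized = pp.binarize_input(bundle.corrupted)
model = gmvae.fit(binarized, gmvae.TrainConfig(k=3, quick=True,
                                               max_epochs=100, patience=15,
                                               seed=0))
features = gmvae.extract_features(binarized, model)
assignment = cl.kmeans_cluster(features, 3)
report = cl.evaluate(assignment, bundle.labels)

print(f"latent features: {features.shape}")
print(f"ARI {report.ari:.3f}  NMI {report.nmi:.3f}  F1 {report.f1:.3f}")
print("ARI/NMI/F1 of 1.0 mean the 3 simulated cell types are recovered "
      "exactly despite 40% dropout.")
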