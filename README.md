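# atacmix

Clustering, imputation and interpretation of single-cell ATAC-seq
peak-by-cell matrices with a Gaussian-mixture variational autoencoder.

## The problem

scATAC-seq measures chromatin accessibility one cell at a time, but a
diploid genome offers at most two chances to capture each open site, so the
peak-by-cell matrix is near-binary and overwhelmingly sparse: most truly
open sites read zero (dropout). Distances computed on the raw matrix are
unreliable, which breaks both cell-type clustering and any downstream
per-cell analysis. `atacmix` is for analysts who have an already-called
peak × cell count matrix and want (i) cell clusters, (ii) a denoised,
hole-filled version of the matrix, and (iii) the peaks that characterize
each cluster or latent feature.

## The model

Each cell's binarized profile **x** is generated from a latent cluster
c and a low-dimensional feature vector **z**:

```
c ~ Discrete(π),   z | c ~ N(μ_c, σ_c² I),   x | z ~ Bernoulli(μ_x)
```

with μ_x = sigmoid(Wz + b) from a single-layer decoder, and a ReLU MLP
encoder producing q(z|x) = N(μ_z, σ_z² I) via z = μ_z + σ_z ⊙ ε. Training
maximizes the evidence lower bound

```
L = E_q[log p(x|z)] − D_KL(q(z,c|x) ‖ p(z,c))
```

by Adam (weight decay 5e-4, mini-batches of 32) over encoder, decoder and
the mixture prior jointly, after an EM Gaussian-mixture initialization of
(π, μ_c, σ_c). Cells are clustered by K-means on the latent means μ_z;
imputation is the decoder output μ_x. All gradients are analytic numpy,
finite-difference-checked in the test suite. See `docs/methods.md` for the
closed-form KL, the training schedule, the Tracy-Widom cluster-number
estimate, and the entropy-based peak-specificity score.

## Worked example

```python
from atacmix import cluster as cl, gmvae, preprocess as pp
from atacmix.simulate import SimConfig, simulate

# 300 cells x 1000 peaks, 3 cell types, 40% dropout + 10% noise
bundle = simulate(SimConfig(dropout_rate=0.4, noise_prob=0.1, seed=0))
binarized = pp.binarize_input(bundle.corrupted)
model = gmvae.fit(binarized, gmvae.TrainConfig(k=3, quick=True,
                                               max_epochs=100, patience=15,
                                               seed=0))
features = gmvae.extract_features(binarized, model)   # (300, 10)
report = cl.evaluate(cl.kmeans_cluster(features, 3), bundle.labels)
print(f"ARI {report.ari:.3f}  NMI {report.nmi:.3f}  F1 {report.f1:.3f}")
```

prints (about a minute on one CPU):

```
ARI 1.000  NMI 1.000  F1 1.000
```

— the three simulated cell types are recovered exactly despite 40% of the
signal entries having been zeroed out. ARI and NMI are chance-adjusted and
information-theoretic agreement scores (1 = identical partitions); F1 is
micro-averaged after matching clusters to reference classes. The scripts in
`examples/` walk through imputation recovery, cluster-number estimation and
cluster-specific peak ranking the same way, and
`examples/04_full_pipeline_cli.sh` shows the equivalent shell workflow with
the `atacmix` command.

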