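# Methods

## The model

`atacmix` models a binarized peak-by-cell chromatin-accessibility matrix
with a variational autoencoder whose latent prior is a mixture of Gaussians.
Per cell, with `K` clusters and `d` latent dimensions:

```
c      ~ Discrete(π)                          cluster indicator
z | c  ~ N(μ_c, σ_c² I)                       diagonal Gaussian component
x | z  ~ Bernoulli(μ_x),  μ_x = sigmoid(Wz+b) single-layer decoder
```

The recognition network `q(z|x) = N(μ_z, σ_z² I)` is a ReLU MLP (hidden
widths 3200–1600–800–400 by default; the input layer adapts to the number
of peaks) with the reparameterization `z = μ_z + σ_z ⊙ ε`. The discrete
posterior factor is taken as `q(c|x) = p(c|z)` evaluated at the sampled `z`
(the standard choice for mixture-prior VAEs), which makes the KL term of
the evidence lower bound available in closed form:

```
ELBO = Σ_j [x_j log μ_xj + (1−x_j) log(1−μ_xj)]
     − Σ_c γ_c Σ_l ½[log σ²_cl + (σ²_zl + (μ_zl − μ_cl)²)/σ²_cl]
     + ½ Σ_l (1 + log σ²_zl)
     + Σ_c γ_c log(π_c/γ_c)
```

with responsibilities `γ_c ∝ π_c N(z; μ_c, σ_c² I)` computed in log space.
Cluster assignments come from K-means on the latent means `μ_z` (not from
`γ` directly), and imputation is the decoder evaluated at `μ_z`: a dense
matrix of Bernoulli means that fills dropout zeros and damps noise.

### Why a mixture prior

scATAC-seq matrices are extremely sparse and near-binary; a single
isotropic Gaussian prior tends to blur multimodal structure. Conditioning
`z` on a discrete cluster variable lets each component model one cell
population, which both sharpens the latent geometry for clustering and
regularizes imputation toward population-specific profiles. With `K = 1`
the model reduces exactly to a standard VAE (verified in the tests against
an independently coded Gaussian-prior KL).

## Training

All gradients are derived analytically and implemented in numpy; the test
suite checks every parameter gradient against central finite differences
at 1e-5 relative tolerance. One deliberate approximation: within each
gradient step the responsibilities `γ` are treated as constants
(stop-gradient) and recomputed from the current `z` every step — an
EM-flavoured scheme that keeps every term's gradient closed-form. The
optimizer is Adam with weight decay 5e-4 applied to weight matrices
(biases and prior parameters are exempt so the prior is not shrunk toward
zero), mini-batch size 32.

Schedule:

1. **Warm-up** (20 epochs): reconstruction loss only, with deterministic
   `z = μ_z`, so the encoder learns a useful embedding before the prior
   exists. Ten epochs — the smallest budget we tried — leave the latent
   space insufficiently structured for the mixture fit on harder inputs.
2. **Prior initialization**: a diagonal-covariance EM Gaussian mixture
   (scikit-learn, 5 restarts) fit to the warm-up latent means initializes
   `π`, `μ_c`, `σ_c²`.
3. **Joint training** (default 300 epochs): full ELBO over encoder,
   decoder and prior. `π` is kept on the simplex by a softmax
   parameterization and is learned by default (`learn_pi=False` freezes
   it); component variances are stored as log-variances.

Quick mode for larger matrices shrinks the encoder to 1024–128 and adds an
iteration cap of 30,000 mini-batches with early stopping after 10 epochs
without improvement; outside quick mode training runs for a fixed epoch
budget unless `patience` is set.

### Tunables that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | number of mixture components (clusters); estimate with `estimate_k` |
| `latent_dim` | 10 | latent features per cell |
| `encoder_dims` | 3200-1600-800-400 | hidden widths (1024-128 in quick mode) |
| `learning_rate` | 1e-3 | Adam step size; the published protocol leaves it open, and smaller values (2e-4) need several-fold more epochs to reach the same optimum |
| `batch_size` | 32 | mini-batch size |
| `weight_decay` | 5e-4 | L2 coupling added to weight gradients |
| `warmup_epochs` | 20 | reconstruction-only epochs before the mixture fit |
| `max_epochs` | 300 | joint-training budget |

### Numerical choices

* posterior and prior log-variances clamped to `[log 1e-4, 5]`; gradients
  are zeroed on the clamp boundary;
* decoder probabilities clamped to `[1e-7, 1 − 1e-7]` before logs;
* all mixture computations in log space with log-sum-exp, so `γ` is finite
  and sums to 1 even when every component density underflows;
* EM components with degenerate variance are floored at 1e-4 and logged;
* one global seed drives weight init, shuffling and `ε` sampling; K-means
  uses seed 18 by default so cluster assignments are repeatable.

## Preprocessing

Filters run in a fixed order: peak filter (≥ `min_reads` in ≥ `min_cells`
cells), cell filter (total reads ≥ n_filtered_peaks / 50), optional
rare/ubiquitous peak removal for very large peak sets (rare: reads > 2 in
< X% of cells; ubiquitous: reads ≥ 1 in ≥ (100−X)% of cells, both against
the same input set), then binarization (values > 1 masked to 1). The raw
counts are kept alongside: the post-hoc binarization of imputed values
thresholds on raw per-peak and per-cell means. Per-dataset thresholds used
in the published validation mixtures ship as named presets
(`atacmix.preprocess.PRESETS`) rather than hard-coded defaults.

## Cluster-number estimation

`estimate_k` counts eigenvalues of the cells × cells Gram matrix `XᵀX`
above `mean + t·s.d.` with `mean = (√(n−1)+√p)²` and
`s.d. = (√(n−1)+√p)(1/√(n−1)+1/p)^{1/3}` (n peaks, p cells), the
Tracy-Widom significance construction used in the SC3 lineage; the default
multiplier `t = 3.2724` is the upper ≈0.001 quantile. The second factor of
the s.d. is implemented as printed in its source (`1/p`); the classical
form `1/√p` is available via `sd_form="corrected"` — at benchmark sizes
the two thresholds differ by well under the gap between signal and bulk
eigenvalues, so the estimate is insensitive to the choice. The matrix is
used binarized and uncentered by default (`center=True` subtracts peak
means first).

## Evaluation metrics

ARI and NMI (geometric-mean normalization) delegate to scikit-learn, which
implements exactly the contingency-table formulas the package documents;
the tests verify both against brute-force implementations over exhaustive
small labelings. Micro-F1 requires a cluster-to-class correspondence that
is not part of the metric's definition; predicted clusters are matched to
reference classes by maximum-overlap Hungarian assignment on the
contingency table, after which micro precision = recall = F1 = the
fraction of correctly assigned cells; clusters left unmatched count their
cells as errors. A zero-entropy labeling makes NMI 0/0 and raises instead
of returning a convention value.

## Interpretation scores

**Confusion score**: Pearson cross-correlation matrix between imputed and
raw meta-cells (cluster-mean profiles), each diagonal entry `r` replaced
by `1 − r`, averaged over the upper triangle *including* the transformed
diagonal — excluding it would make the diagonal transformation a no-op.
Because the cross-correlation matrix is not symmetric, each unordered
cluster pair contributes the mean of its two entries, so the score does
not depend on how clusters happen to be ordered. 0 means structure
perfectly preserved.

**Cluster specificity**: per peak and cluster,
`score = 1 − sqrt(JensenDiv(p, q))` where `p` is the peak's signal
normalized to a distribution, `q` the ideal pattern with all mass on one
cluster, and the divergence uses base-2 entropies so both divergence and
score are exactly bounded by [0, 1]. The printed `q` is indexed by
cluster, so by default `p` aggregates each peak's mass per cluster
(`per_cell=True` compares distributions over individual cells; the two
coincide for uniform within-cluster signal). The one-hot `q` is normalized
to a probability distribution so its entropy is well defined. A peak's
final score is the maximum over clusters; the top 200 peaks (1000 for
larger analyses) are reported as cluster-specific.

**Feature-associated peaks**: the decoder is a single layer, so column `j`
of its weight matrix is feature `j`'s direct wiring to peaks. Each
feature's weights are summarized as a Gaussian; peaks beyond 2.5 s.d. from
the mean (both tails by default) are that feature's associated peaks.

## The simulation and what it does (not) show

`generate_reference` emulates a mixture of cell types with disjoint
marker-peak blocks: 300 cells in three equal clusters, 1000 peaks, 100
specific peaks per cluster carrying counts 1 or 2 at ratio 1:4
(P(2) = 0.8), all other entries zero. Corruption drops each nonzero entry
with probability `dropout_rate` (benchmarks sweep 0.1–0.8), then
overwrites each entry with 1 or 2 (same 1:4 ratio) with probability 0.1.
Whether noise may overwrite surviving signal entries is not constrained;
here it may (pure independent overwrite), and masks record exactly which
entries each step touched. Cluster sizes and block assignment are
deterministic; only values and masks are random. Cells divide evenly;
remainders are assigned round-robin.

This generator has disjoint, equally sized, internally homogeneous
clusters and peak-independent corruption. Real scATAC-seq data have
overlapping regulatory programs, depth gradients, batch effects and
peak-dependent capture rates — so recovery of this simulation demonstrates
the machinery (optimization, imputation, score definitions) rather than
field performance on real tissue.

## Problem sizes used in the shipped checks

The test suite and the examples run the quick-mode encoder (1024–128) on
the 300 × 1000 benchmark simulation with a 100-epoch budget and patience
15 — the package's standard single-CPU configuration, at which the suite
verifies exact cluster recovery (ARI 1.0) at dropout 0, ARI ≥ 0.8 at
dropout 0.4, and imputed-vs-truth correlation above the corrupted input's
at dropout 0.2–0.6. The gradient checks, metric oracles and closed-form
identity tests run on tiny matrices where brute force is exact.

## Known limitations

* Training is CPU-bound numpy; matrices beyond ~10⁵ peaks × 10⁴ cells call
  for mini-batched streaming and quick mode, and nothing here targets GPUs.
* The Bernoulli likelihood discards count magnitude beyond presence;
  datasets where 1-vs-2 reads carry signal lose that distinction.
* `q(c|x) = p(c|z)` with stop-gradient is an approximation to the exact
  mean-field optimum; in practice it matches the usual mixture-VAE
  training dynamics but it is not an exact coordinate ascent.
* The Tracy-Widom estimate assumes the non-signal spectrum is governed by
  a white Wishart edge; strong depth variation between cells can inflate
  the leading eigenvalues and the estimate with them.
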