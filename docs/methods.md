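# Methods

## Model

`moesimvae` implements a similarity-guided, mixture-of-experts
variational autoencoder for clustering and mode-specific generation of
[0,1]-scaled sample × feature matrices (CyTOF marker panels, scRNA-seq
expression, or any continuous omics matrix).

Components:

- **Encoder** — a fully connected network mapping a sample
  `x ∈ [0,1]^D` to a Gaussian variational posterior
  `q(z|x) = N(m(x), diag(e^{s(x)}))` over a latent space of dimension
  `D_z`. Codes are drawn with the reparameterization
  `z = m + e^{s/2} ⊙ ε`, `ε ~ N(0, I)`.
- **Clustering (gating) network** — an MLP with softmax head mapping
  `z` to probabilities `p_i ∈ Δ^{K-1}` over `K` experts. Each sample is
  routed *hard* to expert `argmax_k p_ik` (ties to the lowest index).
- **Mixture-of-experts decoder** — `K` independent MLPs with sigmoid
  output; expert `k` reconstructs only the samples gated to it, so each
  expert specializes on one data mode. Experts that end training with
  zero occupancy are "silenced"; the number of occupied experts
  estimates the number of clusters in the data.
- **Latent mixture** — the latent representation is shaped toward a
  mixture of standard Gaussians `z ~ Σ_k ω_k N(μ_k, I)`. The means are
  empirical, EM-style: `μ_k = (1/N_k) Σ_i p_ik z_i`, where `N_k` is the
  *hard* occupancy count (the printed estimator mixes a soft numerator
  with a hard denominator; `soft_cluster_means=True` switches to the
  fully soft weighted mean). Weights `ω_k = N_k / N` are empirical
  occupancies. Empty clusters carry flagged NaN means and are refused
  as sampling targets.

## Losses

With `x̂` the reconstruction, `P = {p_ik}` the clean assignment matrix,
`p̂` its dropout-noised counterpart and `S` the binary batch similarity
matrix:

- **Reconstruction** — full binary cross-entropy, summed over features,
  averaged over samples. (The source publications of this family of
  models often print the truncated `x log x̂` form; the truncated,
  sign-free variant is available via `truncated=True` for ablation but
  is unbounded below and not used for training.)
- **Covariance KL** — for each cluster with ≥ 2 members, per-dimension
  latent variances `σ_j` are estimated (maximum likelihood, ddof=0)
  from its hard-assigned codes and
  `KL(N(0,I) ‖ N(0,diag σ)) = ½ Σ_j (1/σ_j − 1 + ln σ_j)` is averaged
  over clusters (unweighted). Variances are floored at `1e-6`; clusters
  with < 2 members are skipped. `kl_per_cluster=False` uses one global
  estimate.
- **Similarity** — binary cross-entropy between `S` and the cluster
  co-membership matrix `G = P Pᵀ`, averaged over all `N²` entries.
  `G_ij ≈ 1` only when samples i and j concentrate probability on the
  same expert, so minimizing this reconstructs the similarity graph.
- **DEPICT** — cross-entropy `−(1/N) Σ_ik q_ik log p̂_ik` between the
  noisy path and sharpened targets
  `q_ik ∝ p_ik / (Σ_i' p_i'k)^{1/2}` (row-normalized). Targets are
  computed from the clean `p` and treated as constants; empty cluster
  columns contribute zero. This makes cluster features robust to
  dropout noise.

The total objective is
`L = L_reconst + π1·L_KL + w_sim·L_Similarity + π2·L_DEPICT`,
optimized end-to-end with Adam. `w_sim` (`similarity_weight`) is the
coefficient the similarity-ablation studies set to zero.

Reduction conventions are fixed as above so that the weights
`π1, π2, w_sim` have reproducible meaning across datasets.

## Similarity matrix

Built per batch, always binary, symmetric, unit-diagonal:

- `umap_knn` (default): the batch is projected with UMAP (metric
  configurable; `canberra` is the choice used for mass-cytometry
  panels) and `S_ij = 1` iff j is among i's k nearest neighbors in the
  projection *or vice versa* (OR-symmetrization, so isolated points
  keep neighbors).
- `umap_threshold`: `S_ij = 1` iff the projected distance ≤ threshold.
- `precomputed`: validated pass-through of a user matrix — the hook for
  weak supervision.
- `signature`: prior-knowledge mode for expression data. A cell is
  tagged with every signature feature on which it is strictly above the
  batch mean; cells tagged by exactly one signature are kept and are
  similar iff they share the tag.

A degenerate batch (all points identical) yields an all-ones S with a
warning.

## Training procedure

Batches are drawn once from a seeded permutation and kept fixed across
epochs; the last incomplete batch is dropped so S has a fixed size.
This lets each batch's similarity matrix be computed once and makes
runs bit-for-bit reproducible on a single CPU thread (the whole stack
is float64 numpy). Cluster means/weights are refreshed once per epoch
from a deterministic full pass (posterior means, no sampling noise);
`predict_clusters` uses the same deterministic pass.

`noise_warmup_epochs` linearly ramps the reparameterization noise from
0 to full scale: the gating first locks onto the similarity blocks on a
near-deterministic latent, after which the growing noise forces the
clusters to separate at the prior's unit scale.

Optimizer: Adam, default learning rate 1e-3 (the benchmark recipe uses
2e-3). No learning-rate schedules, early stopping, or pretraining.

## Defaults and the benchmark recipe

Library defaults follow the published guidance that reconstruction and
clustering coefficients sit near one while the KL coefficient sits near
zero: `pi1 = 0.01`, `pi2 = 1.0`, `similarity_weight = 1.0`, dropout
0.1, learned posterior log-variance with initial bias −3 (a tight
initial posterior; see below).

The Gaussian-mixture recovery benchmark (`synthetic` module) uses a
documented, stronger recipe (`study_model_config`,
`study_similarity_spec`, `STUDY_TRAIN_KWARGS`):

- `similarity_weight = 3` — the similarity loss is what spreads the
  latent mixture components apart; at weight 1 the components separate
  enough for clustering but not far enough (relative to the prior's
  unit variance) for sampled latents to gate cleanly.
- `posterior_logvar = 0.0` (pinned) — unit posterior noise makes each
  latent cluster round at the prior scale by construction, so the
  learned mixture of standard Gaussians matches what generation
  samples. Pinning also removes the `1/σ` gradient blow-up of the KL
  term (cluster variances can then never fall below ~1).
- noise warm-up 200 epochs, 600 epochs total, batch 200, lr 2e-3,
  latent dimension 2, UMAP-kNN similarity with k = 50 (k of the order
  of the expected within-batch cluster size, so within-cluster
  similarity coverage is near-complete; small k leaves most
  within-cluster pairs marked dissimilar, which fragments clusters
  under the full cross-entropy).

## Synthetic data

`simulate` draws `k_true` component means uniformly in
`[−mean_scale, mean_scale]^dim`, adds isotropic Gaussian noise
(`within_sd`), and min-max scales features to [0,1]. Defaults
(`dim=10`, `n_per_component=200`, `mean_scale=10`, `within_sd=1`) give
components a k-means oracle recovers at NMI ≥ 0.99, so failures of the
model are attributable to the model.

What this emulates — and does not: well-separated continuous Gaussian
modes. It does not produce negative-binomial scRNA-seq counts, zero
inflation, CyTOF marker skew, batch effects, or rare populations.
Passing the recovery study shows the architecture identifies
well-separated modes and silences surplus experts; it does not certify
performance on real single-cell data.

## Evaluation

- **NMI** — mutual information normalized by the arithmetic mean of the
  label entropies.
- **Matched accuracy** — accuracy after exact optimal one-to-one
  cluster↔class assignment (Hungarian algorithm on the contingency
  table, dummy-padded when cluster and class counts differ).
- **Population F-measure** — per true population, the best F1 over
  predicted clusters, averaged with size-proportional weights (the
  flow-cytometry benchmarking convention; `weighted=False` gives the
  plain mean). NaN/negative predictions count as unassigned and are
  excluded with a warning.
- **MMD** — unbiased squared maximum-mean-discrepancy estimate with an
  RBF kernel, bandwidth from the median pairwise distance of the pooled
  sample, scaled by the pooled sample size (n+m). The unbiased
  estimator can be slightly negative under the null. This scaling
  convention is this package's own; absolute MMD values are not
  comparable across conventions, only signs and orderings are. The
  ablation comparison is computed on *sampled* posterior codes: on
  posterior means the statistic saturates for tightly collapsed
  clusters and can rank a worse-separated representation higher.

## Numerical choices

- Probabilities and reconstructions clamped to `[1e-7, 1 − 1e-7]`
  inside all cross-entropies.
- Argmax ties break to the lowest index, deterministically.
- Constant features min-max scale to 0 (with a warning) and invert back
  to their original value.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; UMAP runs single-threaded with a fixed
  `random_state`.

## Problem sizes

The bundled studies run at desk scale: 600-sample mixtures, 15 experts,
600 epochs (~10–20 s per training run plus the one-off UMAP/numba
compilation). The recovery sweep over larger `k_true` grids and the
40-expert setting of the original study run with the same code via
`recovery_study`; their runtime grows linearly in epochs × batches.

## Known limitations

- The covariance KL constrains only per-dimension variances; latent
  clusters can be diagonally correlated. Pinning the posterior variance
  (benchmark recipe) sidesteps this; with a learned posterior, gating
  purity of mixture samples can degrade even when clustering is
  perfect.
- Hard routing means experts receive no gradient for samples they do
  not own; a cluster assigned to a poorly initialized expert must be
  re-routed by the gating rather than rescued by that expert.
- Per-batch UMAP projections are independent across batches; the
  similarity graph is only as stable as the projection on a batch-size
  sample.
- The printed mixed soft/hard mean estimator is kept as the default for
  fidelity; with very soft assignments it is not a convex combination
  of the member codes (the fully soft variant is).
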