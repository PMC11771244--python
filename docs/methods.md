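# Methods

## Problem and model

Spatially resolved transcriptomics measures a gene expression profile at
each capture location ("spot") together with its 2-D tissue position.
The package identifies *spatial domains* — spatially coherent regions of
spots sharing expression programs — by learning a per-spot embedding that
fuses expression with spatial neighbourhood structure, then clustering the
embeddings.

### Spatial graphs

* **SAG** (spatial adjacency graph): spots i and j are linked iff
  ‖x_i − x_j‖ < r (strict inequality). The radius r is tuned so the mean
  neighbour count lies in [5, 6], the connectivity of a hexagonally packed
  spot array. `tune_radius` searches candidate radii at quantiles of the
  per-spot k-th nearest-neighbour distance (k = 5..8, each nudged up by a
  relative 1e-9 so the k-th neighbour itself is included under the strict
  inequality) and returns the first candidate inside the band, else the
  closest one with a warning. On a *square* unit lattice the attainable
  mean degrees jump from ≈3.8 (4-neighbourhood) to ≈7.4 (8-neighbourhood),
  so the band is genuinely unreachable there and the fallback fires; on a
  hexagonally packed grid (`hex_grid_coords`) the band is reached exactly.
* **Corrupted views**: two stochastic edge-subsets of the SAG used as
  contrastive augmentations. An edge's removal probability is
  min(c_k · (s_max − s_ij)/(s_max − s_mean), γ) where s_ij is the cosine
  similarity of the endpoints' preprocessed expression; c_1 = 0.05,
  c_2 = 0.1, γ = 0.7. s_max and s_mean are taken over the *edge set*, not
  all n² pairs — a deliberate restriction for tractability, documented
  here because either reading is defensible. When s_max = s_mean the rule
  degenerates to uniform pruning at min(c_k, γ), avoiding 0/0. Views are
  re-drawn fresh every epoch.
* **ctSAG** (cell-type-aware SAG): a union-symmetrised kNN graph over
  spot coordinates (k = 35) whose cross-cluster edges — relative to an
  initial Louvain clustering of expression — are each removed with
  probability θ = 0.96. The initial clustering runs Louvain (igraph's
  multilevel algorithm, seeded) on a 15-NN graph over the top-30 principal
  components of the preprocessed expression at resolution 1.0. The kNN
  graph is built in coordinate space because the object is a *spatial*
  adjacency graph densified, not an expression graph.

### Encoder

A single-head graph-attention layer followed by a fully connected layer:

    e_ij   = σ(aᵀ [W h_i ‖ W h_j])            σ = logistic
    α_ij   = softmax over j ∈ N(i) ∪ {i}
    h_i'   = σ( Σ_j α_ij W h_j )
    h_i^F  = W_F · ELU(h_i')

Neighbourhoods are *closed* (the centre spot participates in both the
softmax and the sum). No bias terms; the logistic is used both for the
attention score and the aggregation nonlinearity. Weights use seeded
uniform Glorot initialisation. Defaults: 256 GAT units, 64 latent units —
in line with sibling spatial-transcriptomics encoders; both configurable.

### Objectives

* **Contrastive (every epoch)**: two-view InfoNCE with cosine similarity
  and temperature τ = 0.5. For spot i, the positive is its own embedding
  in the other view; negatives are all other spots in both views. The
  per-spot term is the *negative* log of the softmax probability so that
  minimisation is meaningful; a raw-dot-product mode is not offered
  because cosine keeps the loss scale-invariant in the embeddings.
* **Adjacency reconstruction**: MSE between logistic(H_F H_Fᵀ) and the
  0/1 ctSAG adjacency; the logistic squashes the inner product into [0,1]
  against the binary target.
* **Expression reconstruction**: MSE between the preprocessed expression
  and ELU(H_F W_gene).
* **Deep embedding clustering**: Student-t (1 d.o.f.) soft assignment Q
  to trainable centroids μ, sharpened target
  p_ij ∝ q_ij² / Σ_i q_ij (column mass over *all* spots — the standard
  DEC auxiliary distribution), and KL(P‖Q). `dec_loss` returns the plain
  KL sum. Inside the joint objective the trainer uses the **per-spot mean
  KL**: the sum grows linearly with n while the two reconstruction terms
  are means, and at n = 400 the unnormalised KL empirically overwhelms
  them and collapses the contrastively learned structure (end-to-end ARI
  drops from ≈0.85 to ≈0.1 on the benchmark tissue). The mean reduction
  puts all three tasks on a per-observation scale.
* **Multi-task sum**: L_MT = α_adj·l_adj + α_gene·l_gene + α_pred·l_pred
  with all α = 1 by default.

### Schedule and optimisation

Epochs are 1-based. Every epoch takes one full-batch Adam step
(lr 1e-3, β = (0.9, 0.999)) on the contrastive loss of two freshly drawn
views; at epochs divisible by `inv` (default 50) the encoder additionally
runs on the original SAG and L_MT is added. DEC centroids are initialised
by seeded K-Means at the first multi-task epoch, persist thereafter, and
receive gradient updates; P is recomputed from the current Q at each
multi-task epoch and treated as a constant within the step. Defaults:
600 epochs. Final embeddings always come from the uncorrupted SAG.
All randomness flows from a single integer seed (corruption draws,
K-Means, Louvain, parameter init), so a run is bitwise reproducible.

### Clustering and evaluation

With known K, a Gaussian mixture with one full covariance matrix shared
by all components (equal volume/shape/orientation — tied covariance) is
fitted by EM with a 1e-6 diagonal ridge, initialised from seeded K-Means
(not a hierarchical initialisation; the separable-mixture tests pin the
behaviour). With unknown K, Louvain on a 15-NN embedding graph.
Metrics: adjusted Rand index; mutual information normalised by the
arithmetic mean of entropies; and a Hungarian-matched mean IoU — the
truth×prediction overlap matrix is matched to maximise total overlap,
each matched pair contributes |∩|/|∪|, unmatched truth domains contribute
0, and the mean is over truth domains.

### Denoising decoder

A separate GAT + fully-connected model (same closed-neighbourhood
semantics, GAT stage first) trained after the encoder with the encoder
frozen: it maps the learned embeddings back to gene space and is fitted
by MSE against the expression. Defaults: hidden 64, 300 epochs, lr 1e-2 —
at 1e-3 the decoder underfits desk-scale fixtures and its output
degenerates toward per-gene means. The reconstruction is the denoised
profile. Because it is an MSE-trained spatial smoother it reduces
within-domain variability strongly (CV of marker genes drops several-fold
on the benchmark fixture) while *preserving*, not amplifying, the
domain-mean contrast ratio: under uniform dropout the contrast ratio of
the raw data is already nearly unbiased, so imputation cannot raise it.

## Preprocessing

Only panels larger than 3000 genes undergo selection of the top-3000
highly variable genes; small targeted panels are used whole. The ranking
is a Seurat-style normalized dispersion: per-gene var/mean of log1p
values, z-scored within 20 equal-frequency mean bins (degenerate bins get
z = 0), with raw dispersion and then gene order as tie-breaks. Expression
is then log(1 + x)-transformed and standardised per gene to mean 0 and
unit variance with the sample (n − 1) denominator; constant genes map to
zero columns, and re-applying the transform warns. Spots outside the
tissue are assumed removed upstream by platform tooling; the loader warns
about all-zero spots only.

## Synthetic tissue generator

Spots sit on a unit-spaced integer grid partitioned into contiguous
domains: horizontal bands (spot in row ρ gets label ⌊ρ·D/R⌋) or
concentric quantile rings. Each domain owns a disjoint block of marker
genes whose negative-binomial mean is multiplied by the effect size
inside the domain; counts are Gamma–Poisson draws with Var = μ + aμ²
(dispersion a), thinned by independent Bernoulli dropout applied after
all counts are drawn (so the same seed with and without dropout shares
the pre-dropout matrix). The canonical benchmark
(`three_band_benchmark`) is a 20×20 grid, 3 bands, 60 genes with 8
markers per domain, base mean 10, effect size 4, dispersion 0.5, dropout
0.3 — overdispersion and dropout in a range typical of spot-level counts,
with a marker shift strong enough that recovery is expected but not
trivial (PCA + GMM alone reaches only ≈0.4 ARI; the spatial model
reaches ≈0.8–0.94).

What the generator does *not* emulate: gene–gene correlation beyond the
block markers, library-size variation between spots, hexagonal spot
packing (domains sit on a square lattice; the hex helper exists for
radius-tuning geometry), segmentation noise, or multi-slice structure.
Passing the recovery tests therefore demonstrates that the pipeline
extracts planted spatially coherent signal from overdispersed, zero-
inflated counts — not that it matches annotation accuracy on real tissue.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 600-epoch training
on the 400-spot benchmark (about a minute per seed on one CPU core) and
use reduced sizes (8×8–10×10 grids, 16–48 hidden units, ≤120 epochs) for
schedule, determinism and denoising checks. Other fixed choices: strict
`<` in the radius graph; Hungarian objective = total intersection;
KL convention 0·log(0/q) = 0 with an error when q = 0 where p > 0;
an error (not a silent fix) for empty soft clusters, zero-norm embedding
rows, and non-finite losses (the diagnostic names the offending
component).

## Known limitations

* Full-batch training: memory is O(n²) in the contrastive and adjacency
  terms, appropriate for single slices up to a few thousand spots.
* DEC centroids receive only epochs/inv gradient steps; with the default
  schedule they stay close to their K-Means initialisation.
* The tied-covariance mixture is initialised by K-Means rather than a
  model-based hierarchical pass, so label assignments can differ from
  other EEE implementations on poorly separated mixtures.
* No histology features, no multi-slice integration, 2-D coordinates only.
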