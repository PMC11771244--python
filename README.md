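# stcluster

Spatial-domain identification for spatially resolved transcriptomics.

Spatial transcriptomics assays measure a gene expression profile at each
capture spot together with its 2-D position in the tissue. A central
analysis task is to segment the slice into *spatial domains* — regions of
spots that share both expression programs and spatial coherence (cortical
layers, organ substructures, embryonic tissues). `stcluster` learns a
per-spot embedding with a graph-attention autoencoder trained by graph
contrastive learning plus intermittent multi-task fine-tuning, then
clusters the embeddings.

## Model

Spots are linked into a spatial adjacency graph (SAG): an edge joins i
and j when ‖x_i − x_j‖ < r, with r tuned so spots have 5–6 neighbours on
average. A one-head GAT layer plus a fully connected layer encode the
preprocessed expression H over a graph A:

    e_ij  = σ(aᵀ[W h_i ‖ W h_j]),   α_ij = softmax_{j ∈ N(i)∪{i}}(e_ij)
    h_i'  = σ(Σ_j α_ij W h_j),      h_i^F = W_F ELU(h_i')

Training alternates two signals:

* **every epoch** — a two-view InfoNCE contrastive loss between encodings
  of two corrupted SAGs, where each edge is pruned with probability
  min(c_k (s_max − s_ij)/(s_max − s_mean), γ) driven by the endpoints'
  expression cosine similarity s_ij;
* **every `inv` epochs** — a multi-task loss combining (i) reconstruction
  of a cell-type-aware kNN graph (cross-cluster edges pruned at θ = 0.96)
  from logistic(H_F H_Fᵀ), (ii) expression reconstruction ELU(H_F W_gene),
  and (iii) deep embedding clustering: Student-t soft assignments Q to
  trainable centroids, sharpened into a target P, penalised by KL(P‖Q).

Domains come from a tied-covariance Gaussian mixture (all components
share one full covariance — the "EEE" family) when K is known, or Louvain
otherwise. Labelings are scored by ARI, NMI, and Hungarian-matched mean
IoU. A separate GAT + FC decoder trained on the frozen embeddings
returns a denoised expression matrix.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import stcluster as sc

# synthetic 20x20 tissue: 3 horizontal bands, 60 genes, 8 markers/domain,
# NB counts (effect size 4, dispersion 0.5) with 30% dropout
ds = sc.three_band_benchmark(seed=1)

result = sc.run_pipeline(ds, config=sc.TrainConfig(n_clusters=3, seed=1))
print("domains:", result.labeling.K)
print("ARI vs planted:", round(sc.ari(ds.labels, result.labels), 3))
print("IoU vs planted:", round(sc.iou_hungarian(ds.labels, result.labels), 3))
```

prints

```
domains: 3
ARI vs planted: 0.811
IoU vs planted: 0.874
```

i.e. the three planted bands are recovered almost spot-for-spot: an ARI
of 0.81 means the vast majority of spot pairs are grouped/separated in
agreement with the ground truth, and matched domains overlap their truth
regions by 87% on average. The same dataset clustered without spatial
information (PCA + GMM on expression alone) reaches only ≈0.42 ARI.

The same workflow is available from the shell:

```
stcluster run --input tissue.h5ad --n-clusters 3 --seed 1 --output out.h5ad
stcluster evaluate --pred pred.csv --truth truth.csv
stcluster denoise --input out.h5ad --output denoised.h5ad
```

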