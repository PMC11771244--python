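"""Graph-attention encoder: one single-head GAT layer followed by a fully
connected layer.

For spot i with preprocessed expression h_i the GAT layer computes attention
scores over the closed neighbourhood N(i) ∪ {i}

    e_ij  = sigmoid(a^T [W h_i || W h_j])
    α_ij  = softmax_j(e_ij)          (j runs over N(i) ∪ {i})
    h_i'  = sigmoid(Σ_j α_ij W h_j)

and the fully connected layer maps h_i^(F) = W_F ELU(h_i').  The attention
vector a is shared across spots (single head); no bias terms are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gather, segment_sum
from .graph import SpatialGraph

__all__ = ["EncoderParams", "Embeddings", "init_params", "compute_attention",
           "encode", "encode_tensors", "save_params", "load_params"]


@dataclass
class EncoderParams:
    """Trainable weights.  w_gat: gene_dim x gat_dim; a_vec: 2*gat_dim;
    w_f: gat_dim x latent_dim; w_gene: latent_dim x gene_dim (the expression-
    reconstruction head, trained by the multi-task objective)."""

    w_gat: Tensor
    a_vec: Tensor
    w_f: Tensor
    w_gene: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.w_gat, self.a_vec, self.w_f, self.w_gene]

    @property
    def gene_dim(self) -> int:
        return self.w_gat.shape[0]

    @property
    def gat_dim(self) -> int:
        return self.w_gat.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.w_f.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(gene_dim: int, gat_dim: int = 256, latent_dim: int = 64,
                seed: int = 0) -> EncoderParams:
    """Seeded uniform Glorot (fan-based) initialization."""
    rng = np.random.default_rng(seed)
    return EncoderParams(
        w_gat=Tensor(_glorot(rng, gene_dim, gat_dim, (gene_dim, gat_dim)),
                     requires_grad=True),
        a_vec=Tensor(_glorot(rng, 2 * gat_dim, 1, (2 * gat_dim,)),
                     requires_grad=True),
        w_f=Tensor(_glorot(rng, gat_dim, latent_dim, (gat_dim, latent_dim)),
                   requires_grad=True),
        w_gene=Tensor(_glorot(rng, latent_dim, gene_dim, (latent_dim, gene_dim)),
                      requires_grad=True),
    )


@dataclass
class Embeddings:
    """h_gat: spot x gat_dim GAT-layer output; h_f: spot x latent_dim final
    latent representation."""

    h_gat: np.ndarray
    h_f: np.ndarray


def _attention_tensors(features: Tensor, graph: SpatialGraph,
                       params: EncoderParams):
    """Per-directed-edge attention weights over closed neighbourhoods.

    Returns (centers, nbrs, alpha, wh): alpha[e] is the weight with which
    spot nbrs[e] contributes to center centers[e]; weights sum to 1 within
    each center.
    """
    if features.shape[0] != graph.n_spots:
        raise ValueError("feature rows do not match graph spot count")
    if features.shape[1] != params.gene_dim:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match encoder gene dim "
            f"{params.gene_dim}")
    centers, nbrs = graph.directed_closed()
    wh = features @ params.w_gat  # n x gat_dim
    d = params.gat_dim
    a_src = gather(params.a_vec, np.arange(d))       # first half of a
    a_dst = gather(params.a_vec, np.arange(d, 2 * d))  # second half
    s_src = wh @ a_src  # (n,)
    s_dst = wh @ a_dst
    e = (gather(s_src, centers) + gather(s_dst, nbrs)).sigmoid()
    # segment softmax over each center's closed neighbourhood; e is bounded
    # in (0,1) so no max-shift is needed for stability
    exp_e = e.exp()
    denom = gather(segment_sum(exp_e, centers, graph.n_spots), centers)
    alpha = exp_e / denom
    return centers, nbrs, alpha, wh


def compute_attention(features: np.ndarray, graph: SpatialGraph,
                      params: EncoderParams):
    """Attention weights as arrays: (centers, neighbours, alpha)."""
    centers, nbrs, alpha, _ = _attention_tensors(ad.as_tensor(features),
                                                 graph, params)
    return centers, nbrs, alpha.data


def encode_tensors(features: Tensor, graph: SpatialGraph,
                   params: EncoderParams) -> tuple[Tensor, Tensor]:
    """Differentiable forward pass; returns (h_gat, h_f) Tensors."""
    centers, nbrs, alpha, wh = _attention_tensors(features, graph, params)
    # weighted aggregation: h_gat[i] = sigmoid(sum_j alpha_ij * (W h_j))
    alpha_col = _as_column(alpha)
    weighted = gather(wh, nbrs) * alpha_col
    h_gat = segment_sum(weighted, centers, graph.n_spots).sigmoid()
    h_f = h_gat.elu() @ params.w_f
    return h_gat, h_f


def _as_column(t: Tensor) -> Tensor:
    def bw(g):
        if t.requires_grad:
            t._accumulate(g[:, 0])

    return Tensor._make(t.data[:, None], (t,), bw)


def encode(features: np.ndarray, graph: SpatialGraph,
           params: EncoderParams) -> Embeddings:
    """Forward pass returning plain arrays (no gradient bookkeeping)."""
    h_gat, h_f = encode_tensors(ad.as_tensor(features), graph, params)
    return Embeddings(h_gat=h_gat.data, h_f=h_f.data)


# ---------------------------------------------------------------------------
# checkpointing

def save_params(params: EncoderParams, path) -> None:
    np.savez(path, w_gat=params.w_gat.data, a_vec=params.a_vec.data,
             w_f=params.w_f.data, w_gene=params.w_gene.data)


def load_params(path) -> EncoderParams:
    with np.load(path) as z:
        return EncoderParams(
            w_gat=Tensor(z["w_gat"], requires_grad=True),
            a_vec=Tensor(z["a_vec"], requires_grad=True),
            w_f=Tensor(z["w_f"], requires_grad=True),
            w_gene=Tensor(z["w_gene"], requires_grad=True),
        )
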