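"""Loss functions for the contrastive and multi-task objectives.

Every loss has a differentiable Tensor form (used by the trainer) and a
NumPy-facing wrapper returning a float.  The contrastive loss is the
two-view InfoNCE objective: for spot i with embeddings u_i, v_i in the two
corrupted views,

    l(u_i) = -log  e^{s(u_i,v_i)/τ} /
             [ e^{s(u_i,v_i)/τ} + Σ_{k≠i} e^{s(u_i,v_k)/τ}
                                + Σ_{k≠i} e^{s(u_i,u_k)/τ} ]

with s the cosine similarity, averaged over both views and all spots.  The
multi-task sum combines adjacency reconstruction against the ctSAG
(logistic inner-product decoder, MSE), expression reconstruction
(ELU-linear head, MSE), and the deep-embedding-clustering KL term built
from the Student-t soft assignment Q and its sharpened target P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, diagonal

__all__ = ["ClusterState", "LossWeights", "contrastive_loss", "amr_loss",
           "ger_loss", "soft_assign", "target_distribution", "dec_loss",
           "multitask_loss"]


@dataclass
class LossWeights:
    """Task weights α_adj, α_gene, α_pred for the multi-task sum and the
    contrastive temperature τ (default 0.5)."""

    alpha_adj: float = 1.0
    alpha_gene: float = 1.0
    alpha_pred: float = 1.0
    tau: float = 0.5

    def validate(self) -> None:
        if min(self.alpha_adj, self.alpha_gene, self.alpha_pred) < 0:
            raise ValueError("task weights must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ClusterState:
    """DEC state: K centroids mu (trainable), soft assignment Q and its
    sharpened target P (row-stochastic)."""

    mu: Tensor
    q: np.ndarray | None = None
    p: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# helpers

def _row_normalize(t: Tensor) -> Tensor:
    norms = (t * t).sum(axis=1, keepdims=True).sqrt()
    if np.any(norms.data == 0):
        raise ValueError("zero-norm embedding row: cosine similarity undefined")
    return t / norms


def _to_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# contrastive (InfoNCE over two views)

def contrastive_loss_t(u: Tensor, v: Tensor, tau: float = 0.5) -> Tensor:
    if u.shape != v.shape:
        raise ValueError("view embeddings must have identical shape")
    n = u.shape[0]
    un = _row_normalize(u)
    vn = _row_normalize(v)
    s_uv = (un @ vn.T) * (1.0 / tau)
    s_uu = (un @ un.T) * (1.0 / tau)
    s_vv = (vn @ vn.T) * (1.0 / tau)
    e_uv, e_uu, e_vv = s_uv.exp(), s_uu.exp(), s_vv.exp()
    pos = diagonal(s_uv)  # s(u_i, v_i)/tau; symmetric between views
    # denominator for l(u_i): full cross-view row (includes the positive)
    # plus the within-view row minus its diagonal (self pair excluded)
    den_u = e_uv.sum(axis=1) + e_uu.sum(axis=1) - diagonal(e_uu)
    den_v = e_uv.T.sum(axis=1) + e_vv.sum(axis=1) - diagonal(e_vv)
    loss = ((den_u.log() - pos) + (den_v.log() - pos)).sum() / (2.0 * n)
    return loss


def contrastive_loss(u, v, tau: float = 0.5) -> float:
    """Two-view InfoNCE loss (>= 0; 0 when each spot is its own only pair)."""
    return float(contrastive_loss_t(_to_tensor(u), _to_tensor(v), tau).data)


# ---------------------------------------------------------------------------
# adjacency-matrix reconstruction (AMR)

def amr_loss_t(h_f: Tensor, target_adjacency: np.ndarray) -> Tensor:
    a_p = np.asarray(target_adjacency, dtype=float)
    n = h_f.shape[0]
    if a_p.shape != (n, n):
        raise ValueError(
            f"adjacency shape {a_p.shape} does not match {n} embedding rows")
    a_r = (h_f @ h_f.T).sigmoid()
    diff = a_r - Tensor(a_p)
    return (diff * diff).mean()


def amr_loss(h_f, target_adjacency) -> float:
    """MSE between logistic(H_F H_F^T) and the (dense 0/1) ctSAG adjacency."""
    return float(amr_loss_t(_to_tensor(h_f), target_adjacency).data)


# ---------------------------------------------------------------------------
# gene-expression reconstruction (GER)

def ger_loss_t(h_original: np.ndarray, h_f: Tensor, w_gene: Tensor) -> Tensor:
    h = np.asarray(h_original, dtype=float)
    recon = (h_f @ w_gene).elu()
    if recon.shape != h.shape:
        raise ValueError(
            f"reconstruction shape {recon.shape} != expression shape {h.shape}")
    diff = recon - Tensor(h)
    return (diff * diff).mean()


def ger_loss(h_original, h_f, w_gene) -> float:
    """MSE between the preprocessed expression and ELU(H_F W_gene)."""
    return float(ger_loss_t(np.asarray(h_original, float), _to_tensor(h_f),
                            _to_tensor(w_gene)).data)


# ---------------------------------------------------------------------------
# deep embedding clustering (SDP)

def soft_assign_t(h_f: Tensor, mu: Tensor) -> Tensor:
    """Student-t (1 dof) soft assignment: q_ij ∝ (1 + ||h_i - mu_j||^2)^-1."""
    h_sq = (h_f * h_f).sum(axis=1, keepdims=True)          # n x 1
    m_sq = (mu * mu).sum(axis=1, keepdims=True).T          # 1 x K
    cross = h_f @ mu.T                                     # n x K
    sqdist = h_sq + m_sq - 2.0 * cross
    kernel = 1.0 / (1.0 + sqdist)
    return kernel / kernel.sum(axis=1, keepdims=True)


def soft_assign(h_f, mu) -> np.ndarray:
    q = soft_assign_t(_to_tensor(h_f), _to_tensor(mu)).data
    return q


def target_distribution(q) -> np.ndarray:
    """Sharpened DEC target: p_ij ∝ q_ij^2 / f_j with f_j the soft cluster
    frequency Σ_i q_ij; rows renormalised to 1."""
    q = np.asarray(q, dtype=float)
    f = q.sum(axis=0)
    if np.any(f == 0):
        raise ValueError("empty soft cluster: a column of Q sums to zero")
    w = q**2 / f
    return w / w.sum(axis=1, keepdims=True)


def dec_loss_t(p: np.ndarray, q: Tensor) -> Tensor:
    p = np.asarray(p, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same shape")
    if np.any((q.data <= 0) & (p > 0)):
        raise ValueError("KL(P||Q) infinite: q_ij = 0 where p_ij > 0")
    mask = p > 0
    # sum over supported entries only (0 log 0 := 0); constant P entropy term
    # is kept so the value is the true KL divergence
    logq = (q + Tensor((~mask) * 1.0)).log()  # pad zeros where p == 0
    plogp = np.sum(p[mask] * np.log(p[mask]))
    return Tensor(plogp) - (Tensor(p) * logq).sum()


def dec_loss(p, q) -> float:
    """KL(P || Q) = Σ_ij p_ij log(p_ij / q_ij); >= 0, 0 iff P = Q."""
    return float(dec_loss_t(np.asarray(p, float), _to_tensor(q)).data)


# ---------------------------------------------------------------------------
# weighted multi-task sum

def multitask_loss(l_adj, l_gene, l_pred, weights: LossWeights):
    """L_MT = α_adj l_adj + α_gene l_gene + α_pred l_pred (Tensor-aware)."""
    weights.validate()
    total = (weights.alpha_adj * ad.as_tensor(l_adj)
             + weights.alpha_gene * ad.as_tensor(l_gene)
             + weights.alpha_pred * ad.as_tensor(l_pred))
    if isinstance(l_adj, Tensor) or isinstance(l_gene, Tensor) \
            or isinstance(l_pred, Tensor):
        return total
    return float(total.data)
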