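"""Collaborative training loop: contrastive learning every epoch,
multi-task fine-tuning every `inv` epochs.

Each epoch draws two fresh corrupted views of the SAG, encodes both, and
takes a gradient step on the two-view contrastive loss.  At epochs that are
multiples of `inv` (1-based), the encoder is additionally run on the
original, uncorrupted SAG and the multi-task loss — ctSAG adjacency
reconstruction + expression reconstruction + DEC — is added before the
step.  DEC centroids are initialised by seeded K-Means at the first
multi-task epoch and then persist, updated by gradient; the target
distribution P is recomputed from the current Q at every multi-task epoch
and treated as a constant within the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .dataset import SpatialDataset
from .encoder import EncoderParams, encode, encode_tensors, init_params
from .graph import CorruptionConfig, SpatialGraph, corrupt_graph, expression_louvain
from .objectives import (ClusterState, LossWeights, amr_loss_t, contrastive_loss_t,
                         dec_loss_t, ger_loss_t, multitask_loss, soft_assign_t,
                         target_distribution)

__all__ = ["TrainConfig", "TrainResult", "init_centroids", "train"]


@dataclass
class TrainConfig:
    """Hyperparameters of the collaborative optimisation.

    epochs/inv: total epochs and the fine-tuning interval (multi-task loss
    fires at epochs inv, 2*inv, ...).  c1/c2 are the per-view base pruning
    probabilities, gamma the truncation.  n_clusters: DEC cluster count K;
    when None, K is the number of Louvain communities of the initial
    expression clustering.
    """

    epochs: int = 600
    inv: int = 50
    lr: float = 1e-3
    weights: LossWeights = field(default_factory=LossWeights)
    c1: float = 0.05
    c2: float = 0.1
    gamma: float = 0.7
    n_clusters: int | None = None
    gat_dim: int = 256
    latent_dim: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.inv < 1:
            raise ValueError("epochs and inv must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        self.weights.validate()

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        weights = LossWeights(**raw.pop("weights", {}))
        return cls(weights=weights, **raw)


@dataclass
class TrainResult:
    params: EncoderParams
    embeddings: np.ndarray          # final H_F on the original SAG
    cluster_state: ClusterState | None
    loss_log: pd.DataFrame          # epoch, l_cl, l_adj, l_gene, l_pred, l_total
    n_clusters: int

    def write_loss_log(self, path) -> None:
        self.loss_log.to_csv(path, sep="\t", index=False)


def init_centroids(h_f: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded K-Means on the embeddings; centroids are member means."""
    from sklearn.cluster import KMeans

    h_f = np.asarray(h_f, dtype=float)
    if k > h_f.shape[0]:
        raise ValueError(f"K = {k} exceeds the number of spots {h_f.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(h_f)
    mu = np.vstack([h_f[km.labels_ == j].mean(axis=0) for j in range(k)])
    return mu


def train(dataset: SpatialDataset, sag: SpatialGraph, ctsag: SpatialGraph,
          config: TrainConfig) -> TrainResult:
    """Run the collaborative optimisation and return the trained model."""
    config.validate()
    x = dataset.dense()
    n = x.shape[0]
    if sag.n_spots != n or ctsag.n_spots != n:
        raise ValueError("graph spot counts do not match the dataset")

    params = init_params(x.shape[1], config.gat_dim, config.latent_dim,
                         seed=config.seed)
    opt = Adam(params.tensors(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    a_p = np.asarray(ctsag.adjacency().todense())
    x_t = Tensor(x)

    will_finetune = config.inv <= config.epochs
    n_clusters = config.n_clusters
    if n_clusters is None and will_finetune:
        n_clusters = int(expression_louvain(x, seed=config.seed).max()) + 1

    state: ClusterState | None = None
    rows = []
    for epoch in range(1, config.epochs + 1):
        seed_u = int(rng.integers(2**31))
        seed_v = int(rng.integers(2**31))
        view_u = corrupt_graph(sag, x, CorruptionConfig(config.c1, config.gamma, seed_u))
        view_v = corrupt_graph(sag, x, CorruptionConfig(config.c2, config.gamma, seed_v))
        _, hf_u = encode_tensors(x_t, view_u, params)
        _, hf_v = encode_tensors(x_t, view_v, params)
        l_cl = contrastive_loss_t(hf_u, hf_v, config.weights.tau)
        _check_finite(l_cl, "contrastive loss", epoch)

        total = l_cl
        l_adj_v = l_gene_v = l_pred_v = np.nan
        if epoch % config.inv == 0:
            _, h_f = encode_tensors(x_t, sag, params)
            l_adj = amr_loss_t(h_f, a_p)
            l_gene = ger_loss_t(x, h_f, params.w_gene)
            if state is None:
                mu0 = init_centroids(h_f.data, n_clusters, seed=config.seed)
                state = ClusterState(mu=Tensor(mu0, requires_grad=True))
                opt.add_param(state.mu)
            q_t = soft_assign_t(h_f, state.mu)
            state.q = q_t.data
            state.p = target_distribution(state.q)
            # per-spot mean KL so the clustering term is on the same
            # per-observation scale as the two MSE reconstruction terms;
            # the raw KL sum grows with n and overwhelms them
            l_pred = dec_loss_t(state.p, q_t) * (1.0 / n)
            for name, t in (("adjacency reconstruction", l_adj),
                            ("expression reconstruction", l_gene),
                            ("clustering KL", l_pred)):
                _check_finite(t, f"{name} loss", epoch)
            total = l_cl + multitask_loss(l_adj, l_gene, l_pred, config.weights)
            l_adj_v, l_gene_v, l_pred_v = (float(l_adj.data), float(l_gene.data),
                                           float(l_pred.data))

        opt.zero_grad()
        total.backward()
        opt.step()
        rows.append((epoch, float(l_cl.data), l_adj_v, l_gene_v, l_pred_v,
                     float(total.data)))

    log = pd.DataFrame(rows, columns=["epoch", "l_cl", "l_adj", "l_gene",
                                      "l_pred", "l_total"])
    final = encode(x, sag, params)
    return TrainResult(params=params, embeddings=final.h_f,
                       cluster_state=state, loss_log=log,
                       n_clusters=n_clusters if state is not None else 0)


def _check_finite(t: Tensor, name: str, epoch: int) -> None:
    if not np.all(np.isfinite(t.data)):
        raise FloatingPointError(
            f"non-finite {name} at epoch {epoch}; "
            "try lowering the learning rate")
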