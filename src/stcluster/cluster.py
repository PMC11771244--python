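"""Spatial-domain labelling and clustering evaluation.

Labelling uses a tied-covariance Gaussian mixture — all K components share
one full covariance matrix (equal volume, shape and orientation, the Mclust
"EEE" family) — when the number of domains is known, and Louvain community
detection on a kNN embedding graph when it is not.  Evaluation offers ARI,
NMI and a Hungarian-matched mean intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["Labeling", "fit_gmm_eee", "louvain_cluster", "ari", "nmi",
           "iou_hungarian"]


@dataclass
class Labeling:
    """Per-spot integer cluster ids, contiguous from 0."""

    labels: np.ndarray
    K: int

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "Labeling":
        _, labels = np.unique(np.asarray(raw), return_inverse=True)
        return cls(labels=labels.astype(int), K=int(labels.max()) + 1)


def fit_gmm_eee(embeddings: np.ndarray, k: int, seed: int = 0,
                return_model: bool = False):
    """EM fit of a K-component Gaussian mixture with one shared full
    covariance matrix (ridge 1e-6 on the diagonal for stability); labels
    are argmax responsibilities.  K-Means (seeded) initialises EM."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(embeddings, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("embeddings must be finite")
    if k > x.shape[0]:
        raise ValueError(f"K = {k} exceeds number of spots {x.shape[0]}")
    gmm = GaussianMixture(n_components=k, covariance_type="tied",
                          reg_covar=1e-6, random_state=seed, n_init=5,
                          max_iter=300)
    try:
        labels = gmm.fit_predict(x)
    except np.linalg.LinAlgError as err:  # pragma: no cover - rare
        raise RuntimeError(
            "EM failed (singular covariance); increase the regularization "
            "ridge or reduce K") from err
    labeling = Labeling.from_raw(labels)
    return (labeling, gmm) if return_model else labeling


def louvain_cluster(embeddings: np.ndarray, resolution: float = 1.0,
                    seed: int = 0, n_neighbors: int = 15) -> Labeling:
    """Louvain communities of a kNN graph over the embeddings; the number
    of domains emerges from the partition."""
    import igraph
    import random as _pyrandom
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(embeddings, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to cluster")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    edges = np.unique(np.column_stack([lo, hi]), axis=0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges])
    igraph.set_random_number_generator(_pyrandom.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    return Labeling.from_raw(np.asarray(part.membership))


# ---------------------------------------------------------------------------
# metrics

def _check_lengths(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and pred must be 1-D arrays of equal length")
    return truth, pred


def ari(truth, pred) -> float:
    """Adjusted Rand index (pair counting, chance-corrected; in [-1, 1])."""
    from sklearn.metrics import adjusted_rand_score

    truth, pred = _check_lengths(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def nmi(truth, pred) -> float:
    """Mutual information normalised by the arithmetic mean of entropies."""
    from sklearn.metrics import normalized_mutual_info_score

    truth, pred = _check_lengths(truth, pred)
    return float(normalized_mutual_info_score(truth, pred,
                                              average_method="arithmetic"))


def iou_hungarian(truth, pred) -> float:
    """Mean per-domain IoU after Hungarian matching.

    The truth-by-pred overlap matrix is matched to maximise the total
    intersection; each matched pair contributes |∩| / |∪|, unmatched truth
    domains contribute 0, and the mean is over truth domains.
    """
    truth, pred = _check_lengths(truth, pred)
    t_vals, t_inv = np.unique(truth, return_inverse=True)
    p_vals, p_inv = np.unique(pred, return_inverse=True)
    overlap = np.zeros((len(t_vals), len(p_vals)), dtype=np.int64)
    np.add.at(overlap, (t_inv, p_inv), 1)
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    t_sizes = overlap.sum(axis=1)
    p_sizes = overlap.sum(axis=0)
    ious = np.zeros(len(t_vals))
    for r, c in zip(rows, cols):
        inter = overlap[r, c]
        union = t_sizes[r] + p_sizes[c] - inter
        ious[r] = inter / union if union else 0.0
    return float(ious.mean())
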