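"""Spatial adjacency graphs: the radius graph (SAG), its randomly corrupted
contrastive views, and the cell-type-aware kNN graph (ctSAG).

The SAG links two spots when their Euclidean distance is strictly below a
radius r, tuned so the mean neighbour count lands between 5 and 6 — the
connectivity of a hexagonally packed spot array.  Contrastive views prune
SAG edges with a probability that grows as the endpoints' expression
profiles become less similar (low-similarity edges are least informative,
so removing them perturbs the graph while preserving coherent structure).
The ctSAG densifies the spatial graph with k nearest neighbours and then
prunes edges crossing an initial expression-based clustering with high
probability, leaving a graph that mostly respects putative cell types.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = ["SpatialGraph", "CorruptionConfig", "build_sag", "tune_radius",
           "edge_prune_probability", "corrupt_graph", "build_ctsag",
           "expression_louvain"]


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-view pruning strength c_k, truncation probability gamma, and seed.

    The two contrastive views use c_k = 0.05 and 0.1 by default; gamma caps
    any single edge's removal probability at 0.7.
    """

    c_k: float = 0.05
    gamma: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.c_k <= 1.0:
            raise ValueError("c_k must lie in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


class SpatialGraph:
    """Sparse symmetric 0/1 adjacency over spots, stored as an edge list.

    Edges are unordered pairs (i < j); self-edges are never stored — the
    encoder handles the self-contribution through its closed neighbourhood.
    """

    def __init__(self, n_spots: int, edges: np.ndarray, radius: float | None = None):
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            if np.any(lo == hi):
                raise ValueError("self-edges are not allowed")
            edges = np.unique(np.column_stack([lo, hi]), axis=0)
            if edges.max() >= n_spots or edges.min() < 0:
                raise ValueError("edge endpoint out of range")
        else:
            edges = edges.reshape(0, 2)
        self.n_spots = int(n_spots)
        self.edges = edges
        self.radius = radius

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def adjacency(self) -> sp.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges)
        a = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_spots, self.n_spots))
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_spots, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_spots

    def directed_closed(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers, neighbours) for the closed neighbourhood N(i) ∪ {i},
        both directions of every edge plus one self-loop per spot."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        loops = np.arange(self.n_spots, dtype=np.int64)
        centers = np.concatenate([i, j, loops])
        nbrs = np.concatenate([j, i, loops])
        order = np.argsort(centers, kind="stable")
        return centers[order], nbrs[order]

    # ---- I/O -------------------------------------------------------------
    def to_edge_tsv(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t", header="i\tj")

    @classmethod
    def from_edge_tsv(cls, path, n_spots: int) -> "SpatialGraph":
        edges = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
        return cls(n_spots, edges)

    def to_mtx(self, path) -> None:
        import scipy.io
        scipy.io.mmwrite(path, self.adjacency())

    @classmethod
    def from_mtx(cls, path) -> "SpatialGraph":
        import scipy.io
        a = scipy.io.mmread(path).tocoo()
        mask = a.row < a.col
        edges = np.column_stack([a.row[mask], a.col[mask]])
        return cls(a.shape[0], edges)


# ---------------------------------------------------------------------------
# SAG construction

def build_sag(coords: np.ndarray, radius: float) -> SpatialGraph:
    """Radius graph: edge (i, j) iff ||x_i - x_j|| < radius (strict)."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]  # query_pairs uses <=; enforce strict
    return SpatialGraph(coords.shape[0], pairs, radius=radius)


def tune_radius(coords: np.ndarray, target_degree: tuple[float, float] = (5.0, 6.0)
                ) -> float:
    """Find a radius whose mean spot degree falls in `target_degree`.

    Candidate radii are quantiles of the per-spot k-th nearest-neighbour
    distance for k = 5..8 (nudged up so the k-th neighbour, at strictly
    smaller distance, is included).  Returns the first candidate whose mean
    degree lands in the interval; if none does, the closest one, with a
    warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 7:
        raise ValueError("need at least 7 spots to target mean degree 5-6")
    tree = cKDTree(coords)
    kmax = min(8, n - 1)
    # column k of dists = distance to the k-th nearest neighbour
    dists, _ = tree.query(coords, k=kmax + 1)
    if np.allclose(dists[:, 1:], 0):
        raise ValueError("all spots coincident; radius is undefined")
    lo, hi = target_degree
    candidates: list[float] = []
    for k in range(5, kmax + 1):
        dk = dists[:, k]
        for q in np.linspace(0.05, 0.95, 19):
            r = float(np.quantile(dk, q)) * (1.0 + 1e-9)
            if r > 0:
                candidates.append(r)
    best_r, best_gap = None, np.inf
    for r in candidates:
        mean_deg = 2.0 * _count_pairs_strict(tree, coords, r) / n
        if lo <= mean_deg <= hi:
            return r
        gap = max(lo - mean_deg, mean_deg - hi, 0.0)
        if gap < best_gap:
            best_gap, best_r = gap, r
    warnings.warn(f"no candidate radius reaches mean degree in [{lo}, {hi}]; "
                  f"returning closest (gap {best_gap:.2f})")
    return float(best_r)


def _count_pairs_strict(tree: cKDTree, coords: np.ndarray, radius: float) -> int:
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if not pairs.size:
        return 0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return int((d < radius).sum())


# ---------------------------------------------------------------------------
# corrupted views

def edge_prune_probability(sim, sim_max: float, sim_mean: float,
                           c_k: float, gamma: float):
    """Removal probability of an edge given its endpoint cosine similarity.

    p = min(c_k * (sim_max - sim) / (sim_max - sim_mean), gamma): the most
    similar pair is never pruned, an average pair is pruned at the base rate
    c_k, and gamma truncates the probability for very dissimilar pairs.
    When sim_max == sim_mean (all similarities equal) pruning is uniform at
    min(c_k, gamma).
    """
    sim = np.asarray(sim, dtype=float)
    if sim_max < sim_mean:
        raise ValueError("sim_max must be >= sim_mean")
    if sim_max == sim_mean:
        p = np.full_like(sim, min(c_k, gamma))
    else:
        p = np.minimum((sim_max - sim) / (sim_max - sim_mean) * c_k, gamma)
    return p if p.ndim else float(p)


def _edge_cosine(features: np.ndarray, edges: np.ndarray) -> np.ndarray:
    f = np.asarray(features, dtype=float)
    norms = np.linalg.norm(f, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    fn = f / norms[:, None]
    return np.einsum("ij,ij->i", fn[edges[:, 0]], fn[edges[:, 1]])


def corrupt_graph(graph: SpatialGraph, features: np.ndarray,
                  config: CorruptionConfig) -> SpatialGraph:
    """Draw one corrupted view: remove each edge independently with the
    similarity-dependent probability.  Deterministic under config.seed."""
    config.validate()
    features = np.asarray(features, dtype=float)
    if features.shape[0] != graph.n_spots:
        raise ValueError("feature rows do not match graph spot count")
    if graph.n_edges == 0 or config.c_k == 0.0:
        return SpatialGraph(graph.n_spots, graph.edges.copy(), radius=graph.radius)
    sim = _edge_cosine(features, graph.edges)
    p = edge_prune_probability(sim, float(sim.max()), float(sim.mean()),
                               config.c_k, config.gamma)
    rng = np.random.default_rng(config.seed)
    keep = rng.random(graph.n_edges) >= p
    return SpatialGraph(graph.n_spots, graph.edges[keep], radius=graph.radius)


# ---------------------------------------------------------------------------
# ctSAG

def _seeded_igraph_rng(seed: int):
    import igraph
    igraph.set_random_number_generator(_pyrandom.Random(seed))


def expression_louvain(expression: np.ndarray, seed: int = 0,
                       n_pcs: int = 30, n_neighbors: int = 15,
                       resolution: float = 1.0) -> np.ndarray:
    """Initial clustering C: Louvain communities of a kNN graph built over
    the top principal components of the (preprocessed) expression matrix."""
    import igraph
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(expression, dtype=float)
    n = x.shape[0]
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs >= 1:
        x = PCA(n_components=n_pcs, svd_solver="full", random_state=seed
                ).fit_transform(x)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    edges = np.unique(np.column_stack([lo, hi]), axis=0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges])
    _seeded_igraph_rng(seed)
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def build_ctsag(coords: np.ndarray, expression: np.ndarray, k: int = 35,
                theta: float = 0.96, seed: int = 0,
                return_clusters: bool = False):
    """Cell-type-aware spatial graph.

    A union-symmetrised kNN graph over spot coordinates (k neighbours per
    spot) is pruned so that each edge whose endpoints fall in different
    communities of the initial expression clustering is removed with
    probability theta; within-community edges always survive.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the spot count {n}")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    base_edges = np.unique(np.column_stack([lo, hi]), axis=0)

    clusters = expression_louvain(expression, seed=seed)
    cross = clusters[base_edges[:, 0]] != clusters[base_edges[:, 1]]
    rng = np.random.default_rng(seed)
    drop = cross & (rng.random(base_edges.shape[0]) < theta)
    graph = SpatialGraph(n, base_edges[~drop])
    if return_clusters:
        return graph, clusters, SpatialGraph(n, base_edges)
    return graph
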