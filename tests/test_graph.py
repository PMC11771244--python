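"""Spatial graph construction, corrupted views, and the ctSAG."""

import numpy as np
import pytest

from stcluster.graph import (CorruptionConfig, SpatialGraph, build_ctsag,
                             build_sag, corrupt_graph, edge_prune_probability,
                             tune_radius)
from stcluster.synthetic import hex_grid_coords


def brute_force_edges(coords, radius):
    n = len(coords)
    return {(i, j) for i in range(n) for j in range(i + 1, n)
            if np.linalg.norm(coords[i] - coords[j]) < radius}


class TestBuildSag:
    def test_collinear_spots(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        g = build_sag(coords, 1.5)
        assert g.edge_set() == {(0, 1), (1, 2)}

    def test_radius_below_minimum_distance_gives_empty_graph(self):
        coords = np.array([[0.0, 0], [2, 0], [0, 2]])
        assert build_sag(coords, 1.0).n_edges == 0

    def test_strict_inequality_at_exact_distance(self):
        coords = np.array([[0.0, 0], [1, 0]])
        assert build_sag(coords, 1.0).n_edges == 0
        assert build_sag(coords, 1.0 + 1e-9).n_edges == 1

    def test_matches_brute_force_on_grid(self):
        xx, yy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        g = build_sag(coords, 1.5)
        assert g.edge_set() == brute_force_edges(coords, 1.5)

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            coords = rng.uniform(0, 20, size=(500, 2))
            radius = rng.uniform(0.5, 2.5)
            g = build_sag(coords, radius)
            assert g.edge_set() == brute_force_edges(coords, radius)

    def test_symmetric_adjacency_no_self_loops(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 5, size=(40, 2))
        a = build_sag(coords, 1.0).adjacency().todense()
        assert np.all(a == a.T)
        assert np.all(np.diag(a) == 0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            build_sag(np.array([[0.0, 0], [np.nan, 1]]), 1.0)


class TestTuneRadius:
    def test_hex_grid_reaches_target_band(self):
        coords = hex_grid_coords(20, 20)
        r = tune_radius(coords)
        # verify with the O(n^2) oracle, not the package's own counting
        n = len(coords)
        deg = 2 * len(brute_force_edges(coords, r)) / n
        assert 5.0 <= deg <= 6.0

    def test_seven_spot_cluster_reaches_target_band(self):
        # complete graph on 7 nodes has degree 6, so [5, 6] is attainable
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 0.1, size=(7, 2))
        r = tune_radius(coords)
        deg = build_sag(coords, r).mean_degree()
        assert 5.0 <= deg <= 6.0

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError):
            tune_radius(np.array([[0.0, 0], [1, 0]]))

    def test_coincident_spots_rejected(self):
        with pytest.raises(ValueError):
            tune_radius(np.zeros((10, 2)))

    def test_square_lattice_falls_back_with_warning(self):
        # on a unit square lattice the attainable mean degrees jump from
        # ~3.8 to ~7.4, so the target band is unreachable and the closest
        # radius is returned with a warning
        xx, yy = np.meshgrid(np.arange(20.0), np.arange(20.0))
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        with pytest.warns(UserWarning, match="mean degree"):
            tune_radius(coords)


class TestPruneProbability:
    def test_most_similar_edge_never_pruned(self):
        assert edge_prune_probability(0.9, 0.9, 0.5, 0.05, 0.7) == 0.0

    def test_average_edge_pruned_at_base_rate(self):
        assert edge_prune_probability(0.5, 0.9, 0.5, 0.05, 0.7) \
            == pytest.approx(0.05)
        assert edge_prune_probability(0.5, 0.9, 0.5, 0.1, 0.7) \
            == pytest.approx(0.1)

    def test_truncation_at_gamma(self):
        # unclipped value (0.9 - 0.0)/(0.9 - 0.8) * 0.1 = 0.9 -> clipped to 0.7
        assert edge_prune_probability(0.0, 0.9, 0.8, 0.1, 0.7) \
            == pytest.approx(0.7)

    def test_degenerate_similarities_prune_uniformly(self):
        assert edge_prune_probability(0.5, 0.5, 0.5, 0.05, 0.7) \
            == pytest.approx(0.05)
        assert edge_prune_probability(0.5, 0.5, 0.5, 0.9, 0.7) \
            == pytest.approx(0.7)

    def test_monotone_nonincreasing_in_similarity(self):
        sims = np.linspace(-1, 1, 50)
        p = edge_prune_probability(sims, 1.0, 0.2, 0.1, 0.7)
        assert np.all(np.diff(p) <= 1e-12)
        assert np.all((p >= 0) & (p <= 0.7))


class TestCorruptGraph:
    @pytest.fixture
    def grid_graph(self):
        xx, yy = np.meshgrid(np.arange(12.0), np.arange(12.0))
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(len(coords), 8))
        return build_sag(coords, 1.5), feats

    def test_zero_base_rate_keeps_graph(self, grid_graph):
        g, feats = grid_graph
        out = corrupt_graph(g, feats, CorruptionConfig(c_k=0.0, seed=0))
        assert out.edge_set() == g.edge_set()

    def test_certain_pruning_removes_all_edges(self):
        # all similarities equal -> degenerate rule at min(c_k, gamma) = 1
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        g = build_sag(coords, 1.5)
        feats = np.ones((4, 5))
        out = corrupt_graph(g, feats, CorruptionConfig(c_k=1.0, gamma=1.0, seed=0))
        assert out.n_edges == 0

    def test_view_is_edge_subset(self, grid_graph):
        g, feats = grid_graph
        out = corrupt_graph(g, feats, CorruptionConfig(c_k=0.3, seed=1))
        assert out.edge_set() <= g.edge_set()
        assert out.n_spots == g.n_spots

    def test_deterministic_under_seed(self, grid_graph):
        g, feats = grid_graph
        a = corrupt_graph(g, feats, CorruptionConfig(c_k=0.2, seed=42))
        b = corrupt_graph(g, feats, CorruptionConfig(c_k=0.2, seed=42))
        assert a.edge_set() == b.edge_set()

    def test_removed_count_matches_binomial_sum(self):
        # mean removals over repeats within 3 sigma of sum(c_ij)
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 40, size=(700, 2))
        g = build_sag(coords, 2.0)
        assert g.n_edges >= 1000
        feats = rng.normal(size=(700, 10))
        from stcluster.graph import _edge_cosine
        sim = _edge_cosine(feats, g.edges)
        p = edge_prune_probability(sim, sim.max(), sim.mean(), 0.1, 0.7)
        expected = p.sum()
        sigma = np.sqrt((p * (1 - p)).sum())
        reps = 200
        removed = np.mean([
            g.n_edges - corrupt_graph(g, feats,
                                      CorruptionConfig(0.1, 0.7, seed=s)).n_edges
            for s in range(reps)])
        assert abs(removed - expected) < 3 * sigma / np.sqrt(reps)

    def test_size_mismatch_rejected(self, grid_graph):
        g, feats = grid_graph
        with pytest.raises(ValueError):
            corrupt_graph(g, feats[:-1], CorruptionConfig(seed=0))


class TestCtsag:
    @pytest.fixture
    def two_cluster_data(self):
        # two spatial halves with very different expression programs
        rng = np.random.default_rng(5)
        n_half = 60
        coords = np.vstack([rng.uniform(0, 5, size=(n_half, 2)),
                            rng.uniform(0, 5, size=(n_half, 2)) + [10, 0]])
        expr = np.vstack([rng.normal(0, 1, size=(n_half, 20)),
                          rng.normal(8, 1, size=(n_half, 20))])
        return coords, expr

    def test_theta_zero_keeps_knn_graph(self, two_cluster_data):
        coords, expr = two_cluster_data
        g, clusters, base = build_ctsag(coords, expr, k=10, theta=0.0, seed=0,
                                        return_clusters=True)
        assert g.edge_set() == base.edge_set()

    def test_theta_one_removes_all_cross_cluster_edges(self, two_cluster_data):
        coords, expr = two_cluster_data
        g, clusters, base = build_ctsag(coords, expr, k=10, theta=1.0, seed=0,
                                        return_clusters=True)
        cross = clusters[g.edges[:, 0]] != clusters[g.edges[:, 1]]
        assert not np.any(cross)

    def test_subset_of_base_knn_graph(self, two_cluster_data):
        coords, expr = two_cluster_data
        g, _, base = build_ctsag(coords, expr, k=10, theta=0.96, seed=0,
                                 return_clusters=True)
        assert g.edge_set() <= base.edge_set()

    def test_cross_edge_survival_rate_binomial(self):
        # strong 2-band tissue: surviving cross-cluster edges ~ Binomial(m, 1-theta)
        from stcluster.synthetic import TissueSpec, generate_dataset
        from stcluster.preprocess import normalize_log_scale
        spec = TissueSpec(n_rows=16, n_cols=16, n_domains=2, n_genes=40,
                          markers_per_domain=15, effect_size=8.0,
                          base_mean=10.0, dispersion=0.1, dropout_rate=0.0,
                          seed=6)
        ds = normalize_log_scale(generate_dataset(spec))
        theta = 0.9
        survived = []
        total_cross = None
        for seed in range(40):
            g, clusters, base = build_ctsag(ds.coords, ds.dense(), k=12,
                                            theta=theta, seed=seed,
                                            return_clusters=True)
            cross_base = clusters[base.edges[:, 0]] != clusters[base.edges[:, 1]]
            cross_kept = clusters[g.edges[:, 0]] != clusters[g.edges[:, 1]]
            survived.append(cross_kept.sum())
            total_cross = cross_base.sum()
        m = total_cross
        mean_surv = np.mean(survived)
        expect = m * (1 - theta)
        sigma = np.sqrt(m * theta * (1 - theta))
        assert abs(mean_surv - expect) < 3 * sigma / np.sqrt(len(survived))

    def test_k_too_large_rejected(self):
        coords = np.random.default_rng(7).uniform(0, 5, size=(10, 2))
        with pytest.raises(ValueError):
            build_ctsag(coords, np.ones((10, 4)), k=10, seed=0)

    def test_deterministic_under_seed(self, two_cluster_data):
        coords, expr = two_cluster_data
        a = build_ctsag(coords, expr, k=10, theta=0.96, seed=3)
        b = build_ctsag(coords, expr, k=10, theta=0.96, seed=3)
        assert a.edge_set() == b.edge_set()


class TestGraphContainer:
    def test_rejects_self_edges_and_out_of_range(self):
        with pytest.raises(ValueError):
            SpatialGraph(3, np.array([[1, 1]]))
        with pytest.raises(ValueError):
            SpatialGraph(3, np.array([[0, 5]]))

    def test_edge_tsv_roundtrip(self, tmp_path):
        g = SpatialGraph(5, np.array([[0, 1], [2, 4], [1, 3]]))
        path = tmp_path / "edges.tsv"
        g.to_edge_tsv(path)
        back = SpatialGraph.from_edge_tsv(path, 5)
        assert back.edge_set() == g.edge_set()

    def test_mtx_roundtrip(self, tmp_path):
        g = SpatialGraph(6, np.array([[0, 1], [2, 4], [1, 3], [4, 5]]))
        path = tmp_path / "adj.mtx"
        g.to_mtx(path)
        back = SpatialGraph.from_mtx(path)
        assert back.edge_set() == g.edge_set()
        assert back.n_spots == 6
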