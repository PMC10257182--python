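"""Diversity QC: distances, graph construction, clustering sweeps.

Oracles: MST totals against exhaustive spanning-tree enumeration, ARI
against the brute-force contingency-table formula, Tanimoto/cosine against
hand computation.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from senoscreen import (
    adjusted_rand_index,
    build_diversity_graph,
    continuous_tanimoto_distance,
    cosine_distance,
    detect_plateaus,
    graph_edge_summary,
    kmeans_diversity_curve,
    louvain_sweep,
    tanimoto_distance_matrix,
)
from senoscreen.diversity import SweepResult, export_edge_list


class TestCosineDistance:
    @pytest.mark.parametrize("u,v,expected", [
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([1.0, 0.0], [1.0, 1.0], 1.0 - 1.0 / math.sqrt(2)),  # hand computed
        ([1.0, 0.0], [-1.0, 0.0], 2.0),
    ])
    def test_known_values(self, u, v, expected):
        assert cosine_distance(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestContinuousTanimoto:
    @pytest.mark.parametrize("u,v,expected", [
        ([2.0, 1.0], [2.0, 1.0], 0.0),            # identical
        ([1.0, 0.0], [0.0, 1.0], 1.0),            # disjoint support
        ([1.0, 1.0], [1.0, 0.0], 0.5),            # 1 - 1/(2+1-1), hand computed
        ([0.0, 0.0], [0.0, 0.0], 0.0),            # all-zero convention
    ])
    def test_known_values(self, u, v, expected):
        assert continuous_tanimoto_distance(u, v) == pytest.approx(expected)

    def test_symmetry_range_and_identity(self, rng):
        for _ in range(50):
            u = rng.random(6)
            v = rng.random(6)
            d_uv = continuous_tanimoto_distance(u, v)
            assert d_uv == pytest.approx(continuous_tanimoto_distance(v, u))
            assert 0.0 <= d_uv <= 1.0
        assert continuous_tanimoto_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_matrix_agrees_with_scalar(self, rng):
        X = rng.random((8, 5))
        D = tanimoto_distance_matrix(X)
        for i, j in itertools.combinations(range(8), 2):
            assert D[i, j] == pytest.approx(
                continuous_tanimoto_distance(X[i], X[j]), abs=1e-12)


def _brute_force_ari(a, b):
    """Contingency-table ARI from its defining formula."""
    a, b = list(a), list(b)
    n = len(a)
    ca, cb = sorted(set(a)), sorted(set(b))
    nij = np.array([[sum(1 for x, y in zip(a, b) if x == i and y == j)
                     for j in cb] for i in ca])
    comb2 = lambda m: m * (m - 1) // 2
    index = sum(comb2(v) for v in nij.flat)
    sum_a = sum(comb2(v) for v in nij.sum(axis=1))
    sum_b = sum(comb2(v) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if index == expected else 0.0
    return (index - expected) / (max_index - expected)


def _set_partitions(n):
    """All set partitions of range(n), as label vectors."""
    if n == 0:
        yield []
        return
    for part in _set_partitions(n - 1):
        k = max(part, default=-1) + 1
        for lbl in range(k + 1):
            yield part + [lbl]


class TestARI:
    def test_identical_labellings(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_single_cluster_degenerate(self):
        assert adjusted_rand_index([0, 0, 0, 0], [1, 2, 1, 2]) == 0.0

    def test_hand_computed_negative_case(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_matches_brute_force_on_all_partitions_of_5(self):
        parts = list(_set_partitions(5))
        assert len(parts) == 52  # Bell(5)
        for a in parts:
            for b in parts:
                assert adjusted_rand_index(a, b) == pytest.approx(
                    _brute_force_ari(a, b), abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 4, size=30)
        b = rng.integers(0, 4, size=30)
        remap = {0: 7, 1: 3, 2: 9, 3: 0}
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index([remap[x] for x in a], b))

    def test_random_labellings_mean_near_zero(self, rng):
        vals = []
        for _ in range(1000):
            vals.append(adjusted_rand_index(rng.integers(0, 3, 40),
                                            rng.integers(0, 3, 40)))
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            adjusted_rand_index([1, 2], [1, 2, 3])


def _brute_force_mst_weight(D):
    """Minimum spanning-tree weight by enumeration over all spanning trees."""
    n = D.shape[0]
    nodes = range(n)
    all_edges = list(itertools.combinations(nodes, 2))
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = min(best, sum(D[i, j] for i, j in subset))
    return best


class TestDiversityGraph:
    def test_small_n_saturates_to_complete_graph(self, rng):
        X = rng.random((3, 4))
        g = build_diversity_graph(X, ["a", "b", "c"], k=7)
        assert g.number_of_edges() == 3

    def test_collinear_points_give_path_graph(self):
        # 10 points at 1..10 on one feature: MST is the chain, 1-NN adds nothing
        X = np.arange(1.0, 11.0).reshape(-1, 1)
        ids = [f"p{i}" for i in range(10)]
        g = build_diversity_graph(X, ids, k=1)
        assert g.number_of_edges() == 9
        degrees = sorted(d for _, d in g.degree)
        assert degrees == [1, 1] + [2] * 8

    def test_mst_weight_matches_exhaustive_enumeration(self, rng):
        for trial in range(6):
            n = int(rng.integers(4, 7))
            X = rng.random((n, 3))
            D = tanimoto_distance_matrix(X)
            ids = [f"c{i}" for i in range(n)]
            complete = nx.Graph()
            for i, j in itertools.combinations(range(n), 2):
                complete.add_edge(ids[i], ids[j], weight=D[i, j])
            mst = nx.minimum_spanning_tree(complete)
            total = sum(d["weight"] for _, _, d in mst.edges(data=True))
            assert total == pytest.approx(_brute_force_mst_weight(D), abs=1e-9)

    def test_connected_for_any_input(self, rng):
        X = rng.random((25, 6))
        g = build_diversity_graph(X, [f"c{i}" for i in range(25)], k=2)
        assert nx.is_connected(g)
        assert not any(a == b for a, b in g.edges)  # no self-loops

    def test_union_superset_of_intersection(self, rng):
        X = rng.random((15, 4))
        ids = [f"c{i}" for i in range(15)]
        g_u = build_diversity_graph(X, ids, k=3, combine="union")
        g_i = build_diversity_graph(X, ids, k=3, combine="intersection")
        assert set(map(frozenset, g_i.edges)) <= set(map(frozenset, g_u.edges))

    def test_k_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            build_diversity_graph(rng.random((4, 2)), list("abcd"), k=0)


class TestEdgeSummary:
    def test_triangle_median(self):
        g = nx.Graph()
        g.add_edge("a", "b", distance=0.1)
        g.add_edge("b", "c", distance=0.2)
        g.add_edge("a", "c", distance=0.3)
        summary = graph_edge_summary(g)
        assert summary["n_edges"] == 3
        assert summary["median_distance"] == pytest.approx(0.2)

    def test_single_edge_median_is_weight(self):
        g = nx.Graph()
        g.add_edge("a", "b", distance=0.77)
        assert graph_edge_summary(g)["median_distance"] == pytest.approx(0.77)

    def test_even_count_midpoint_convention(self):
        g = nx.Graph()
        for pair, d in [("ab", 0.1), ("bc", 0.2), ("cd", 0.4), ("da", 0.8)]:
            g.add_edge(*pair, distance=d)
        assert graph_edge_summary(g)["median_distance"] == pytest.approx(0.3)


class TestKMeansCurve:
    def test_two_separated_blobs(self, rng):
        a = rng.normal([5, 0, 0], 0.05, size=(10, 3))
        b = rng.normal([0, 5, 0], 0.05, size=(10, 3))
        X = np.vstack([a, b])
        curve = kmeans_diversity_curve(X, [1, 2, 3], repeats=10, seed=0)
        assert curve.silhouette_mean[1] > 0.9
        drop_12 = curve.score_mean[0] - curve.score_mean[1]
        drop_23 = curve.score_mean[1] - curve.score_mean[2]
        assert drop_12 > 10 * max(drop_23, 1e-12)

    def test_identical_points_score_zero(self):
        X = np.ones((12, 3))
        curve = kmeans_diversity_curve(X, [1, 2], repeats=3, seed=0)
        np.testing.assert_allclose(curve.score_mean, 0.0, atol=1e-9)

    def test_isotropic_gaussian_has_low_silhouette(self, rng):
        X = rng.normal(size=(60, 8))
        curve = kmeans_diversity_curve(X, [2, 3, 4], repeats=5, seed=0)
        assert np.nanmax(curve.silhouette_mean) < 0.3

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_diversity_curve(rng.random((5, 2)), [6], repeats=2, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.random((20, 4)) + 0.1
        c1 = kmeans_diversity_curve(X, [2, 3], repeats=5, seed=9)
        c2 = kmeans_diversity_curve(X, [2, 3], repeats=5, seed=9)
        np.testing.assert_array_equal(c1.score_mean, c2.score_mean)


def _two_cliques(n=5, weak=0.05):
    g = nx.Graph()
    for block, offset in (("a", 0), ("b", n)):
        for i, j in itertools.combinations(range(n), 2):
            g.add_edge(f"{block}{i}", f"{block}{j}", similarity=1.0, distance=0.0)
    g.add_edge("a0", "b0", similarity=weak, distance=1 - weak)
    return g


class TestLouvain:
    def test_two_cliques_resolve_to_two_communities(self):
        g = _two_cliques()
        sweep = louvain_sweep(g, [1.0], runs=20, seed=0)
        assert sweep.n_clusters_mean[0] == 2.0
        assert sweep.n_clusters_sd[0] == 0.0

    def test_single_node_graph(self):
        g = nx.Graph()
        g.add_node("only")
        sweep = louvain_sweep(g, [0.5, 1.0, 2.0], runs=3, seed=0)
        np.testing.assert_array_equal(sweep.n_clusters_mean, 1.0)

    def test_reference_equal_to_found_partition_gives_ari_1(self):
        g = _two_cliques()
        ref = {v: v[0] for v in g.nodes}  # the two cliques
        sweep = louvain_sweep(g, [1.0], runs=10, seed=0, reference_labels=ref)
        assert sweep.ari_mean[0] == pytest.approx(1.0)

    def test_gamma_to_zero_recovers_connected_components(self):
        g = _two_cliques()
        g.remove_edge("a0", "b0")  # two components now
        sweep = louvain_sweep(g, [1e-6], runs=5, seed=0)
        assert sweep.n_clusters_mean[0] == 2.0

    def test_empty_gamma_grid_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            louvain_sweep(_two_cliques(), [], runs=2, seed=0)


class TestPlateaus:
    def test_linear_curve_has_no_wide_plateau(self):
        gg = np.arange(0.0, 2.0, 0.1)
        # the count rises by one per grid step, so no rounded value persists
        sweep = SweepResult(gg, n_clusters_mean=1 + 10 * gg,
                            n_clusters_sd=np.zeros_like(gg))
        assert detect_plateaus(sweep, min_width=0.25) == []

    def test_constant_stretch_detected(self):
        gg = np.arange(0.0, 1.01, 0.1)
        counts = np.array([2, 3, 5, 5, 5, 5, 5, 7, 8, 9, 10], dtype=float)
        sweep = SweepResult(gg, counts, np.zeros_like(gg))
        plateaus = detect_plateaus(sweep, min_width=0.3)
        assert len(plateaus) == 1
        assert plateaus[0]["n_clusters"] == 5
        assert plateaus[0]["gamma_lo"] == pytest.approx(0.2)
        assert plateaus[0]["gamma_hi"] == pytest.approx(0.6)

    def test_planted_five_community_graph_shows_plateau_at_five(self, rng):
        # 5 tight communities, loose between-community edges
        g = nx.Graph()
        for c in range(5):
            members = [f"c{c}_{i}" for i in range(6)]
            for a, b in itertools.combinations(members, 2):
                g.add_edge(a, b, similarity=0.9, distance=0.1)
        for c in range(5):
            g.add_edge(f"c{c}_0", f"c{(c + 1) % 5}_0", similarity=0.05, distance=0.95)
        grid = np.arange(0.4, 1.65, 0.1)
        sweep = louvain_sweep(g, grid, runs=10, seed=1)
        plateaus = detect_plateaus(sweep, min_width=0.2)
        fives = [p for p in plateaus if p["n_clusters"] == 5]
        assert fives, f"no 5-community plateau in {plateaus}"
        assert fives[0]["gamma_hi"] - fives[0]["gamma_lo"] >= 0.2


def test_edge_list_export(tmp_path, rng):
    X = rng.random((6, 3))
    g = build_diversity_graph(X, [f"c{i}" for i in range(6)], k=2)
    path = tmp_path / "edges.csv"
    export_edge_list(g, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source,target,distance"
    assert len(lines) == g.number_of_edges() + 1
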