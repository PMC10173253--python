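"""Graph generators against brute-force oracles and hand-checked cases."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom

from proximap import (
    PointCloud,
    RuleConfig,
    acceptance_curve,
    build_epsilon_ball_graph,
    build_knn_graph,
    build_stochastic_graph,
    build_voronoi_graph,
    default_rules,
    giant_component,
    neighbor_frequency,
)
from proximap.graphs import ParameterError, ProximityGraph, calibrate_scale


def edge_set(graph: ProximityGraph) -> set:
    return {tuple(e) for e in graph.edges}


def brute_force_knn_edges(coords: np.ndarray, k: int) -> set:
    """O(N^2) union-symmetrised kNN: sort all pair distances per node."""
    n = len(coords)
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    edges = set()
    for i in range(n):
        for j in np.argsort(d[i], kind="stable")[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


class TestKnnGraph:
    def test_collinear_hand_example(self):
        pts = PointCloud([0, 1, 2], [[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        g = build_knn_graph(pts, k=1)
        assert edge_set(g) == {(0, 1), (1, 2)}

    def test_inverse_distance_weights(self):
        pts = PointCloud([0, 1, 2], [[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        g = build_knn_graph(pts, k=1, weighted=True)
        w = {tuple(e): wt for e, wt in zip(map(tuple, g.edges), g.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)
        assert w[(1, 2)] == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [1, 4, 7])
    def test_matches_brute_force(self, cloud_2d_200, k):
        g = build_knn_graph(cloud_2d_200, k=k)
        assert edge_set(g) == brute_force_knn_edges(cloud_2d_200.coordinates, k)

    def test_matches_brute_force_3d(self, cloud_3d_200):
        g = build_knn_graph(cloud_3d_200, k=5)
        assert edge_set(g) == brute_force_knn_edges(cloud_3d_200.coordinates, 5)

    def test_k_too_large(self, cloud_2d_small):
        with pytest.raises(ParameterError, match="k"):
            build_knn_graph(cloud_2d_small, k=20)

    def test_duplicate_coordinates_tie_break_by_id(self):
        # two coincident candidates: the smaller ID must win the single slot
        pts = PointCloud([0, 1, 2], [[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        g = build_knn_graph(pts, k=1)
        # node 0 nominates node 1 (tie with 2 broken by ID); 1 and 2 nominate
        # each other (distance 0)
        assert (0, 1) in edge_set(g) and (1, 2) in edge_set(g)
        assert (0, 2) not in edge_set(g)


class TestEpsilonBallGraph:
    def test_boundary_is_closed(self):
        pts = PointCloud([0, 1], [[0.0, 0.0], [1.0, 0.0]])
        g = build_epsilon_ball_graph(pts, epsilon=1.0)
        assert edge_set(g) == {(0, 1)}

    def test_subcritical_epsilon_empty(self, cloud_2d_small):
        dmin = pdist(cloud_2d_small.coordinates).min()
        g = build_epsilon_ball_graph(cloud_2d_small, epsilon=dmin * 0.99)
        assert g.n_edges == 0

    def test_matches_brute_force(self, cloud_2d_200):
        eps = 0.12
        g = build_epsilon_ball_graph(cloud_2d_200, eps)
        d = squareform(pdist(cloud_2d_200.coordinates))
        expected = {
            (i, j)
            for i in range(200)
            for j in range(i + 1, 200)
            if d[i, j] <= eps
        }
        assert edge_set(g) == expected


class TestVoronoiGraph:
    def test_triangle_is_complete(self):
        pts = PointCloud([0, 1, 2], [[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
        g = build_voronoi_graph(pts)
        assert edge_set(g) == {(0, 1), (0, 2), (1, 2)}

    def test_unit_square_has_five_edges(self):
        # 4 sides + exactly one diagonal; both diagonals cannot coexist
        pts = PointCloud([0, 1, 2, 3], [[0, 0], [1, 0], [1, 1], [0, 1]])
        g = build_voronoi_graph(pts)
        assert g.n_edges == 5
        sides = {(0, 1), (1, 2), (2, 3), (0, 3)}
        assert sides <= edge_set(g)
        diagonals = edge_set(g) - sides
        assert diagonals in ({(0, 2)}, {(1, 3)})

    def test_matches_empty_circumcircle_oracle(self):
        # Delaunay edge iff some circumcircle through the pair is point-free;
        # brute force over all point triples on a small cloud
        rng = np.random.default_rng(3)
        coords = rng.random((12, 2))
        pts = PointCloud(np.arange(12), coords)
        g = build_voronoi_graph(pts)
        from itertools import combinations

        def circumcircle(a, b, c):
            ax, ay = a; bx, by = b; cx, cy = c
            d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
            if abs(d) < 1e-14:
                return None, None
            ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                  + (cx**2 + cy**2) * (ay - by)) / d
            uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                  + (cx**2 + cy**2) * (bx - ax)) / d
            center = np.array([ux, uy])
            return center, np.linalg.norm(a - center)

        expected = set()
        for i, j in combinations(range(12), 2):
            for k in range(12):
                if k in (i, j):
                    continue
                center, radius = circumcircle(coords[i], coords[j], coords[k])
                if center is None:
                    continue
                dists = np.linalg.norm(coords - center, axis=1)
                others = np.delete(dists, [i, j, k])
                if np.all(others > radius - 1e-12):
                    expected.add((i, j))
                    break
        assert edge_set(g) == expected

    def test_3d_mean_degree_near_fifteen(self):
        from proximap import SceneConfig, generate_scene

        cloud = generate_scene(SceneConfig(3, 1000, seed=2))
        g = build_voronoi_graph(cloud)
        assert abs(g.mean_degree - 15) <= 2

    def test_degenerate_input_jittered(self):
        pts = PointCloud(np.arange(5), np.column_stack([np.arange(5.0), np.zeros(5)]))
        with pytest.warns(UserWarning, match="jitter"):
            g = build_voronoi_graph(pts)
        assert g.n_edges >= 4


class TestStochasticGraph:
    def test_certain_acceptance_gives_complete_graph(self, cloud_2d_small):
        cfg = RuleConfig("random_rule", acceptance_fn=lambda d: np.ones_like(d))
        g = build_stochastic_graph(cloud_2d_small, cfg)
        n = cloud_2d_small.n_points
        assert g.n_edges == n * (n - 1) // 2

    def test_zero_acceptance_gives_empty_graph(self, cloud_2d_small):
        cfg = RuleConfig("random_rule", acceptance_fn=lambda d: np.zeros_like(d))
        g = build_stochastic_graph(cloud_2d_small, cfg)
        assert g.n_edges == 0

    def test_acceptance_outside_unit_interval_rejected(self, cloud_2d_small):
        cfg = RuleConfig("random_rule", acceptance_fn=lambda d: 2 * np.ones_like(d))
        with pytest.raises(ParameterError, match=r"\[0, 1\]"):
            build_stochastic_graph(cloud_2d_small, cfg)

    def test_seed_determinism(self, cloud_2d_200):
        cfg = RuleConfig("decaying", decay_scale=0.05, seed=9)
        a = build_stochastic_graph(cloud_2d_200, cfg)
        b = build_stochastic_graph(cloud_2d_200, cfg)
        assert np.array_equal(a.edges, b.edges)

    def test_decaying_rule_matches_closed_form(self):
        # binned empirical acceptance within 99% binomial CIs of exp(-d/lam)
        from proximap import SceneConfig, generate_scene

        cloud = generate_scene(SceneConfig(2, 500, seed=4))
        lam = 0.08
        g = build_stochastic_graph(
            cloud, RuleConfig("decaying", decay_scale=lam, seed=12)
        )
        d = pdist(cloud.coordinates)
        has_edge = np.zeros(len(d), dtype=bool)
        n = 500
        for i, j in g.edges:
            has_edge[n * i - i * (i + 1) // 2 + (j - i - 1)] = True
        bins = np.linspace(0, 3 * lam, 10)
        which = np.digitize(d, bins) - 1
        for b in range(9):
            mask = which == b
            trials = mask.sum()
            if trials < 50:
                continue
            k = has_edge[mask].sum()
            mid = 0.5 * (bins[b] + bins[b + 1])
            p = np.exp(-mid / lam)
            lo, hi = binom.ppf([0.005, 0.995], trials, p)
            assert lo <= k <= hi, f"bin {b}: {k} outside [{lo}, {hi}]"


class TestGiantComponent:
    def test_connected_graph_unchanged(self, cloud_2d_200):
        g = build_knn_graph(cloud_2d_200, k=6)
        sub, retained = giant_component(g)
        assert retained == 1.0
        assert edge_set(sub) == edge_set(g)

    def test_two_triangles_tie_broken_by_min_id(self):
        g = ProximityGraph(
            np.arange(6),
            [[0, 1], [1, 2], [0, 2], [3, 4], [4, 5], [3, 5]],
        )
        sub, retained = giant_component(g)
        assert retained == 0.5
        assert set(sub.node_ids.tolist()) == {0, 1, 2}

    def test_matches_networkx_components(self, cloud_2d_200):
        import networkx as nx

        g = build_epsilon_ball_graph(cloud_2d_200, epsilon=0.05)  # subcritical
        sub, retained = giant_component(g)
        assert retained < 1.0
        comps = list(nx.connected_components(g.to_networkx()))
        biggest = max(comps, key=len)
        assert retained == pytest.approx(len(biggest) / 200)
        assert set(sub.node_ids.tolist()) == biggest


class TestDiagnostics:
    def test_epsilon_acceptance_curve_is_step(self, cloud_2d_200):
        eps = 0.15
        g = build_epsilon_ball_graph(cloud_2d_200, eps)
        curve = acceptance_curve(cloud_2d_200, g, n_bins=40)
        below = curve[curve.distance_bin < eps - 0.01]
        above = curve[curve.distance_bin > eps + 0.01]
        assert np.allclose(below.edge_probability, 1.0)
        assert np.allclose(above.edge_probability, 0.0)

    def test_complete_graph_probability_one(self, cloud_2d_small):
        cfg = RuleConfig("random_rule", acceptance_fn=lambda d: np.ones_like(d))
        g = build_stochastic_graph(cloud_2d_small, cfg)
        curve = acceptance_curve(cloud_2d_small, g, n_bins=10)
        assert np.allclose(curve.edge_probability, 1.0)

    def test_neighbor_frequency_normalised(self, cloud_2d_200):
        g = build_knn_graph(cloud_2d_200, k=5)
        freq = neighbor_frequency(cloud_2d_200, g, n_bins=20)
        assert freq.normalized_count.sum() == pytest.approx(1.0)

    def test_single_edge_mass_in_one_bin(self):
        pts = PointCloud([0, 1, 2], [[0, 0], [0.5, 0], [0, 0.9]])
        g = ProximityGraph([0, 1, 2], [[0, 1]])
        freq = neighbor_frequency(pts, g, n_bins=5)
        assert (freq.normalized_count > 0).sum() == 1

    def test_rules_have_distinct_length_distributions(self, cloud_2d_200):
        gk = build_knn_graph(cloud_2d_200, k=12)
        ge = build_epsilon_ball_graph(cloud_2d_200, 0.15)
        fk = neighbor_frequency(cloud_2d_200, gk, n_bins=15)
        fe = neighbor_frequency(cloud_2d_200, ge, n_bins=15)
        assert not np.allclose(fk.normalized_count, fe.normalized_count, atol=0.02)


class TestDefaultRules:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_seven_rules_with_calibrated_degree(self, dim):
        from proximap import SceneConfig, generate_scene

        n = 1000
        cloud = generate_scene(SceneConfig(dim, n, seed=6))
        rules = default_rules(dim, n, seed=1)
        assert len(rules) == 7
        from proximap import build_graph

        for rule in rules:
            g = build_graph(cloud, rule)
            if rule.rule_kind == "voronoi":
                continue  # parameter-free; 2D Delaunay degree is ~6
            # bulk calibration, minus boundary losses
            assert 8 <= g.mean_degree <= 20, rule.label

    def test_symmetry_of_every_rule(self, cloud_2d_200):
        from proximap import build_graph

        for rule in default_rules(2, 200, include_weighted=True):
            adj = build_graph(cloud_2d_200, rule).to_csr()
            assert (adj != adj.T).nnz == 0, rule.label


class TestRuleConfigValidation:
    def test_missing_parameter_rejected(self):
        with pytest.raises(ParameterError, match="requires exactly"):
            RuleConfig("knn")

    def test_extra_parameter_rejected(self):
        with pytest.raises(ParameterError, match="requires exactly"):
            RuleConfig("voronoi", k=5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError, match="rule_kind"):
            RuleConfig("gabriel")
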