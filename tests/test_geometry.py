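import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import networkx as nx

from famgeo.geometry import (
    Curve,
    GeodesicConfig,
    GridConfig,
    curve_energy,
    entropy_grid,
    expected_hamming,
    expected_sq_distance,
    geodesic,
    grid_path_cost,
    refine_geodesic,
    sample_sequences,
    shortest_grid_path,
    _energy_and_grad,
    _resample_polyline,
)
from conftest import constant_model, far_entropy_params


def random_simplex_rows(rng, L, C):
    p = rng.gamma(1.0, size=(L, C))
    return p / p.sum(axis=1, keepdims=True)


def mc_expected_sq_distance(a, b, n, rng):
    sa = sample_sequences(a, n, rng)
    sb = sample_sequences(b, n, rng)
    return 2.0 * (sa != sb).sum(axis=1).mean(), 2.0 * (sa != sb).sum(axis=1).std() / np.sqrt(n)


class TestExpectedSqDistance:
    def test_identical_onehot_zero_and_disjoint_two(self):
        e = np.eye(4)
        assert expected_sq_distance(e[[0]], e[[0]]) == 0.0
        assert expected_sq_distance(e[[0]], e[[1]]) == 2.0

    def test_uniform_c4_l2_closed_form(self):
        a = np.full((2, 4), 0.25)
        assert expected_sq_distance(a, a) == pytest.approx(3.0, rel=1e-12)
        rng = np.random.default_rng(0)
        mc, se = mc_expected_sq_distance(a, a, 100_000, rng)
        assert abs(mc - 3.0) < 3 * se

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            expected_sq_distance(np.full((2, 4), 0.25), np.full((3, 4), 0.25))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_bounded_property(self, seed):
        rng = np.random.default_rng(seed)
        L, C = int(rng.integers(1, 6)), int(rng.integers(2, 8))
        a = random_simplex_rows(rng, L, C)
        b = random_simplex_rows(rng, L, C)
        d_ab = expected_sq_distance(a, b)
        assert d_ab == pytest.approx(expected_sq_distance(b, a), rel=1e-12)
        assert -1e-12 <= d_ab <= 2 * L + 1e-12

    def test_nonzero_for_identical_nondeterministic(self):
        a = np.array([[0.5, 0.5, 0.0]])
        assert expected_sq_distance(a, a) == pytest.approx(1.0)


class TestCurveEnergy:
    def test_constant_curve_zero(self):
        m = constant_model(np.full((3, 4), 0.25))
        c = Curve(np.zeros((5, 2)))
        assert curve_energy(m, c) == 0.0

    def test_uniform_decoder_closed_form(self):
        L, C = 3, 4
        m = constant_model(np.full((L, C), 1.0 / C))
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0]])
        c = Curve(pts)
        total_len = 3.0
        expect = 2 * L * (1 - 1 / C) * total_len
        assert curve_energy(m, c) == pytest.approx(expect, rel=1e-12)

    def test_two_point_deterministic_distinct(self):
        # alpha=1 decoders flipping one position; dt = 0.5 -> E = 2*1*0.5 = 1
        m = constant_model(np.array([[1.0, 0.0, 0.0]]))
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])
        probs = m.decode_batch(pts)
        probs_b = probs.copy()
        probs_b[1] = np.array([[0.0, 1.0, 0.0]])
        dt = 0.5
        e_manual = expected_sq_distance(probs_b[0], probs_b[1]) * dt
        assert e_manual == pytest.approx(1.0, rel=1e-12)
        # Monte-Carlo energy oracle on the same pair
        rng = np.random.default_rng(0)
        sa = sample_sequences(probs_b[0], 50_000, rng)
        sb = sample_sequences(probs_b[1], 50_000, rng)
        mc = 2.0 * np.mean((sa != sb).sum(axis=1)) * dt
        assert mc == pytest.approx(1.0, abs=1e-9)

    def test_reversal_invariance(self, tiny_model):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        assert curve_energy(tiny_model, Curve(pts)) == pytest.approx(
            curve_energy(tiny_model, Curve(pts[::-1])), rel=1e-12
        )

    def test_monte_carlo_energy_consistency(self, tiny_model):
        """Sampled one-hot energy converges to the closed-form expectation."""
        rng = np.random.default_rng(3)
        pts = tiny_model.train_embeddings[:3]
        analytic = curve_energy(tiny_model, Curve(pts))
        probs = tiny_model.decode_batch(pts)
        n = 40_000
        total, var = 0.0, 0.0
        for i in range(len(pts) - 1):
            dt = np.linalg.norm(pts[i + 1] - pts[i])
            sa = sample_sequences(probs[i], n, rng)
            sb = sample_sequences(probs[i + 1], n, rng)
            d2 = 2.0 * (sa != sb).sum(axis=1)
            total += d2.mean() * dt
            var += (d2.std() / np.sqrt(n) * dt) ** 2
        assert abs(total - analytic) < 3 * np.sqrt(var) + 1e-9


class TestDecodeVjp:
    def test_matches_finite_differences(self, tiny_model):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        E, g = _energy_and_grad(tiny_model, pts)
        eps = 1e-6
        for i in range(pts.shape[0]):
            for k in range(2):
                p1, p2 = pts.copy(), pts.copy()
                p1[i, k] += eps
                p2[i, k] -= eps
                num = (curve_energy(tiny_model, Curve(p1))
                       - curve_energy(tiny_model, Curve(p2))) / (2 * eps)
                assert g[i, k] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestEntropyGrid:
    def test_uniform_landscape_weight_ratios(self):
        m = constant_model(np.full((3, 4), 0.25))
        g = entropy_grid(m, bounds=(0, 1, 0, 1), resolution=4)
        W = g.graph.tocoo()
        weights = {}
        for u, v, w in zip(W.row, W.col, W.data):
            du = np.linalg.norm(g.nodes[u] - g.nodes[v])
            weights.setdefault(round(du, 9), set()).add(round(w, 12))
        straight, diag = sorted(weights)
        assert len(weights[straight]) == 1 and len(weights[diag]) == 1
        assert (next(iter(weights[diag])) / next(iter(weights[straight]))
                == pytest.approx(np.sqrt(2), rel=1e-9))

    def test_all_weights_positive(self, tiny_model):
        g = entropy_grid(tiny_model, resolution=12)
        assert np.all(g.graph.data > 0)

    def test_far_nodes_attain_max_entropy(self, tiny_model):
        c = tiny_model.entropy.centers
        hi = c.max() + 100
        g = entropy_grid(tiny_model, bounds=(hi, hi + 10, hi, hi + 10), resolution=5)
        assert np.allclose(g.entropies, tiny_model.max_entropy, atol=1e-3 * tiny_model.L)

    def test_degenerate_bounds_error(self, tiny_model):
        with pytest.raises(ValueError):
            entropy_grid(tiny_model, bounds=(0, 0, 0, 1), resolution=4)


def _nx_from_grid(grid):
    G = nx.Graph()
    W = grid.graph.tocoo()
    for u, v, w in zip(W.row, W.col, W.data):
        G.add_edge(int(u), int(v), weight=float(w))
    return G


class TestShortestGridPath:
    def test_same_point_single_node(self, tiny_model):
        g = entropy_grid(tiny_model, resolution=8)
        z = tiny_model.train_embeddings[0]
        path = shortest_grid_path(g, z, z)
        assert path.shape[0] == 1

    @pytest.mark.parametrize("resolution", [3, 4, 5])
    def test_equals_brute_force_enumeration(self, tiny_model, resolution):
        g = entropy_grid(tiny_model, resolution=resolution)
        G = _nx_from_grid(g)
        a = g.nodes[0]
        b = g.nodes[-1]
        cost = grid_path_cost(g, a, b)
        # independent oracle: networkx Dijkstra on the same graph
        assert cost == pytest.approx(
            nx.dijkstra_path_length(G, 0, g.resolution**2 - 1), rel=1e-9
        )
        # exhaustive enumeration of simple paths (bounded length; on these
        # landscapes longer detours are strictly costlier)
        cutoff = None if resolution == 3 else 2 * resolution
        best = min(
            sum(G[u][v]["weight"] for u, v in zip(p, p[1:]))
            for p in nx.all_simple_paths(G, 0, g.resolution**2 - 1, cutoff=cutoff)
        )
        assert cost == pytest.approx(best, rel=1e-9)

    def test_high_entropy_wall_forces_detour(self):
        # deterministic raw decoder + one proximity center at the origin:
        # a low-entropy basin at the center, high-entropy walls elsewhere
        m = constant_model(np.eye(5)[np.zeros(4, int)], entropy=far_entropy_params(1.0))
        g = entropy_grid(m, bounds=(-1, 1, -1, 1), resolution=5)
        G = _nx_from_grid(g)
        a, b = np.array([-1.0, -1.0]), np.array([1.0, -1.0])
        path = shortest_grid_path(g, a, b)
        cost = grid_path_cost(g, a, b)
        best = nx.dijkstra_path_length(G, g.nearest_node(a), g.nearest_node(b))
        assert cost == pytest.approx(best, rel=1e-9)
        # the optimal path dips toward the low-entropy basin instead of
        # running straight along the high-entropy bottom edge
        assert path[:, 1].max() > -1.0

    def test_uniform_grid_cost_is_chamfer_distance(self):
        m = constant_model(np.full((2, 4), 0.25))
        g = entropy_grid(m, bounds=(0, 4, 0, 4), resolution=5)
        h = 1.0  # grid spacing
        Hn = m.sequence_entropy(np.zeros(2)) / m.max_entropy
        w_straight = h * (0.01 + Hn)
        w_diag = np.sqrt(2) * h * (0.01 + Hn)
        # from node (0,0) to (3,1): chamfer = 1 diagonal + 2 straight
        cost = grid_path_cost(g, np.array([0.0, 0.0]), np.array([3.0, 1.0]))
        assert cost == pytest.approx(2 * w_straight + 1 * w_diag, rel=1e-9)


class TestRefineGeodesic:
    def test_endpoints_fixed_and_energy_nonincreasing(self, tiny_model):
        rng = np.random.default_rng(5)
        init = rng.normal(size=(6, 2))
        cfg = GeodesicConfig(n_samples=64)
        gd = refine_geodesic(tiny_model, init, cfg)
        assert np.allclose(gd.curve.points[0], init[0])
        assert np.allclose(gd.curve.points[-1], init[-1])
        spline0 = _resample_polyline(init, cfg.n_samples)
        # initial spline through the init polyline: compare against its energy
        E0 = curve_energy(tiny_model, Curve(spline0))
        assert gd.energy <= E0 + 1e-9
        assert gd.length == pytest.approx(np.sqrt(gd.energy), rel=1e-12)

    def test_flat_landscape_stays_straight(self):
        m = constant_model(np.full((3, 4), 0.25))
        init = np.array([[0.0, 0.0], [2.0, 0.0]])
        gd = refine_geodesic(m, init, GeodesicConfig(n_samples=32))
        ys = gd.curve.points[:, 1]
        assert np.max(np.abs(ys)) < 1e-6


class TestGeodesic:
    def test_same_point_zero_length(self, tiny_model):
        z = tiny_model.train_embeddings[0]
        gd = geodesic(tiny_model, z, z)
        assert gd.length == 0.0

    def test_never_longer_than_straight_line(self, tiny_model):
        rng = np.random.default_rng(6)
        emb = tiny_model.train_embeddings
        grid = entropy_grid(tiny_model, resolution=30)
        cfg = GeodesicConfig(n_samples=64)
        for _ in range(5):
            i, j = rng.choice(len(emb), 2, replace=False)
            gd = geodesic(tiny_model, emb[i], emb[j], grid=grid, config=cfg)
            straight = Curve(_resample_polyline(np.vstack([emb[i], emb[j]]), cfg.n_samples))
            assert gd.energy <= curve_energy(tiny_model, straight) + 1e-9

    def test_symmetry_within_tolerance(self, tiny_model):
        emb = tiny_model.train_embeddings
        grid = entropy_grid(tiny_model, resolution=30)
        cfg = GeodesicConfig(n_samples=64)
        rng = np.random.default_rng(7)
        for _ in range(3):
            i, j = rng.choice(len(emb), 2, replace=False)
            ab = geodesic(tiny_model, emb[i], emb[j], grid=grid, config=cfg).length
            ba = geodesic(tiny_model, emb[j], emb[i], grid=grid, config=cfg).length
            assert abs(ab - ba) / max(ab, 1e-12) <= 0.05

    def test_triangle_inequality_audit(self, tiny_model):
        emb = tiny_model.train_embeddings
        grid = entropy_grid(tiny_model, resolution=30)
        cfg = GeodesicConfig(n_samples=64)
        rng = np.random.default_rng(8)
        for _ in range(3):
            i, j, k = rng.choice(len(emb), 3, replace=False)
            d_ij = geodesic(tiny_model, emb[i], emb[j], grid=grid, config=cfg).length
            d_ik = geodesic(tiny_model, emb[i], emb[k], grid=grid, config=cfg).length
            d_kj = geodesic(tiny_model, emb[k], emb[j], grid=grid, config=cfg).length
            assert d_ij <= d_ik + d_kj + 0.05 * d_ij


class TestExpectedHamming:
    def test_identical_deterministic_zero(self):
        m = constant_model(np.eye(4)[np.array([0, 1, 2])])
        z = np.zeros(2)
        assert expected_hamming(m, z, z, n_samples=20, seed=0) == 0.0

    def test_disjoint_deterministic_full_length(self):
        from conftest import linear_logit_model

        L, C, s = 4, 5, 3.0
        W = np.zeros((2, L * C))
        for pos in range(L):
            W[0, pos * C + 0] = s
            W[0, pos * C + 1] = -s
        m = linear_logit_model(W, L, C)
        z1, z2 = np.array([10.0, 0.0]), np.array([-10.0, 0.0])
        assert expected_hamming(m, z1, z2, n_samples=10, seed=0) == L

    def test_matches_half_expected_sq_distance(self, tiny_model):
        emb = tiny_model.train_embeddings
        z1, z2 = emb[0], emb[9]
        n = 20_000
        eh = expected_hamming(tiny_model, z1, z2, n_samples=n, seed=1)
        esd = expected_sq_distance(tiny_model.decode(z1), tiny_model.decode(z2))
        pa, pb = tiny_model.decode(z1), tiny_model.decode(z2)
        pvar = np.sum((1 - np.sum(pa * pb, axis=1)) * np.sum(pa * pb, axis=1))
        se = np.sqrt(max(pvar, 1e-12) / n)
        assert abs(eh - esd / 2) < 3 * se + 1e-9
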