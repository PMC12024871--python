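import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicsmap import (EmbedConfig, HyperbolicCoords, MultiOmicsNetwork,
                      circular_correlation, connection_probability,
                      estimate_gamma, hm_refine, labne_embed, log_likelihood,
                      read_coords, write_coords)
from omicsmap.network import Edge
from omicsmap.simulate import ps_cutoff


def protein_net(graph):
    net = MultiOmicsNetwork()
    for v in graph.nodes:
        net.add_node(f"P{v:04d}", layer="protein")
    for a, b in graph.edges:
        net.add_edge(Edge(f"P{a:04d}", f"P{b:04d}", ("ppi",), 1.0))
    return net


class TestEstimateGamma:
    def pareto_sample(self, gamma, n, seed):
        rng = np.random.default_rng(seed)
        # inverse-CDF sampling of a pure Pareto tail with exponent gamma
        return (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))

    @pytest.mark.parametrize("gamma,tol", [(2.98, 0.1), (2.2, 0.15)])
    def test_recovers_planted_exponent(self, gamma, tol):
        estimates = [estimate_gamma(self.pareto_sample(gamma, 10_000, seed))
                     for seed in range(10)]
        assert abs(np.mean(estimates) - gamma) < tol

    def test_constant_degrees_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_gamma([5] * 100)

    def test_too_few_degrees_rejected(self):
        with pytest.raises(ValueError):
            estimate_gamma([1, 2, 3])


class TestLabneEmbed:
    def test_cycle_graph_angles_are_arithmetic(self):
        # Laplacian eigenvectors of a cycle are sines/cosines, so inferred
        # angles must follow the node index up to rotation/reflection
        net = protein_net(nx.cycle_graph(64))
        coords = labne_embed(net, EmbedConfig(gamma=2.5, temperature=0.5))
        index_angle = 2 * np.pi * np.arange(64) / 64
        rho = circular_correlation(coords.theta, index_angle)
        assert abs(rho) > 0.99

    def test_max_degree_node_gets_min_radius(self):
        net = protein_net(nx.barabasi_albert_graph(60, 2, seed=1))
        coords = labne_embed(net, EmbedConfig())
        degrees = {f"P{v:04d}": d for v, d in
                   nx.barabasi_albert_graph(60, 2, seed=1).degree()}
        top = max(degrees, key=lambda v: (degrees[v], v))
        r_by_id = dict(zip(coords.ids, coords.r))
        assert r_by_id[top] == min(coords.r)

    def test_radius_order_follows_degree_rank(self):
        graph = nx.barabasi_albert_graph(80, 3, seed=2)
        net = protein_net(graph)
        coords = labne_embed(net, EmbedConfig())
        r_by_id = dict(zip(coords.ids, coords.r))
        ranked = sorted(graph.nodes, key=lambda v: (-graph.degree(v), f"P{v:04d}"))
        radii = [r_by_id[f"P{v:04d}"] for v in ranked]
        assert radii == sorted(radii)

    def test_disconnected_input_rejected(self):
        graph = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            labne_embed(protein_net(graph), EmbedConfig())

    def test_deterministic(self):
        net = protein_net(nx.barabasi_albert_graph(50, 2, seed=3))
        c1 = labne_embed(net, EmbedConfig(seed=5))
        c2 = labne_embed(net, EmbedConfig(seed=5))
        assert c1.to_frame().equals(c2.to_frame())


class TestConnectionProbability:
    def test_half_probability_at_cutoff(self):
        assert connection_probability(3.0, 3.0, 0.5) == pytest.approx(0.5)

    def test_logistic_quartile_point(self):
        R, T = 2.0, 0.3
        assert connection_probability(R + 2 * T * math.log(3), R, T) == \
            pytest.approx(0.25)

    def test_vanishes_at_infinity(self):
        assert connection_probability(1e6, 3.0, 0.5) == pytest.approx(0.0)

    def test_strictly_decreasing(self):
        x = np.linspace(0, 20, 200)
        p = connection_probability(x, 5.0, 0.7)
        assert np.all(np.diff(p) < 0)

    def test_zero_temperature_rejected(self):
        with pytest.raises(ValueError):
            connection_probability(1.0, 1.0, 0.0)


def two_node_net():
    net = MultiOmicsNetwork()
    net.add_edge(Edge("A", "B", ("ppi",), 1.0))
    return net


def coords_table(rows):
    return HyperbolicCoords(
        pd.DataFrame(rows, columns=["id", "layer", "r", "theta"]))


class TestLogLikelihood:
    def test_single_edge_at_cutoff(self):
        net = two_node_net()
        cfg = EmbedConfig(gamma=3.0, temperature=0.5, m=1)
        R = ps_cutoff(2, 1, cfg.beta, cfg.temperature)
        coords = coords_table([("A", "protein", R / 2, 0.0),
                               ("B", "protein", R / 2, math.pi)])
        # distance = r_a + r_b = R, so p = 1/2
        assert log_likelihood(net, coords, cfg) == pytest.approx(math.log(0.5))

    def test_non_edge_at_cutoff_adds_log_half(self):
        net = two_node_net()
        net.add_node("C", layer="protein")
        base = EmbedConfig(gamma=3.0, temperature=0.5, m=1)
        R = ps_cutoff(3, 1, base.beta, base.temperature)
        cfg = EmbedConfig(gamma=3.0, temperature=0.5, m=1, cutoff_R=R)
        coords = coords_table([("A", "protein", R / 2, 0.0),
                               ("B", "protein", R / 2, math.pi),
                               ("C", "protein", R / 2, math.pi / 2)])
        # pairs: (A,B) edge at distance R; (A,C) and (B,C) non-edges
        from omicsmap import hyperbolic_distance
        d = hyperbolic_distance(R / 2, 0.0, R / 2, math.pi / 2)
        p = connection_probability(d, R, 0.5)
        expected = math.log(0.5) + 2 * math.log(1 - p)
        assert log_likelihood(net, coords, cfg) == pytest.approx(expected)

    def test_matches_brute_force_pairwise_sum(self):
        rng = np.random.default_rng(0)
        graph = nx.erdos_renyi_graph(50, 0.12, seed=4)
        net = protein_net(graph)
        cfg = EmbedConfig(gamma=2.5, temperature=0.6)
        rows = [(f"P{v:04d}", "protein", rng.uniform(0.5, 8.0),
                 rng.uniform(0, 2 * np.pi)) for v in graph.nodes]
        coords = coords_table(rows)
        from omicsmap import hyperbolic_distance
        from omicsmap.embedding import _calibration
        _, R = _calibration(net, cfg)
        expected = 0.0
        nodes = sorted(net.graph.nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                d = hyperbolic_distance(*coords.get(a), *coords.get(b))
                p = min(max(connection_probability(d, R, 0.6), 1e-12), 1 - 1e-12)
                if net.graph.has_edge(a, b):
                    expected += math.log(p)
                else:
                    expected += math.log(1 - p)
        assert log_likelihood(net, coords, cfg) == pytest.approx(expected, rel=1e-9)


@pytest.fixture(scope="module")
def small_ps():
    from omicsmap import PSParams, simulate_ps_network
    from omicsmap.network import largest_connected_component
    net, _ = simulate_ps_network(
        PSParams(n=200, m=3, gamma=2.5, temperature=0.3, seed=8))
    return largest_connected_component(net)


class TestHmRefine:
    def test_single_candidate_window_is_identity(self, small_ps):
        cfg = EmbedConfig(gamma=2.5, temperature=0.3, grid=1, window=1e-9,
                          max_sweeps=1)
        c0 = labne_embed(small_ps, cfg)
        c1 = hm_refine(small_ps, c0, cfg)
        assert np.allclose(c0.theta, c1.theta)
        assert np.allclose(c0.r, c1.r)

    def test_log_likelihood_never_decreases(self, small_ps):
        cfg = EmbedConfig(gamma=2.5, temperature=0.3, grid=72, max_sweeps=2)
        c0 = labne_embed(small_ps, cfg)
        c1 = hm_refine(small_ps, c0, cfg)
        assert log_likelihood(small_ps, c1, cfg) >= log_likelihood(small_ps, c0, cfg)

    def test_radii_unchanged(self, small_ps):
        cfg = EmbedConfig(gamma=2.5, temperature=0.3, grid=72, max_sweeps=1)
        c0 = labne_embed(small_ps, cfg)
        c1 = hm_refine(small_ps, c0, cfg)
        assert np.allclose(np.sort(c0.r), np.sort(c1.r))

    def test_idempotent_at_convergence(self, small_ps):
        cfg = EmbedConfig(gamma=2.5, temperature=0.3, grid=72, max_sweeps=8)
        c0 = labne_embed(small_ps, cfg)
        c1 = hm_refine(small_ps, c0, cfg)
        ll1 = log_likelihood(small_ps, c1, cfg)
        c2 = hm_refine(small_ps, c1, cfg)
        ll2 = log_likelihood(small_ps, c2, cfg)
        assert ll2 - ll1 <= 1e-6 * abs(ll1)


class TestCoordsIO:
    def test_round_trip_full_precision(self, tmp_path, random_coords):
        p = tmp_path / "coords.tsv"
        write_coords(random_coords, p)
        back = read_coords(p)
        pd.testing.assert_frame_equal(back.to_frame(), random_coords.to_frame())

    def test_negative_theta_canonicalized(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tlayer\tr\ttheta\nP1\tprotein\t1.0\t-0.1\n")
        coords = read_coords(p)
        assert coords.get("P1")[1] == pytest.approx(2 * math.pi - 0.1)

    def test_negative_radius_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tlayer\tr\ttheta\nP1\tprotein\t-1.0\t0.1\n")
        with pytest.raises(ValueError, match="row 2"):
            read_coords(p)

    def test_non_finite_value_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tlayer\tr\ttheta\nP1\tprotein\t1.0\tnan\n")
        with pytest.raises(ValueError, match="row 2"):
            read_coords(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tr\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_coords(p)

    def test_layer_inferred_when_absent(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tr\ttheta\nSLM:000000470\t3.0\t0.5\n")
        coords = read_coords(p)
        assert coords.layer_of("SLM:000000470") == "lipid"


def test_recovery_degrades_with_temperature():
    """Hotter PS networks carry less angular signal: mean recovery over a
    fixed seed set decreases across T = 0.5, 0.7, 0.9."""
    from omicsmap import angular_recovery_experiment
    means = [angular_recovery_experiment(n=400, m=3, gamma=2.5, temperature=T,
                                         seeds=(0, 1, 2),
                                         refine=False)["labne_corr"].mean()
             for T in (0.5, 0.7, 0.9)]
    assert means[0] > means[1] > means[2]


def test_circular_correlation_properties():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 2 * np.pi, 300)
    noise = rng.normal(0, 0.1, 300)
    b = (a + 1.0 + noise) % (2 * np.pi)
    assert circular_correlation(a, b) > 0.9
    # reflection flips the sign
    assert circular_correlation(a, (-a - 0.5) % (2 * np.pi)) < -0.9
    # independent angles are uncorrelated
    c = rng.uniform(0, 2 * np.pi, 300)
    assert abs(circular_correlation(a, c)) < 0.2
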