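import networkx as nx
import numpy as np
import pytest

from socnetlong.centrality import (
    bonacich_power,
    centralization,
    cohesion,
    group_dispersion,
    information_centrality,
    strength,
)
from socnetlong.community import cpmw_communities
from socnetlong.centrality import centrality_table
from socnetlong.errors import ConfigError, DegenerateInputError, DomainError
from .conftest import random_weighted_graph


def star(leaves=3, w=0.5):
    g = nx.Graph()
    g.add_weighted_edges_from([("c", i, w) for i in range(leaves)])
    return g


def path3(w=1.0):
    g = nx.Graph()
    g.add_weighted_edges_from([(0, 1, w), (1, 2, w)])
    return g


class TestStrength:
    def test_star(self):
        s = strength(star())
        assert s["c"] == pytest.approx(1.5)
        assert s[0] == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        g = star()
        g.add_node("iso")
        assert strength(g)["iso"] == 0.0

    def test_matches_row_sums(self):
        g = random_weighted_graph(np.random.default_rng(0), n=6)
        s = strength(g)
        for node in g.nodes:
            expected = sum(d["weight"] for _, _, d in g.edges(node, data=True))
            assert s[node] == pytest.approx(expected)


class TestBonacichPower:
    def test_beta_zero_is_strength(self):
        g = random_weighted_graph(np.random.default_rng(1), n=6)
        p = bonacich_power(g, beta=0.0, normalize=False)
        s = strength(g)
        for node in g.nodes:
            assert p[node] == pytest.approx(s[node])

    def test_single_edge_half_beta(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        p = bonacich_power(g, beta=0.5, normalize=False)
        assert p[0] == pytest.approx(2.0)
        assert p[1] == pytest.approx(2.0)

    def test_matches_power_series(self):
        g = random_weighted_graph(np.random.default_rng(2), n=5, p_edge=0.8)
        w = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str))
        rho = max(abs(np.linalg.eigvalsh(w)))
        beta = 0.9 / rho
        # series oracle: sum_m beta^m W^(m+1) 1
        expected = np.zeros(len(w))
        vec = w @ np.ones(len(w))  # term m: beta^m W^(m+1) 1, folded into vec
        for _ in range(4000):
            expected += vec
            vec = beta * (w @ vec)
        p = bonacich_power(g, beta=beta, normalize=False)
        got = np.array([p[n] for n in sorted(g.nodes, key=str)])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_beta_beyond_spectral_bound_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        with pytest.raises(DomainError, match="spectral"):
            bonacich_power(g, beta=1.5)


class TestInformationCentrality:
    def test_path3_hand_inversion(self):
        info = information_centrality(path3())
        assert info[0] == pytest.approx(1.0, abs=1e-10)
        assert info[1] == pytest.approx(1.5, abs=1e-10)
        assert info[2] == pytest.approx(1.0, abs=1e-10)

    def test_complete_graph_symmetric(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.3, "weight")
        vals = list(information_centrality(g).values())
        assert np.allclose(vals, vals[0])

    def test_connected_graph_strictly_positive(self):
        g = random_weighted_graph(np.random.default_rng(3), n=7, p_edge=0.9)
        assert all(v > 0 for v in information_centrality(g).values())

    def test_disconnected_requires_flag(self):
        g = path3()
        g.add_edge("x", "y", weight=1.0)
        with pytest.raises(DomainError, match="per_component"):
            information_centrality(g)
        info = information_centrality(g, per_component=True)
        assert set(info) == {0, 1, 2, "x", "y"}


class TestGroupDispersion:
    def test_constant_values_zero(self):
        assert group_dispersion({"a": 1, "b": 1, "c": 1},
                                {"a": 0, "b": 0, "c": 0})[0] == 0.0

    def test_population_sd(self):
        assert group_dispersion({"a": 0, "b": 2}, {"a": 0, "b": 0})[0] == pytest.approx(1.0)

    def test_sample_sd(self):
        vals = {k: v for k, v in zip("abcd", (1, 2, 3, 4))}
        groups = {k: 0 for k in "abcd"}
        out = group_dispersion(vals, groups, estimator="sample")
        assert out[0] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_singleton_sample_sd_undefined(self):
        with pytest.raises(DegenerateInputError):
            group_dispersion({"a": 1.0}, {"a": 0}, estimator="sample")

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(5)
        vals = {i: float(rng.normal()) for i in range(12)}
        groups = {i: i % 3 for i in range(12)}
        out = group_dispersion(vals, groups)
        for gid in range(3):
            members = [vals[i] for i in range(12) if i % 3 == gid]
            assert out[gid] == pytest.approx(np.std(members))


class TestCohesion:
    def test_complete_binary_graph_is_one(self):
        g = nx.complete_graph(4)
        assert cohesion(g, "binary") == pytest.approx(1.0)

    def test_path3_binary(self):
        assert cohesion(path3(), "binary") == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        assert cohesion(g, "binary") == pytest.approx(2 / 6)

    def test_inverse_weight_distances(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5)  # length 2
        assert cohesion(g, "inverse_weight") == pytest.approx(0.5)


class TestCentralization:
    def test_star_is_one(self):
        assert centralization(star(3, w=0.7)) == pytest.approx(1.0)

    def test_uniform_complete_graph_is_zero(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.5, "weight")
        assert centralization(g) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_always_in_unit_interval(self, seed):
        g = random_weighted_graph(np.random.default_rng(seed), n=7)
        if g.number_of_edges() == 0:
            return
        assert 0.0 <= centralization(g) <= 1.0

    def test_too_small_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        with pytest.raises(DegenerateInputError):
            centralization(g)


class TestScalingInvariance:
    def test_weight_scaling_properties(self):
        rng = np.random.default_rng(9)
        g = random_weighted_graph(rng, n=7, p_edge=0.8)
        c = 0.37
        g2 = g.copy()
        for _, _, d in g2.edges(data=True):
            d["weight"] *= c
        s1, s2 = strength(g), strength(g2)
        for node in g.nodes:
            assert s2[node] == pytest.approx(c * s1[node])
        assert centralization(g2) == pytest.approx(centralization(g))
        i1 = information_centrality(g)
        i2 = information_centrality(g2)
        order = sorted(g.nodes, key=str)
        rank1 = np.argsort([i1[n] for n in order])
        rank2 = np.argsort([i2[n] for n in order])
        np.testing.assert_array_equal(rank1, rank2)


class TestCentralityTable:
    def test_tidy_outputs(self):
        rng = np.random.default_rng(12)
        g = random_weighted_graph(rng, n=10, p_edge=0.7)
        assignment = cpmw_communities(g, 3, 0.0)
        ind, grp = centrality_table(g, assignment, period="P")
        assert set(ind.columns) >= {"period", "individual", "group",
                                    "strength", "power", "information"}
        assert set(grp.columns) >= {"sd_strength", "sd_power", "sd_information",
                                    "cohesion", "centralization", "size"}
        assert len(ind) == g.number_of_nodes()
        assert (grp["size"] >= 1).all()
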