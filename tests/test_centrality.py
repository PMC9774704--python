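"""Targeted weighting and power-iteration eigenvector centrality."""

import math

import networkx as nx
import numpy as np
import pytest

from swimnet.centrality import (
    eigenvector_centrality,
    hop_distances,
    proximity_factor,
    rank_influencers,
    weight_edges,
)


def _sig_graph(edges, nodes=()):
    """Significance graph from (u, v, r) triples with nominal p-values."""
    g = nx.Graph(alpha=0.05)
    g.add_nodes_from(nodes)
    for u, v, r in edges:
        g.add_edge(u, v, r=r, p=0.01)
    return g


def _path_graph(labels):
    return _sig_graph([(a, b, 0.5) for a, b in zip(labels, labels[1:])])


def _dense_principal(adj):
    """Oracle: principal eigenvector from a dense symmetric eigendecomposition."""
    w, v = np.linalg.eigh(adj)
    x = v[:, -1]
    x = np.abs(x)
    return w[-1], x / np.linalg.norm(x)


class TestHopDistances:
    def test_path_graph_hops(self):
        g = _path_graph("ABCDEF")
        hops = hop_distances(g, "A")
        assert hops == {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4, "F": 5}

    def test_isolated_node_unreachable(self):
        g = _path_graph("ABC")
        g.add_node("Z")
        assert math.isinf(hop_distances(g, "A")["Z"])

    def test_missing_target_lists_nodes(self):
        with pytest.raises(KeyError, match="A"):
            hop_distances(_path_graph("ABC"), "Q")

    def test_matches_unit_weight_dijkstra_oracle(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "unit")
        hops = hop_distances(g, "n0")
        oracle = nx.single_source_dijkstra_path_length(g, "n0", weight="unit")
        for node in g.nodes:
            assert hops[node] == oracle.get(node, math.inf)


class TestProximityFactor:
    @pytest.mark.parametrize(
        "k, expected", [(1, 1.0), (2, 0.5), (3, 0.250), (4, 0.125), (5, 0.0625)]
    )
    def test_printed_decay_sequence(self, k, expected):
        assert proximity_factor(k) == expected

    def test_geometric_extension_beyond_fifth(self):
        assert proximity_factor(6) == 0.03125
        assert proximity_factor(10) == 2.0 ** -9

    def test_optional_floor_at_fifth_degree(self):
        assert proximity_factor(6, floor_at_fifth=True) == 0.0625

    @pytest.mark.parametrize("k", [0, -1, 1.5])
    def test_bad_degree_rejected(self, k):
        with pytest.raises(ValueError):
            proximity_factor(k)


class TestWeightEdges:
    def test_edge_touching_target_keeps_abs_r(self):
        g = _sig_graph([("tyr", "X", -0.7)])
        tg = weight_edges(g, "tyr")
        assert tg.graph.edges["tyr", "X"]["weight"] == pytest.approx(0.7)
        assert tg.graph.edges["tyr", "X"]["r"] == -0.7  # sign kept for reporting
        assert tg.graph.edges["tyr", "X"]["k"] == 1

    def test_second_degree_edge_halved(self):
        g = _sig_graph([("tyr", "A", 0.8), ("A", "B", 0.6)])
        tg = weight_edges(g, "tyr")
        assert tg.graph.edges["A", "B"]["weight"] == pytest.approx(0.30)
        assert tg.graph.edges["A", "B"]["k"] == 2

    def test_degree_uses_closer_endpoint(self):
        # A at hop 1, C at hop 2: edge (A, C) takes min(1, 2) -> second degree;
        # edge (B, C) joins two hop-2 nodes -> third degree
        g = _sig_graph([("tyr", "A", 0.9), ("tyr", "B0", 0.9), ("B0", "B", 0.9),
                        ("A", "C", 0.4), ("B", "C", 0.4)])
        tg = weight_edges(g, "tyr")
        assert tg.graph.edges["A", "C"]["k"] == 2
        assert tg.graph.edges["A", "C"]["weight"] == pytest.approx(0.2)
        assert tg.graph.edges["B", "C"]["k"] == 3
        assert tg.graph.edges["B", "C"]["weight"] == pytest.approx(0.1)

    def test_unreachable_edges_dropped_with_record(self):
        g = _sig_graph([("tyr", "A", 0.9), ("X", "Y", 0.9)])
        tg = weight_edges(g, "tyr")
        assert tg.dropped_edges == (("X", "Y"),)
        assert ("X", "Y") not in tg.graph.edges

    def test_weights_bounded_by_abs_r(self, rng):
        g = nx.gnp_random_graph(10, 0.4, seed=8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["r"] = float(rng.uniform(-1, 1))
            g.edges[u, v]["p"] = 0.01
        tg = weight_edges(g, "n0")
        for u, v, d in tg.graph.edges(data=True):
            assert 0 <= d["weight"] <= abs(d["r"]) + 1e-15


class TestEigenvectorCentrality:
    def test_single_edge_scores(self):
        tg = weight_edges(_sig_graph([("tyr", "X", 0.37)]), "tyr")
        res = eigenvector_centrality(tg)
        assert res.converged
        assert res.scores["tyr"] == pytest.approx(1 / math.sqrt(2), abs=1e-10)
        assert res.scores["X"] == pytest.approx(1 / math.sqrt(2), abs=1e-10)

    def test_unweighted_star_closed_form(self):
        """Star, centre + 3 leaves, unit weights: centre 1/sqrt(2), leaves
        1/sqrt(6), lambda = sqrt(3)."""
        g = _sig_graph([("c", leaf, 1.0) for leaf in "xyz"])
        tg = weight_edges(g, "c")
        res = eigenvector_centrality(tg)
        assert res.scores["c"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        for leaf in "xyz":
            assert res.scores[leaf] == pytest.approx(1 / math.sqrt(6), abs=1e-8)
        assert res.eigenvalue == pytest.approx(math.sqrt(3), abs=1e-8)

    def test_unweighted_path_closed_form(self):
        """Path on n nodes, unit weights: x_i ~ sin(i*pi/(n+1)),
        lambda = 2*cos(pi/(n+1))."""
        n = 6
        labels = [f"p{i}" for i in range(n)]
        g = _sig_graph([(a, b, 1.0) for a, b in zip(labels, labels[1:])])
        tg = weight_edges(g, labels[0])
        for u, v in tg.graph.edges:
            tg.graph.edges[u, v]["weight"] = 1.0  # unit path, no decay
        res = eigenvector_centrality(tg)
        x = np.array([math.sin((i + 1) * math.pi / (n + 1)) for i in range(n)])
        x /= np.linalg.norm(x)
        for i, lab in enumerate(labels):
            assert res.scores[lab] == pytest.approx(x[i], abs=1e-8)
        assert res.eigenvalue == pytest.approx(2 * math.cos(math.pi / (n + 1)),
                                               abs=1e-8)

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for trial in range(50):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                g = nx.compose(g, nx.path_graph(n))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            for u, v in g.edges:
                g.edges[u, v]["r"] = float(rng.uniform(0.1, 1.0))
                g.edges[u, v]["p"] = 0.01
            tg = weight_edges(g, "n0")
            res = eigenvector_centrality(tg)
            assert res.converged
            nodes = sorted(g.nodes, key=str)
            idx = {m: i for i, m in enumerate(nodes)}
            adj = np.zeros((n, n))
            for u, v, d in tg.graph.edges(data=True):
                adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = d["weight"]
            lam, x = _dense_principal(adj)
            for m in nodes:
                assert res.scores[m] == pytest.approx(x[idx[m]], abs=1e-8)
            assert res.eigenvalue == pytest.approx(lam, abs=1e-8)

    def test_scale_invariance_of_scores(self):
        edges = [("tyr", "A", 0.8), ("A", "B", 0.6), ("tyr", "B", 0.3)]
        tg1 = weight_edges(_sig_graph(edges), "tyr")
        tg2 = weight_edges(_sig_graph([(u, v, r) for u, v, r in edges]), "tyr")
        for u, v in tg2.graph.edges:
            tg2.graph.edges[u, v]["weight"] *= 7.3
        r1 = eigenvector_centrality(tg1)
        r2 = eigenvector_centrality(tg2)
        for node in r1.scores:
            assert r1.scores[node] == pytest.approx(r2.scores[node], abs=1e-8)
        assert r2.eigenvalue == pytest.approx(7.3 * r1.eigenvalue, rel=1e-8)

    def test_uniform_factor_reduces_to_plain_weighted_centrality(self, rng):
        """With every proximity factor forced to 1 the result is ordinary
        weighted eigenvector centrality (dense-oracle check)."""
        g = nx.gnp_random_graph(8, 0.6, seed=17)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["r"] = float(rng.uniform(0.2, 0.9))
            g.edges[u, v]["p"] = 0.01
        tg = weight_edges(g, "n0")
        for u, v, d in tg.graph.edges(data=True):
            d["weight"] = abs(d["r"])  # strip the proximity decay
        res = eigenvector_centrality(tg)
        nodes = sorted(g.nodes, key=str)
        idx = {m: i for i, m in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for u, v, d in g.edges(data=True):
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = abs(d["r"])
        _, x = _dense_principal(adj)
        for m in nodes:
            assert res.scores[m] == pytest.approx(x[idx[m]], abs=1e-8)

    def test_edge_weight_monotonicity(self, rng):
        """Raising one edge's weight never lowers its endpoints' scores."""
        g = nx.gnp_random_graph(7, 0.6, seed=19)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["r"] = float(rng.uniform(0.2, 0.8))
            g.edges[u, v]["p"] = 0.01
        tg0 = weight_edges(g, "n0")
        base = eigenvector_centrality(tg0)
        u, v = next(iter(tg0.graph.edges))
        for bump in (1.5, 3.0, 10.0):
            tg1 = weight_edges(g, "n0")
            tg1.graph.edges[u, v]["weight"] *= bump
            res = eigenvector_centrality(tg1)
            assert res.scores[u] >= base.scores[u] - 1e-9
            assert res.scores[v] >= base.scores[v] - 1e-9

    def test_unit_norm_and_nonnegativity(self, rng):
        g = nx.gnp_random_graph(9, 0.5, seed=23)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["r"] = float(rng.uniform(-0.9, 0.9)) or 0.5
            g.edges[u, v]["p"] = 0.01
        tg = weight_edges(g, "n0")
        res = eigenvector_centrality(tg)
        comp = [n for n, h in tg.hops.items() if math.isfinite(h)]
        assert sum(res.scores[n] ** 2 for n in comp) == pytest.approx(1.0, abs=1e-10)
        assert all(s >= -1e-12 for s in res.scores.values())

    def test_disconnected_nodes_score_zero(self):
        g = _sig_graph([("tyr", "A", 0.9), ("X", "Y", 0.9)])
        tg = weight_edges(g, "tyr")
        res = eigenvector_centrality(tg)
        assert res.scores["X"] == 0.0 and res.scores["Y"] == 0.0

    def test_bipartite_component_still_converges(self):
        # even cycle = bipartite; the diagonal shift breaks oscillation
        labels = [f"b{i}" for i in range(6)]
        g = _sig_graph(
            [(labels[i], labels[(i + 1) % 6], 0.5) for i in range(6)]
        )
        res = eigenvector_centrality(weight_edges(g, "b0"), max_iter=5000)
        assert res.converged

    def test_max_norm_option(self):
        g = _sig_graph([("c", leaf, 1.0) for leaf in "xyz"])
        res = eigenvector_centrality(weight_edges(g, "c"), norm="max")
        assert res.scores["c"] == pytest.approx(1.0, abs=1e-8)
        for leaf in "xyz":
            assert res.scores[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-8)


class TestRanking:
    def test_star_leaves_tie_alphabetically(self):
        g = _sig_graph([("tyr", leaf, 0.8) for leaf in ("delta", "alpha", "casey")])
        res = eigenvector_centrality(weight_edges(g, "tyr"))
        assert [n for n, _ in res.ranking] == ["alpha", "casey", "delta"]

    def test_single_neighbor_ranked_first(self):
        g = _sig_graph([("tyr", "only", 0.4)])
        res = eigenvector_centrality(weight_edges(g, "tyr"))
        assert res.ranking[0][0] == "only"
        assert res.ranking[0][1] == pytest.approx(1 / math.sqrt(2), abs=1e-8)

    def test_target_excluded_from_ranking(self):
        g = _sig_graph([("tyr", "A", 0.9), ("A", "B", 0.9)])
        res = eigenvector_centrality(weight_edges(g, "tyr"))
        assert "tyr" not in [n for n, _ in res.ranking]
        assert rank_influencers(res) == res.ranking
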