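import numpy as np
import pandas as pd
import pytest

from kinact import (
    build_ppi_network,
    generate_reference_fixtures,
    identify_hub_bottlenecks,
    node_centralities,
    stress_centrality,
)
from kinact.io import EdgeList
from oracles import brute_force_centralities
from conftest import small_config


def _edges(pairs, conf=0.9):
    return EdgeList([(a, b, conf, None) for a, b in pairs])


def _random_graph(rng, n, p):
    nodes = [f"n{i}" for i in range(n)]
    pairs = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if rng.random() < p
    ]
    return nodes, pairs


class TestBuildNetwork:
    def test_isolated_nodes_retained(self):
        net = build_ppi_network(_edges([("A", "B"), ("B", "C")]), {"A", "B", "C", "D"})
        assert net.main_component == {"A", "B", "C"}
        assert net.isolated_nodes == ["D"]

    def test_complete_graph(self):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        net = build_ppi_network(_edges(pairs), {"A", "B", "C", "D"})
        assert len(net.components) == 1 and net.n_edges == 6

    def test_planted_isolates_counted(self):
        """A fixture with 7 nodes absent from the edge list reports 7 isolates."""
        pairs = [(f"m{i}", f"m{i+1}") for i in range(10)]
        restrict = {f"m{i}" for i in range(11)} | {f"iso{i}" for i in range(7)}
        net = build_ppi_network(_edges(pairs), restrict)
        assert len(net.isolated_nodes) == 7

    def test_empty_induced_graph_rejected(self):
        with pytest.raises(ValueError):
            build_ppi_network(_edges([("A", "B")]), set())


class TestCentralities:
    def test_path_graph_closed_forms(self):
        net = build_ppi_network(_edges([("A", "B"), ("B", "C")]))
        cent = node_centralities(net).set_index("node")
        b = cent.loc["B"]
        assert b["degree"] == 2
        assert b["betweenness"] == pytest.approx(1.0)
        assert b["closeness"] == pytest.approx(1.0)
        assert b["stress"] == 1

    def test_star_graph_closed_forms(self):
        net = build_ppi_network(_edges([("X", f"L{i}") for i in range(4)]))
        cent = node_centralities(net).set_index("node")
        assert cent.loc["X", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["X", "stress"] == 6  # C(4,2) leaf pairs
        assert cent.loc["L0", "betweenness"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nodes, pairs = _random_graph(rng, 8, 0.4)
        net = build_ppi_network(_edges(pairs), set(nodes))
        cent = node_centralities(net).set_index("node")
        oracle = brute_force_centralities(nodes, pairs)
        for v in nodes:
            assert cent.loc[v, "degree"] == oracle[v]["degree"]
            assert cent.loc[v, "stress"] == oracle[v]["stress"]
            assert cent.loc[v, "betweenness"] == pytest.approx(oracle[v]["betweenness"], abs=1e-12)
            assert cent.loc[v, "closeness"] == pytest.approx(oracle[v]["closeness"], abs=1e-12)

    def test_bounds_and_isolates(self):
        rng = np.random.default_rng(99)
        nodes, pairs = _random_graph(rng, 10, 0.3)
        net = build_ppi_network(_edges(pairs), set(nodes) | {"lonely"})
        cent = node_centralities(net)
        assert ((cent["betweenness"] >= 0) & (cent["betweenness"] <= 1)).all()
        assert ((cent["closeness"] >= 0) & (cent["closeness"] <= 1)).all()
        row = cent.set_index("node").loc["lonely"]
        assert row["degree"] == 0 and row["stress"] == 0


class TestHubBottlenecks:
    def _component_of_size(self, n):
        """A connected graph on n nodes: path backbone plus a few chords."""
        nodes = [f"g{i:03d}" for i in range(n)]
        pairs = list(zip(nodes, nodes[1:]))
        pairs += [(nodes[i], nodes[(i * 7 + 3) % n]) for i in range(0, n, 5) if nodes[i] != nodes[(i * 7 + 3) % n]]
        return nodes, pairs

    def test_hub_count_uses_ceiling_of_main_component(self):
        """78-node main component at 10% -> exactly ceil(7.8) = 8 hubs."""
        nodes, pairs = self._component_of_size(78)
        net = build_ppi_network(_edges(pairs), set(nodes) | {f"iso{i}" for i in range(7)})
        assert len(net.main_component) == 78
        result = identify_hub_bottlenecks(node_centralities(net), net, hub_fraction=0.10)
        assert len(result.hubs) == 8

    def test_tie_break_deterministic(self):
        # 4-cycle: all nodes identical on every centrality
        net = build_ppi_network(_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]))
        result = identify_hub_bottlenecks(node_centralities(net), net, bottleneck_count=2)
        assert result.hubs == ["A"]
        assert result.bottlenecks == ["A", "B"]

    def test_star_centre_is_unique_hub_bottleneck(self):
        _, _, edges, _ = generate_reference_fixtures(small_config(), topology="star")
        net = build_ppi_network(edges)
        result = identify_hub_bottlenecks(node_centralities(net), net, bottleneck_count=1)
        assert result.hub_bottlenecks == ["PRT001"]

    def test_intersection_invariant_under_relabelling(self):
        rng = np.random.default_rng(5)
        nodes, pairs = _random_graph(rng, 12, 0.3)
        net = build_ppi_network(_edges(pairs), set(nodes))
        res = identify_hub_bottlenecks(node_centralities(net), net, bottleneck_count=4)
        mapping = {n: f"z{n}" for n in nodes}
        pairs2 = [(mapping[a], mapping[b]) for a, b in pairs]
        net2 = build_ppi_network(_edges(pairs2), set(mapping.values()))
        res2 = identify_hub_bottlenecks(node_centralities(net2), net2, bottleneck_count=4)
        assert {mapping[n] for n in res.hub_bottlenecks} == set(res2.hub_bottlenecks)

    def test_bottleneck_count_clipped_with_warning(self):
        net = build_ppi_network(_edges([("A", "B")]))
        with pytest.warns(UserWarning, match="clipping"):
            result = identify_hub_bottlenecks(node_centralities(net), net, bottleneck_count=10)
        assert len(result.bottlenecks) == 2

    def test_adding_edge_never_decreases_degree(self):
        rng = np.random.default_rng(6)
        nodes, pairs = _random_graph(rng, 8, 0.3)
        extra = ("n0", "n7")
        if extra in pairs:
            pairs = [p for p in pairs if p != extra]
        before = node_centralities(build_ppi_network(_edges(pairs), set(nodes))).set_index("node")
        after = node_centralities(
            build_ppi_network(_edges(pairs + [extra]), set(nodes))
        ).set_index("node")
        assert after.loc["n0", "degree"] == before.loc["n0", "degree"] + 1
        assert after.loc["n7", "degree"] == before.loc["n7", "degree"] + 1
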