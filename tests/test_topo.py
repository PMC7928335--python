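import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_betweenness, brute_force_centroid, random_graph
from spcnet.topo import (
    betweenness,
    call_hubs,
    centrality_table,
    centroid,
    condition_specific_hubs,
    differential_correlation,
    edge_overlap,
    ego_network,
)


def star(k=3):
    return nx.star_graph(k)  # node 0 = center


class TestBetweenness:
    def test_path_middle(self):
        g = nx.path_graph(3)
        b = betweenness(g)
        assert b[1] == 1.0 and b[0] == b[2] == 0.0

    def test_star_center(self):
        assert betweenness(star(3))[0] == 3.0  # 3 leaf pairs

    def test_four_cycle_split_paths(self):
        b = betweenness(nx.cycle_graph(4))
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_tree_pair_length_identity(self):
        # for trees: sum of betweenness = sum over pairs of (path length - 1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            tree = nx.random_labeled_tree(int(rng.integers(2, 12)), seed=int(rng.integers(1e6)))
            total = sum(betweenness(tree).values())
            expected = sum(
                nx.shortest_path_length(tree, s, t) - 1
                for s in tree for t in tree if s < t
            )
            assert total == pytest.approx(expected)


class TestCentroid:
    def test_star(self):
        c = centroid(star(3))
        assert c[0] == 2 and all(c[leaf] == -2 for leaf in (1, 2, 3))

    def test_path(self):
        c = centroid(nx.path_graph(3))
        assert c[1] == 1 and c[0] == c[2] == -1

    def test_complete_graph_symmetric(self):
        assert set(centroid(nx.complete_graph(4)).values()) == {0}

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        assert centroid(g)["lonely"] == 0


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g = random_graph(rng)
            bf_b = brute_force_betweenness(g)
            b = betweenness(g)
            assert all(b[v] == pytest.approx(bf_b[v], abs=1e-9) for v in g)
            assert centroid(g) == brute_force_centroid(g)


class TestCallHubs:
    def test_star_ppi_mode(self):
        assert call_hubs(centrality_table(star(3)), mode="ppi") == {0}

    def test_regular_graph_no_degree_hubs(self):
        assert call_hubs(centrality_table(nx.cycle_graph(6)), mode="coexpression") == set()

    def test_path_degree_hubs(self):
        # degrees 1,2,2,1: mean 1.5 -> {b, c}
        assert call_hubs(centrality_table(nx.path_graph(4)), mode="coexpression") == {1, 2}

    def test_or_mode_is_superset_of_and(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            ct = centrality_table(random_graph(rng))
            assert call_hubs(ct, "ppi", "and") <= call_hubs(ct, "ppi", "or")

    def test_empty_network(self):
        assert call_hubs(centrality_table(nx.Graph()), "ppi") == set()


class TestConditionSpecificHubs:
    def test_definition_cases(self):
        hub_sets = {
            "+Mo+Fe": {"everywhere", "fe_only"},
            "-Mo+Fe": {"everywhere", "fe_only"},
            "+Mo-Fe": {"everywhere", "one_net"},
            "-Mo-Fe": {"everywhere"},
        }
        out = condition_specific_hubs(hub_sets, "Fe")
        # hub in both +Fe networks, neither -Fe network
        assert out["+Fe"] == {"fe_only"}
        # hub in all four networks is specific to nothing; hub in a single
        # network fails the both-networks rule
        assert out["-Fe"] == set()

    def test_any_rule_variant(self):
        hub_sets = {
            "+Mo+Fe": {"h"}, "-Mo+Fe": set(), "+Mo-Fe": set(), "-Mo-Fe": set()
        }
        assert condition_specific_hubs(hub_sets, "Fe", rule="any")["+Fe"] == {"h"}
        assert condition_specific_hubs(hub_sets, "Fe", rule="both")["+Fe"] == set()

    def test_level_sets_disjoint(self):
        rng = np.random.default_rng(3)
        proteins = [f"p{i}" for i in range(30)]
        hub_sets = {
            c: {p for p in proteins if rng.random() < 0.4}
            for c in ("+Mo+Fe", "-Mo+Fe", "+Mo-Fe", "-Mo-Fe")
        }
        for factor in ("Fe", "Mo"):
            out = condition_specific_hubs(hub_sets, factor)
            levels = list(out)
            assert out[levels[0]] & out[levels[1]] == set()

    def test_missing_network_rejected(self):
        with pytest.raises(ValueError):
            condition_specific_hubs({"+Mo+Fe": set()}, "Fe")


class TestDifferentialCorrelation:
    GROUPS = ["Fe_sufficiency", "Mo_sufficiency", "Fe_starvation", "Mo_starvation"]

    def _call(self, degrees, means):
        table = pd.DataFrame([degrees], columns=self.GROUPS, index=["prot"])
        return differential_correlation(table, dict(zip(self.GROUPS, means)))

    def test_no_strict_maximum_not_called(self):
        out = self._call([5, 5, 5, 5], [1, 1, 1, 1])
        assert not out.loc["prot", "called"]

    def test_below_focal_mean_not_called(self):
        out = self._call([30, 1, 1, 1], [35, 10, 10, 10])
        assert not out.loc["prot", "called"]

    def test_focal_grouping_assignment(self):
        out = self._call([2, 2, 1, 22], [17.7, 13.0, 15.5, 12.9])
        assert out.loc["prot", "called"]
        assert out.loc["prot", "focal_grouping"] == "Mo_starvation"


class TestEgoAndOverlap:
    def test_ego_shapes(self):
        g = star(4)
        assert set(ego_network(g, 0).nodes) == set(g.nodes)
        assert ego_network(g, 1).number_of_nodes() == 2
        lone = nx.Graph()
        lone.add_node("x")
        assert ego_network(lone, "x").number_of_nodes() == 1
        assert ego_network(g, "absent").number_of_nodes() == 0

    def test_ego_retains_edge_attributes(self):
        g = nx.Graph()
        g.add_edge("h", "a", rho=0.9, sign="positive")
        assert ego_network(g, "h").edges["h", "a"]["rho"] == 0.9

    @pytest.mark.parametrize(
        "coex_edges, ppi_edges, pair_pct",
        [
            ([("a", "b"), ("b", "c")], [("a", "b"), ("b", "c")], 100.0),
            ([("a", "b")], [("c", "d")], 0.0),
            ([("a", "b"), ("b", "c")], [("a", "b")], 50.0),
        ],
    )
    def test_pair_level_overlap(self, coex_edges, ppi_edges, pair_pct):
        coex, ppi = nx.Graph(coex_edges), nx.Graph(ppi_edges)
        assert edge_overlap(coex, ppi).pair_pct == pytest.approx(pair_pct)

    def test_empty_coexpression_undefined(self):
        ov = edge_overlap(nx.Graph(), nx.Graph([("a", "b")]))
        assert ov.pair_pct is None and ov.protein_pct is None
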