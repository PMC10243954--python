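from itertools import combinations, permutations

import networkx as nx
import pytest

from netpharm.io import EdgeRecord
from netpharm.netcore import (average_clustering, average_degree, build_network,
                              centralities, compound_degree_ranking, key_targets,
                              tf_subnetwork)
from netpharm.targets import CompoundAlias, TargetAssociation
from .conftest import random_graph


def brute_force_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Oracle: enumerate all shortest paths between every node pair."""
    scores = {node: 0.0 for node in graph.nodes}
    for s, t in combinations(graph.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for inner in path[1:-1]:
                scores[inner] += 1.0 / len(paths)
    return scores


class TestBuildNetwork:
    def test_confidence_boundary_strict(self):
        edges = [EdgeRecord("A", "B", 0.39), EdgeRecord("C", "D", 0.40),
                 EdgeRecord("E", "F", 0.41)]
        net = build_network(edges)
        assert set(map(frozenset, net.edges)) == {frozenset({"E", "F"})}

    def test_restriction_drops_outside_edges_keeps_isolated_nodes(self):
        edges = [EdgeRecord("A", "C", 0.9), EdgeRecord("A", "B", 0.9)]
        net = build_network(edges, restrict_to={"A", "B", "D"})
        assert set(net.nodes) == {"A", "B", "D"}
        assert set(map(frozenset, net.edges)) == {frozenset({"A", "B"})}
        assert net.degree("D") == 0

    def test_zero_cutoff_keeps_everything(self):
        edges = [EdgeRecord("A", "B", 0.01)]
        assert build_network(edges, min_confidence=0.0).number_of_edges() == 1


class TestTopologyStats:
    def test_average_degree_of_printed_network_size(self):
        # 68 nodes and 402 edges give the published mean degree 11.8
        g = nx.gnm_random_graph(68, 402, seed=1)
        assert average_degree(g) == pytest.approx(11.8, abs=0.05)

    def test_average_degree_small_cases(self, triangle):
        assert average_degree(triangle) == 2.0
        g = nx.Graph([("A", "B")])
        assert average_degree(g) == 1.0

    def test_average_clustering_examples(self, triangle, path4):
        assert average_clustering(triangle) == 1.0
        assert average_clustering(path4) == 0.0
        k4_minus = nx.complete_graph(4)
        k4_minus.remove_edge(0, 1)
        assert average_clustering(k4_minus) == pytest.approx(5 / 6)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            average_degree(nx.Graph())
        with pytest.raises(ValueError):
            average_clustering(nx.Graph())


class TestCentralities:
    def test_star_center_betweenness(self, star3):
        table = centralities(star3)
        assert table["C"] == (3, 3.0)
        assert all(table[leaf] == (1, 0.0) for leaf in ("L1", "L2", "L3"))

    def test_path_middle_node(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        assert centralities(g)["B"] == (2, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        g = random_graph(seed, n=14, p=0.3)
        table = centralities(g)
        oracle = brute_force_betweenness(g)
        for node in g.nodes:
            assert table[node][1] == pytest.approx(oracle[node], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_handshake_lemma(self, seed):
        g = random_graph(seed, n=20)
        table = centralities(g)
        assert sum(d for d, _ in table.values()) == 2 * g.number_of_edges()


class TestKeyTargets:
    def test_star_hub_is_the_only_key_target(self, star3):
        assert key_targets(centralities(star3)) == {"C"}

    def test_regular_graph_has_none(self):
        assert key_targets(centralities(nx.cycle_graph(6))) == set()

    def test_invariant_under_relabeling(self, star3):
        for perm in permutations(["X", "Y", "Z"]):
            mapping = dict(zip(["L1", "L2", "L3"], perm))
            relabeled = nx.relabel_nodes(star3, mapping)
            assert key_targets(centralities(relabeled)) == {"C"}


class TestCompoundRanking:
    ALIASES = [CompoundAlias("c1", "A"), CompoundAlias("c2", "B"),
               CompoundAlias("c3", "AA1")]

    def assocs(self):
        return [
            TargetAssociation("c1", g, 0.9) for g in ("G1", "G2", "G3")
        ] + [TargetAssociation("c2", "G1", 0.9), TargetAssociation("c2", "X", 0.9)]

    def test_degree_counts_common_targets_only(self):
        ranking = compound_degree_ranking(self.assocs(), ["G1", "G2", "G3"], self.ALIASES)
        assert ranking[0] == ("c1", "A", 3)
        assert ranking[1] == ("c2", "B", 1)

    def test_zero_degree_compound_ranked_last(self):
        ranking = compound_degree_ranking(self.assocs(), ["G1"], self.ALIASES)
        assert ranking[-1] == ("c3", "AA1", 0)

    def test_permutation_invariant(self):
        forward = compound_degree_ranking(self.assocs(), ["G1", "G2"], self.ALIASES)
        backward = compound_degree_ranking(self.assocs()[::-1], ["G1", "G2"], self.ALIASES)
        assert forward == backward


class TestTfSubnetwork:
    def test_keeps_only_in_set_edges_and_counts_out_degree(self):
        regulations = [("R1", "T1", "activation"), ("R1", "T2", "repression"),
                       ("R2", "T1", "unknown"), ("OUT", "T1", "activation")]
        kept, out_degree = tf_subnetwork(regulations, {"R1", "R2", "T1", "T2"})
        assert ("R1", "T1", "activation") in kept and len(kept) == 3
        assert out_degree == {"R1": 2, "R2": 1}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            tf_subnetwork([("A", "B", "inhibition")], {"A", "B"})
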