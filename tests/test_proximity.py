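import networkx as nx
import pytest

from netpharm.proximity import (closest_distance_between, null_control,
                                proximity_index, within_distance)
from .conftest import random_graph


def bfs_oracle_closest(graph, set_a, set_b):
    """Oracle: explicit BFS distances, averaged closest-member distances."""
    total = 0
    for a in set_a:
        total += min(nx.shortest_path_length(graph, a, b) for b in set_b)
    for b in set_b:
        total += min(nx.shortest_path_length(graph, b, a) for a in set_a)
    return total / (len(set_a) + len(set_b))


class TestDistances:
    def test_path_worked_example(self, path4):
        assert closest_distance_between(path4, {"1", "2"}, {"3", "4"}) == 1.5
        assert within_distance(path4, {"1", "2"}) == 1.0

    def test_identical_sets_have_zero_between_distance(self, path4):
        assert closest_distance_between(path4, {"1", "2"}, {"1", "2"}) == 0.0

    def test_singleton_sets_give_path_length(self, path4):
        assert closest_distance_between(path4, {"1"}, {"4"}) == 3.0

    def test_clique_within_distance_is_one(self):
        g = nx.relabel_nodes(nx.complete_graph(5), str)
        assert within_distance(g, set(g.nodes)) == 1.0

    def test_singleton_within_distance_undefined(self, path4):
        with pytest.raises(ValueError):
            within_distance(path4, {"1"})

    def test_unreachable_member_listed_in_error(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        with pytest.raises(ValueError, match="X"):
            closest_distance_between(g, {"A", "B"}, {"X", "Y"})

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        g = random_graph(seed, n=25, p=0.2)
        lcc = g.subgraph(max(nx.connected_components(g), key=len))
        nodes = sorted(lcc.nodes)
        if len(nodes) < 8:
            pytest.skip("degenerate draw")
        set_a, set_b = set(nodes[:4]), set(nodes[4:8])
        assert closest_distance_between(lcc, set_a, set_b) == pytest.approx(
            bfs_oracle_closest(lcc, set_a, set_b)
        )


class TestProximityIndex:
    def test_path_worked_example(self, path4):
        result = proximity_index(path4, {"1", "2"}, {"3", "4"})
        assert result.d_ab == 1.5 and result.d_aa == 1.0 and result.d_bb == 1.0
        assert result.s_ab == pytest.approx(0.5, abs=1e-12)

    def test_self_comparison_equals_minus_within_distance(self, path4):
        a = {"1", "2", "3"}
        result = proximity_index(path4, a, a)
        assert result.s_ab == pytest.approx(-within_distance(path4, a), abs=1e-12)
        assert result.s_ab <= 0

    def test_symmetric_in_its_arguments(self, path4):
        ab = proximity_index(path4, {"1", "2"}, {"3", "4"})
        ba = proximity_index(path4, {"3", "4"}, {"1", "2"})
        assert ab.s_ab == pytest.approx(ba.s_ab, abs=1e-12)

    def test_identity_holds_exactly(self, path4):
        r = proximity_index(path4, {"1", "2"}, {"2", "4"})
        assert r.s_ab == pytest.approx(r.d_ab - (r.d_aa + r.d_bb) / 2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_distances_shrink_monotonically_under_edge_addition(self, seed):
        g = random_graph(seed, n=18, p=0.25)
        lcc = nx.Graph(g.subgraph(max(nx.connected_components(g), key=len)))
        nodes = sorted(lcc.nodes)
        if len(nodes) < 8:
            pytest.skip("degenerate draw")
        set_a, set_b = set(nodes[:3]), set(nodes[3:7])
        before = proximity_index(lcc, set_a, set_b)
        missing = [
            (u, v) for u in nodes for v in nodes if u < v and not lcc.has_edge(u, v)
        ]
        lcc.add_edge(*missing[0])
        after = proximity_index(lcc, set_a, set_b)
        assert after.d_ab <= before.d_ab
        assert after.d_aa <= before.d_aa
        assert after.d_bb <= before.d_bb


class TestNullControl:
    def test_deterministic_given_seed(self, ):
        g = random_graph(2, n=30, p=0.2)
        lcc = g.subgraph(max(nx.connected_components(g), key=len))
        set_a = set(sorted(lcc.nodes)[:4])
        first = null_control(lcc, set_a, group_size=4, n_groups=10, seed=99)
        second = null_control(lcc, set_a, group_size=4, n_groups=10, seed=99)
        assert first == second

    def test_forced_overlap_group_gives_minus_within_distance(self, path4):
        set_a = {"1", "2"}
        mean, _, values = null_control(
            path4, set_a, group_size=2, n_groups=1, seed=0, eligible=set_a
        )
        assert values == [pytest.approx(-within_distance(path4, set_a))]

    def test_too_small_pool_rejected(self, path4):
        with pytest.raises(ValueError, match="eligible"):
            null_control(path4, {"1", "2"}, group_size=3, n_groups=5, seed=0)

    def test_planted_near_set_scores_below_null(self):
        from netpharm.synth import SyntheticConfig, gen_ppi

        hits_near = hits_order = 0
        for seed in range(20):
            planted = gen_ppi(SyntheticConfig(seed=seed))
            net = planted.network
            cache: dict = {}
            s_near = proximity_index(net, set(planted.set_a),
                                     set(planted.set_b_near), cache).s_ab
            s_far = proximity_index(net, set(planted.set_a),
                                    set(planted.set_b_far), cache).s_ab
            null_mean, _, _ = null_control(
                net, set(planted.set_a), group_size=len(planted.set_b_near),
                n_groups=50, seed=seed,
            )
            hits_near += s_near < null_mean
            hits_order += s_far > s_near
        assert hits_near >= 19
        assert hits_order >= 19
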