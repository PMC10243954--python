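from itertools import combinations
from math import comb

import numpy as np
import pytest

from netpharm.enrichment import (bh_adjust, correlation_clusters, enrich,
                                 hypergeometric_upper)
from netpharm.io import GeneSet


def enumerate_upper_tail(k, K, n, N):
    """Oracle: exhaustively enumerate all C(N, n) draws."""
    marked = set(range(K))
    hits = sum(
        1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return hits / comb(N, n)


class TestHypergeometric:
    def test_all_marked_draw_closed_form(self):
        # drawing all 5 marked of 10: exactly 1 / C(10, 5)
        assert hypergeometric_upper(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert hypergeometric_upper(0, 4, 3, 10) == 1.0

    def test_saturated_draw_is_certain(self):
        assert hypergeometric_upper(6, 6, 6, 6) == 1.0

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 3), (12, 6, 5)])
    def test_matches_enumeration_oracle(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            assert hypergeometric_upper(k, K, n, N) == pytest.approx(
                enumerate_upper_tail(k, K, n, N), abs=1e-12
            )

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_upper(5, 3, 4, 10)  # k > K


class TestBH:
    def test_hand_computed_example(self):
        # p=(0.01,0.02,0.03): adjusted = min over j>=i of p_j * m / j = 0.03 each
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_equal_inputs_stay_equal(self):
        assert bh_adjust([0.04] * 5) == pytest.approx([0.04] * 5)

    def test_monotone_when_input_sorted(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=30))
        adjusted = bh_adjust(p.tolist())
        assert all(a <= b + 1e-12 for a, b in zip(adjusted, adjusted[1:]))
        assert all(a >= raw for a, raw in zip(adjusted, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestEnrich:
    UNIVERSE = [f"G{i}" for i in range(20)]

    def terms(self):
        return [
            GeneSet("T1", "hit", frozenset(self.UNIVERSE[:5])),
            GeneSet("T2", "miss", frozenset(self.UNIVERSE[15:])),
            GeneSet("T3", "partial", frozenset(self.UNIVERSE[3:8])),
        ]

    def test_disjoint_term_excluded(self):
        results = enrich(set(self.UNIVERSE[:4]), self.terms(), self.UNIVERSE)
        assert {r.term_id for r in results} == {"T1", "T3"}

    def test_p_matches_direct_hypergeometric(self):
        results = enrich(set(self.UNIVERSE[:4]), self.terms(), self.UNIVERSE)
        for r in results:
            assert r.p == pytest.approx(hypergeometric_upper(r.k, r.K, r.n, r.N))

    def test_cutoff_one_flags_everything(self):
        results = enrich(set(self.UNIVERSE[:4]), self.terms(), self.UNIVERSE,
                         p_cutoff=1.0)
        assert all(r.significant for r in results)

    def test_query_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            results = enrich({"G1", "ALIEN"}, self.terms(), self.UNIVERSE)
        assert results[0].n == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"G1"}, [], universe=[])

    def test_planted_term_ranks_first(self):
        from netpharm.synth import SyntheticConfig, gen_gene_sets, gen_ppi

        universe = [f"G{i:04d}" for i in range(150)]
        hits = 0
        for seed in range(20):
            config = SyntheticConfig(seed=seed)
            planted = gen_ppi(config)
            query = set(planted.set_a) | set(planted.set_b_near)
            sets, planted_id = gen_gene_sets(config, query)
            results = enrich(query, sets, universe)
            hits += results[0].term_id == planted_id
        assert hits >= 19


class TestCorrelationClusters:
    def block_matrix(self, sizes, rho=0.8):
        n = sum(sizes)
        matrix = np.zeros((n, n))
        start = 0
        for size in sizes:
            matrix[start:start + size, start:start + size] = rho
            start += size
        np.fill_diagonal(matrix, 1.0)
        return matrix

    def test_two_block_recovery(self):
        genes = [f"G{i}" for i in range(10)]
        matrix = self.block_matrix([5, 5])
        labels = correlation_clusters(matrix, genes, 2)
        assert len({labels[g] for g in genes[:5]}) == 1
        assert len({labels[g] for g in genes[5:]}) == 1
        assert labels[genes[0]] != labels[genes[5]]

    def test_singleton_clusters_at_k_equals_n(self):
        genes = ["A", "B", "C"]
        labels = correlation_clusters(np.eye(3), genes, 3)
        assert len(set(labels.values())) == 3

    def test_equivariant_under_gene_permutation(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(8)]
        matrix = self.block_matrix([4, 4], rho=0.7)
        perm = rng.permutation(8)
        permuted_labels = correlation_clusters(
            matrix[np.ix_(perm, perm)], [genes[i] for i in perm], 2
        )
        labels = correlation_clusters(matrix, genes, 2)
        same = {(g, h) for g in genes for h in genes if labels[g] == labels[h]}
        permuted_same = {(g, h) for g in genes for h in genes
                         if permuted_labels[g] == permuted_labels[h]}
        assert same == permuted_same

    def test_synthetic_block_matrix_recovered(self):
        from netpharm.synth import SyntheticConfig, gen_correlation_matrix

        config = SyntheticConfig(seed=9, correlation_blocks=2)
        genes = [f"G{i:04d}" for i in range(40)]
        matrix, truth = gen_correlation_matrix(config, genes)
        labels = correlation_clusters(matrix, genes, 2)
        partition = {(g, h) for g in genes for h in genes if labels[g] == labels[h]}
        truth_map = dict(zip(genes, truth))
        truth_partition = {(g, h) for g in genes for h in genes
                           if truth_map[g] == truth_map[h]}
        assert partition == truth_partition

    def test_asymmetric_matrix_rejected(self):
        matrix = np.eye(3)
        matrix[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            correlation_clusters(matrix, ["A", "B", "C"], 2)
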