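import networkx as nx
import numpy as np
import pytest

from netpharm.screen import passes_screen
from netpharm.synth import (SyntheticConfig, gen_compound_table,
                            gen_correlation_matrix, gen_disease_genes,
                            gen_gene_sets, gen_ppi, gen_regulation_table,
                            gen_target_associations)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(pass_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(clique_size=2)
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=10)  # too small for planted structure
        with pytest.raises(ValueError):
            SyntheticConfig(enrichment_strength=0.5)


class TestDeterminism:
    def test_same_seed_same_outputs(self):
        a, b = SyntheticConfig(seed=4), SyntheticConfig(seed=4)
        assert gen_compound_table(a) == gen_compound_table(b)
        assert gen_target_associations(a) == gen_target_associations(b)
        assert gen_disease_genes(a) == gen_disease_genes(b)
        assert gen_regulation_table(a) == gen_regulation_table(b)
        ppi_a, ppi_b = gen_ppi(a), gen_ppi(b)
        assert set(ppi_a.network.edges) == set(ppi_b.network.edges)
        assert ppi_a.set_a == ppi_b.set_a and ppi_a.set_b_far == ppi_b.set_b_far

    def test_different_seeds_differ(self):
        one = gen_compound_table(SyntheticConfig(seed=1))
        two = gen_compound_table(SyntheticConfig(seed=2))
        assert one != two


class TestCompounds:
    def test_pass_fraction_limits(self):
        all_pass = gen_compound_table(SyntheticConfig(seed=0, n_compounds=20,
                                                      pass_fraction=1.0))
        assert all(passes_screen(c) for c in all_pass)
        none_pass = gen_compound_table(SyntheticConfig(seed=0, n_compounds=20,
                                                       pass_fraction=0.0))
        assert not any(passes_screen(c) for c in none_pass)

    def test_herb_membership_between_one_and_three(self):
        compounds = gen_compound_table(SyntheticConfig(seed=5))
        assert all(1 <= len(c.herb_ids) <= 3 for c in compounds)
        assert any(len(c.herb_ids) >= 2 for c in compounds)  # shared subset exists


class TestPPI:
    def test_planted_clique_is_complete(self):
        planted = gen_ppi(SyntheticConfig(seed=6, clique_size=5))
        sub = planted.network.subgraph(planted.clique)
        assert sub.number_of_edges() == 10

    def test_near_set_is_one_hop_from_set_a(self):
        planted = gen_ppi(SyntheticConfig(seed=6))
        for node in planted.set_b_near:
            assert min(
                nx.shortest_path_length(planted.network, node, a)
                for a in planted.set_a
            ) == 1

    def test_far_set_is_at_least_three_hops_away(self):
        planted = gen_ppi(SyntheticConfig(seed=6))
        for node in planted.set_b_far:
            assert min(
                nx.shortest_path_length(planted.network, node, a)
                for a in planted.set_a
            ) >= 3

    @pytest.mark.parametrize("seed", range(25))
    def test_connected_for_m_at_least_two(self, seed):
        planted = gen_ppi(SyntheticConfig(seed=seed))
        assert nx.is_connected(planted.network)

    def test_confidences_survive_default_filter(self):
        planted = gen_ppi(SyntheticConfig(seed=2))
        assert all(d["confidence"] > 0.4
                   for _, _, d in planted.network.edges(data=True))


class TestGeneSets:
    def test_term_sizes_within_range(self):
        config = SyntheticConfig(seed=3, term_size_range=(8, 12))
        sets, _ = gen_gene_sets(config, {"G0001", "G0002"})
        assert all(8 <= len(s.genes) <= 12 for s in sets)

    def test_planted_overlap_exceeds_uniform_for_strong_signal(self):
        overlaps_planted, overlaps_rest = [], []
        query = {f"G{i:04d}" for i in range(8)}
        for seed in range(50):
            sets, planted_id = gen_gene_sets(SyntheticConfig(seed=seed), query)
            for s in sets:
                frac = len(s.genes & query) / len(s.genes)
                (overlaps_planted if s.id == planted_id else overlaps_rest).append(frac)
        assert np.mean(overlaps_planted) > 3 * np.mean(overlaps_rest)

    def test_strength_one_means_no_preference(self):
        # with no inflation the planted term's overlap is statistically typical
        query = {f"G{i:04d}" for i in range(8)}
        fracs = []
        for seed in range(100):
            config = SyntheticConfig(seed=seed, enrichment_strength=1.0)
            sets, planted_id = gen_gene_sets(config, query)
            planted = next(s for s in sets if s.id == planted_id)
            fracs.append(len(planted.genes & query) / len(planted.genes))
        assert np.mean(fracs) == pytest.approx(8 / 150, abs=0.02)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            gen_gene_sets(SyntheticConfig(seed=0), set())


class TestCorrelationMatrix:
    def test_unit_diagonal_symmetry_and_bounds(self):
        genes = [f"G{i:04d}" for i in range(40)]
        matrix, _ = gen_correlation_matrix(SyntheticConfig(seed=1), genes)
        assert np.allclose(np.diag(matrix), 1.0)
        assert np.allclose(matrix, matrix.T)
        assert matrix.min() >= -1.0 and matrix.max() <= 1.0

    def test_within_block_mean_near_target(self):
        config = SyntheticConfig(seed=8, correlation_blocks=2, block_correlation=0.8)
        genes = [f"G{i:04d}" for i in range(40)]
        matrix, labels = gen_correlation_matrix(config, genes)
        labels = np.asarray(labels)
        within = []
        for block in (0, 1):
            idx = np.where(labels == block)[0]
            sub = matrix[np.ix_(idx, idx)]
            within.extend(sub[np.triu_indices_from(sub, k=1)].tolist())
        assert np.mean(within) == pytest.approx(0.8, abs=0.05)

    def test_fewer_genes_than_blocks_rejected(self):
        with pytest.raises(ValueError):
            gen_correlation_matrix(SyntheticConfig(seed=0, correlation_blocks=4),
                                   ["A", "B"])


class TestTables:
    def test_disease_scores_positive_and_unique(self):
        records = gen_disease_genes(SyntheticConfig(seed=7))
        scores = [r.score for r in records]
        assert all(s > 0 for s in scores)
        assert len(set(scores)) == len(scores)  # continuous draws never tie
        assert len({(r.gene, r.source) for r in records}) == len(records)

    def test_association_probability_tail_is_uniform(self):
        config = SyntheticConfig(seed=12, n_associations=2000)
        assocs = gen_target_associations(config)
        fraction = sum(a.probability > 0.8 for a in assocs) / len(assocs)
        assert fraction == pytest.approx(0.2, abs=0.03)

    def test_regulation_modes_restricted(self):
        rows = gen_regulation_table(SyntheticConfig(seed=3))
        assert {mode for _, _, mode in rows} <= {"activation", "repression", "unknown"}
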