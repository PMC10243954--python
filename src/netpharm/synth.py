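"""Synthetic input generator with planted ground truth.

Every table and graph the pipeline consumes can be generated here, with
structure planted so each downstream stage has a known answer: a
preferential-attachment interaction network carrying a planted clique (for
complex detection) and a planted proximal pair of gene sets (for the
separation index), a gene-set collection with one over-represented term,
and a block-structured co-expression correlation matrix.

All generators are pure functions of the configuration: a fixed seed gives
byte-identical output.  Child random streams are derived per generator from
the single global seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

from .io import GeneSet
from .screen import TOXICITY_ENDPOINTS, CompoundRecord, ToxicityCall
from .targets import DiseaseGeneRecord, TargetAssociation

__all__ = ["SyntheticConfig", "PlantedPPI", "gen_compound_table", "gen_ppi",
           "gen_gene_sets", "gen_correlation_matrix", "gen_disease_genes",
           "gen_target_associations", "gen_regulation_table", "herb_abbreviations"]

# per-generator stream tags so sub-generators are independent
_TAG_COMPOUNDS = 1
_TAG_PPI = 2
_TAG_GENESETS = 3
_TAG_CORRELATION = 4
_TAG_DISEASE = 5
_TAG_ASSOCIATIONS = 6
_TAG_REGULATION = 7

# probability of an "active" call per toxicity endpoint
_TOXICITY_ACTIVE_P = {
    "hepatotoxicity": 0.05,
    "carcinogenicity": 0.20,
    "immunotoxicity": 0.30,
    "mutagenicity": 0.25,
    "cytotoxicity": 0.30,
    "cardiotoxicity": 0.30,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for every generator.

    Defaults emulate the scale of a small herbal-formula study: ~100
    compounds over 15 botanical drugs with roughly two thirds passing the
    ADMET filter, and a 150-gene scale-free interaction network with a
    planted 5-clique and planted proximal/distal gene-set pairs of size 4.
    """

    seed: int = 0
    n_compounds: int = 100
    pass_fraction: float = 0.67
    n_herbs: int = 15
    n_genes: int = 150
    n_edges_per_node: int = 2
    clique_size: int = 5
    proximal_set_size: int = 4
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 30)
    enrichment_strength: float = 30.0
    correlation_blocks: int = 4
    block_correlation: float = 0.8
    n_associations: int = 2000
    n_disease_genes: int = 200
    n_regulations: int = 300
    n_correlation_samples: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must be in [0, 1]")
        if self.clique_size < 3:
            raise ValueError("clique_size must be >= 3")
        if self.proximal_set_size < 2:
            raise ValueError("proximal_set_size must be >= 2")
        for name in ("n_compounds", "n_herbs", "n_genes", "n_edges_per_node",
                     "n_terms", "correlation_blocks", "n_associations",
                     "n_disease_genes", "n_regulations", "n_correlation_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            raise ValueError("invalid term_size_range")
        if self.enrichment_strength < 1.0:
            raise ValueError("enrichment_strength must be >= 1")
        if not 0.0 < self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in (0, 1)")
        if self.n_genes < self.clique_size + 2 * self.proximal_set_size + 10:
            raise ValueError("n_genes too small for the planted structure")


@dataclass(frozen=True)
class PlantedPPI:
    """A generated network together with its planted ground truth."""

    network: nx.Graph
    clique: frozenset[str]
    set_a: frozenset[str]
    set_b_near: frozenset[str]
    set_b_far: frozenset[str]


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def herb_abbreviations(n_herbs: int) -> dict[str, str]:
    """Deterministic two-letter abbreviations for herb ids HERB01, HERB02, ..."""
    codes = ["".join(pair) for pair in product(string.ascii_uppercase, repeat=2)]
    return {f"HERB{i + 1:02d}": codes[i] for i in range(n_herbs)}


def gen_compound_table(config: SyntheticConfig) -> list[CompoundRecord]:
    """Compound property table with a controlled ADMET pass rate.

    Each compound independently passes the full filter with probability
    ``pass_fraction``; failing compounds violate one or two criteria chosen
    at random (a failed oral-potential draw breaks both the OB and the
    rule-of-five branch).  Herb membership is 1-3 herbs per compound with a
    deliberate shared subset; toxicity labels are drawn per endpoint.
    """
    rng = _rng(config, _TAG_COMPOUNDS)
    herbs = sorted(herb_abbreviations(config.n_herbs))
    compounds: list[CompoundRecord] = []
    for i in range(config.n_compounds):
        n_member = rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1])
        n_member = min(n_member, config.n_herbs)
        herb_ids = frozenset(rng.choice(herbs, size=n_member, replace=False).tolist())

        # passing baseline
        mw = rng.uniform(200, 480)
        alogp = rng.uniform(0.0, 4.5)
        h_donors = int(rng.integers(0, 6))
        h_acceptors = int(rng.integers(0, 10))
        ob = rng.uniform(31, 80)
        caco2 = rng.uniform(0.45, 1.6)
        dl = rng.uniform(0.20, 0.90)
        half_life = rng.uniform(3.5, 24)

        if rng.random() >= config.pass_fraction:
            n_break = 1 + int(rng.random() < 0.3)
            broken = rng.choice(4, size=n_break, replace=False)
            for criterion in broken:
                if criterion == 0:  # oral potential: fail OB and RO5 together
                    ob = rng.uniform(5, 29)
                    mw = rng.uniform(550, 800)
                    alogp = rng.uniform(5.5, 8.0)
                    h_donors = int(rng.integers(6, 10))
                    h_acceptors = int(rng.integers(11, 15))
                elif criterion == 1:
                    caco2 = rng.uniform(-0.5, 0.39)
                elif criterion == 2:
                    dl = rng.uniform(0.01, 0.17)
                else:
                    half_life = rng.uniform(0.5, 2.9)

        toxicity = {}
        for endpoint in TOXICITY_ENDPOINTS:
            active = rng.random() < _TOXICITY_ACTIVE_P[endpoint]
            toxicity[endpoint] = ToxicityCall(
                label="active" if active else "inactive",
                probability=float(rng.uniform(0.5, 1.0)),
            )
        compounds.append(
            CompoundRecord(
                compound_id=f"C{i + 1:04d}",
                name=f"compound-{i + 1}",
                herb_ids=herb_ids,
                mw=float(mw),
                alogp=float(alogp),
                h_donors=h_donors,
                h_acceptors=h_acceptors,
                ob=float(ob),
                caco2=float(caco2),
                dl=float(dl),
                half_life=float(half_life),
                toxicity=toxicity,
                ld50=float(rng.lognormal(mean=6.5, sigma=1.0)),
            )
        )
    return compounds


def gen_ppi(config: SyntheticConfig) -> PlantedPPI:
    """Scale-free interaction network with planted structure.

    Base topology is Barabási-Albert preferential attachment (m edges per
    new node); a clique is planted on the lowest-degree nodes; set_a is
    drawn from peripheral (at-most-median-degree) non-clique nodes,
    set_b_near from the 1-hop neighborhood of set_a and set_b_far from
    nodes at distance >= 3 from every member of set_a.  Edge confidences
    are Uniform(0.41, 1.0), so the default 0.4 filter keeps all edges.
    """
    rng = _rng(config, _TAG_PPI)
    ba_seed = int(np.random.SeedSequence([config.seed, _TAG_PPI, 99]).generate_state(1)[0] % 2**31)
    base = nx.barabasi_albert_graph(config.n_genes, config.n_edges_per_node, seed=ba_seed)
    names = _gene_names(config.n_genes)
    graph = nx.relabel_nodes(base, dict(enumerate(names)))

    by_degree = sorted(graph.nodes, key=lambda n: (graph.degree(n), n))
    clique = frozenset(by_degree[: config.clique_size])
    for a in sorted(clique):
        for b in sorted(clique):
            if a < b:
                graph.add_edge(a, b)

    for a, b in graph.edges:
        graph.edges[a, b]["confidence"] = float(rng.uniform(0.41, 1.0))

    median_degree = float(np.median([d for _, d in graph.degree]))
    periphery = sorted(
        n for n in graph.nodes
        if n not in clique and graph.degree(n) <= median_degree
    )
    size = config.proximal_set_size
    for _ in range(200):
        set_a = frozenset(rng.choice(periphery, size=size, replace=False).tolist())
        neighborhood = sorted(
            set().union(*(set(graph.neighbors(a)) for a in set_a)) - set_a
        )
        # min distance from every node to set_a via multi-source BFS
        lengths = nx.multi_source_dijkstra_path_length(graph, set(set_a), weight=None)
        far = sorted(n for n, d in lengths.items() if d >= 3)
        if len(neighborhood) >= size and len(far) >= size:
            set_b_near = frozenset(rng.choice(neighborhood, size=size, replace=False).tolist())
            set_b_far = frozenset(rng.choice(far, size=size, replace=False).tolist())
            return PlantedPPI(graph, clique, set_a, set_b_near, set_b_far)
    raise ValueError(
        "could not plant proximal/distal sets; increase n_genes or lower proximal_set_size"
    )


def gen_gene_sets(
    config: SyntheticConfig, query: set[str]
) -> tuple[list[GeneSet], str]:
    """Gene-set collection with one planted over-represented term.

    The planted term samples genes with weight ``enrichment_strength`` on
    query genes (weight 1 elsewhere, without replacement); the remaining
    terms sample uniformly.  With strength 1 the planted term is
    indistinguishable from the rest.  Returns the collection and the
    planted term's id.
    """
    if not query:
        raise ValueError("query gene set is empty")
    rng = _rng(config, _TAG_GENESETS)
    universe = np.array(_gene_names(config.n_genes))
    query_mask = np.isin(universe, sorted(query))
    low, high = config.term_size_range
    sets: list[GeneSet] = []
    planted_index = 0
    for t in range(config.n_terms):
        size = int(rng.integers(low, high + 1))
        size = min(size, len(universe))
        if t == planted_index:
            weights = np.where(query_mask, config.enrichment_strength, 1.0)
            weights = weights / weights.sum()
            genes = rng.choice(universe, size=size, replace=False, p=weights)
        else:
            genes = rng.choice(universe, size=size, replace=False)
        sets.append(
            GeneSet(id=f"T{t + 1:03d}", name=f"term-{t + 1}", genes=frozenset(genes.tolist()))
        )
    return sets, sets[planted_index].id


def gen_correlation_matrix(
    config: SyntheticConfig, genes: list[str]
) -> tuple[np.ndarray, list[int]]:
    """Block-structured empirical correlation matrix.

    Genes are split into ``correlation_blocks`` contiguous blocks; profiles
    follow a one-factor-per-block model with loading sqrt(block_correlation)
    so the expected within-block correlation is ``block_correlation`` and
    the between-block correlation is ~0.  Returns the empirical correlation
    of ``n_correlation_samples`` draws and the block label per gene.
    """
    if len(genes) < config.correlation_blocks:
        raise ValueError("fewer genes than correlation blocks")
    rng = _rng(config, _TAG_CORRELATION)
    n = len(genes)
    labels = [int(i * config.correlation_blocks / n) for i in range(n)]
    rho = config.block_correlation
    n_obs = config.n_correlation_samples
    factors = rng.standard_normal((config.correlation_blocks, n_obs))
    data = np.empty((n, n_obs))
    for i, block in enumerate(labels):
        noise = rng.standard_normal(n_obs)
        data[i] = np.sqrt(rho) * factors[block] + np.sqrt(1 - rho) * noise
    matrix = np.corrcoef(data)
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return matrix, labels


def gen_disease_genes(config: SyntheticConfig) -> list[DiseaseGeneRecord]:
    """Score-ranked disease gene list from two sources.

    Scores are heavy-tailed (Pareto) and continuous, so ranks are unique
    with probability 1.  About 70% of records are GeneCards-style scored
    entries; 30% DisGeNET-style, partially overlapping in genes.  Disease
    genes are drawn from the upper 80% of the gene universe so the drug and
    disease target spaces overlap partially, as in a real screen.
    """
    rng = _rng(config, _TAG_DISEASE)
    universe = _gene_names(config.n_genes)[int(0.2 * config.n_genes):]
    records: list[DiseaseGeneRecord] = []
    seen: set[tuple[str, str]] = set()
    while len(records) < config.n_disease_genes:
        gene = str(rng.choice(universe))
        source = "genecards" if rng.random() < 0.7 else "disgenet"
        if (gene, source) in seen:
            continue
        seen.add((gene, source))
        records.append(
            DiseaseGeneRecord(
                gene=gene,
                score=float(1.0 + rng.pareto(1.5)),
                source=source,
            )
        )
    return records


def gen_target_associations(config: SyntheticConfig) -> list[TargetAssociation]:
    """Compound-target association rows with Uniform(0, 1) probabilities.

    Target genes are drawn from the lower 40% of the gene universe: the
    druggable space is a modest, partially disease-overlapping subset of the
    interactome, as in a real target-prediction screen.
    """
    rng = _rng(config, _TAG_ASSOCIATIONS)
    universe = _gene_names(config.n_genes)[: max(10, int(0.4 * config.n_genes))]
    rows = []
    for _ in range(config.n_associations):
        compound = f"C{int(rng.integers(1, config.n_compounds + 1)):04d}"
        gene = str(rng.choice(universe))
        rows.append(
            TargetAssociation(
                compound_id=compound,
                gene=gene,
                probability=float(rng.uniform(0.0, 1.0)),
                source="synthetic",
            )
        )
    return rows


def gen_regulation_table(config: SyntheticConfig) -> list[tuple[str, str, str]]:
    """(regulator, target, mode) rows with modes activation/repression/unknown."""
    rng = _rng(config, _TAG_REGULATION)
    universe = _gene_names(config.n_genes)
    rows: list[tuple[str, str, str]] = []
    for _ in range(config.n_regulations):
        regulator, target = rng.choice(universe, size=2, replace=False)
        mode = str(rng.choice(["activation", "repression", "unknown"], p=[0.4, 0.3, 0.3]))
        rows.append((str(regulator), str(target), mode))
    return rows
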