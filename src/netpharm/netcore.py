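"""PPI graph construction, topology statistics and key-target screening.

The network container is a :class:`networkx.Graph` whose edges carry a
``confidence`` attribute on [0, 1].  Key targets are the nodes whose degree
AND betweenness both exceed twice the network-wide median — a scale-free
hub criterion, so it is insensitive to betweenness normalization.
"""

from __future__ import annotations

import statistics
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import EdgeRecord, canonical_gene
from .targets import CompoundAlias, TargetAssociation

__all__ = [
    "build_network",
    "average_degree",
    "average_clustering",
    "centralities",
    "key_targets",
    "compound_degree_ranking",
    "tf_subnetwork",
    "network_stats",
]

REGULATION_MODES = ("activation", "repression", "unknown")


def build_network(
    edges: Iterable[EdgeRecord],
    min_confidence: float = 0.4,
    restrict_to: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the confidence-filtered interaction graph.

    Keeps edges with confidence strictly above ``min_confidence`` whose
    endpoints both lie in ``restrict_to`` (when given); permitted nodes with
    no surviving edge are retained as isolated nodes.
    """
    allowed = None if restrict_to is None else {canonical_gene(g) for g in restrict_to}
    graph = nx.Graph()
    if allowed is not None:
        graph.add_nodes_from(sorted(allowed))
    for edge in edges:
        a, b = canonical_gene(edge.node_a), canonical_gene(edge.node_b)
        if a == b:
            continue
        if edge.confidence <= min_confidence:
            continue
        if allowed is not None and (a not in allowed or b not in allowed):
            continue
        graph.add_edge(a, b, confidence=edge.confidence)
    return graph


def average_degree(network: nx.Graph) -> float:
    """Mean node degree, 2|E| / |V|."""
    if network.number_of_nodes() == 0:
        raise ValueError("average degree of an empty network is undefined")
    return 2.0 * network.number_of_edges() / network.number_of_nodes()


def average_clustering(network: nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes (degree-<2 nodes
    contribute 0)."""
    if network.number_of_nodes() == 0:
        raise ValueError("average clustering of an empty network is undefined")
    return nx.average_clustering(network, count_zeros=True)


def centralities(network: nx.Graph) -> dict[str, tuple[int, float]]:
    """Exact degree and exact unnormalized shortest-path betweenness per node.

    Betweenness is computed on the unweighted graph; endpoints are excluded
    from their own paths.
    """
    betweenness = nx.betweenness_centrality(network, normalized=False)
    return {
        node: (network.degree(node), betweenness[node]) for node in network.nodes
    }


def key_targets(table: Mapping[str, tuple[int, float]]) -> set[str]:
    """Nodes whose degree and betweenness both strictly exceed twice the
    respective median over all nodes."""
    if not table:
        raise ValueError("centrality table is empty")
    degrees = [d for d, _ in table.values()]
    betweennesses = [b for _, b in table.values()]
    degree_cut = 2.0 * statistics.median(degrees)
    betweenness_cut = 2.0 * statistics.median(betweennesses)
    return {
        node
        for node, (degree, betweenness) in table.items()
        if degree > degree_cut and betweenness > betweenness_cut
    }


def compound_degree_ranking(
    assocs: Iterable[TargetAssociation],
    common: Iterable[str],
    aliases: Sequence[CompoundAlias],
) -> list[tuple[str, str, int]]:
    """Rank compounds by the number of common-target genes they hit.

    Returns (compound_id, alias label, degree) sorted by degree descending,
    ties broken by alias label ascending.  The result is invariant to the
    order of the association rows.
    """
    common_set = {canonical_gene(g) for g in common}
    label_of = {alias.compound_id: alias.label for alias in aliases}
    hits: dict[str, set[str]] = {cid: set() for cid in label_of}
    for assoc in assocs:
        gene = canonical_gene(assoc.gene)
        if gene in common_set and assoc.compound_id in hits:
            hits[assoc.compound_id].add(gene)
    ranking = [
        (cid, label_of[cid], len(genes)) for cid, genes in hits.items()
    ]
    ranking.sort(key=lambda item: (-item[2], item[1]))
    return ranking


def tf_subnetwork(
    regulations: Iterable[tuple[str, str, str]],
    genes: Iterable[str],
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Restrict a (regulator, target, mode) table to a gene set.

    Keeps rows where both regulator and target are in ``genes``; modes must
    be one of activation / repression / unknown.  Also reports per-regulator
    out-degree among the kept edges.
    """
    gene_set = {canonical_gene(g) for g in genes}
    kept: list[tuple[str, str, str]] = []
    out_degree: dict[str, int] = {}
    for regulator, target, mode in regulations:
        if mode not in REGULATION_MODES:
            raise ValueError(f"unknown regulation mode {mode!r}")
        regulator, target = canonical_gene(regulator), canonical_gene(target)
        if regulator in gene_set and target in gene_set:
            kept.append((regulator, target, mode))
            out_degree[regulator] = out_degree.get(regulator, 0) + 1
    return kept, out_degree


def network_stats(network: nx.Graph) -> dict[str, float]:
    """Node count, edge count, average degree and average local clustering."""
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "average_degree": average_degree(network),
        "average_clustering": average_clustering(network),
    }
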