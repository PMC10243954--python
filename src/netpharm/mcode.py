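"""Molecular Complex Detection (MCODE).

A seed-and-grow algorithm for dense subgraphs: each node is weighted by the
density of the highest k-core of its closed neighborhood times that core's
k; complexes grow greedily from the highest-weighted unassigned seed,
admitting neighbors whose weight is within ``node_score_cutoff`` of the
seed's.  An optional haircut trims singly-connected members (iterated to
the 2-core of the complex) and optional fluff adds dense boundary
neighborhoods.  Complex score is induced density times member count, so a
clique K_n scores n.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["MCODEParams", "MCODEComplex", "mcode_node_scores", "mcode_find_complexes"]


@dataclass(frozen=True)
class MCODEParams:
    """MCODE tuning knobs; defaults mirror the Cytoscape plugin's.

    ``degree_cutoff``: nodes below this degree are never scored or seeded.
    ``node_score_cutoff``: growth admits neighbors scoring at least
    ``seed_score * (1 - node_score_cutoff)``.
    ``k_core``: a complex must contain a core of at least this order.
    """

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.degree_cutoff < 2 or self.k_core < 2:
            raise ValueError("degree_cutoff and k_core must both be >= 2")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")


@dataclass(frozen=True)
class MCODEComplex:
    """A detected complex: its members, its seed node and density x size score."""

    members: frozenset[str]
    score: float
    seed: str


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_node_scores(
    network: nx.Graph, params: MCODEParams = MCODEParams()
) -> dict[str, float]:
    """Vertex weighting: density of the highest k-core of the node's closed
    neighborhood, multiplied by the core's k; 0 for nodes with degree below
    ``degree_cutoff``."""
    scores: dict[str, float] = {}
    for node in network.nodes:
        if network.degree(node) < params.degree_cutoff:
            scores[node] = 0.0
            continue
        closed = set(network.neighbors(node)) | {node}
        neighborhood = network.subgraph(closed)
        core_numbers = nx.core_number(neighborhood)
        k = max(core_numbers.values())
        if k == 0:
            scores[node] = 0.0
            continue
        core = neighborhood.subgraph(
            [n for n, c in core_numbers.items() if c >= k]
        )
        scores[node] = _density(core) * k
    return scores


def _two_core_trim(graph: nx.Graph, members: set[str]) -> set[str]:
    # Iterated removal of singly-connected members == 2-core of the complex.
    sub = nx.Graph(graph.subgraph(members))
    while True:
        leaves = [n for n in sub.nodes if sub.degree(n) < 2]
        if not leaves:
            return set(sub.nodes)
        sub.remove_nodes_from(leaves)


def mcode_find_complexes(
    network: nx.Graph, params: MCODEParams = MCODEParams()
) -> list[MCODEComplex]:
    """Detect complexes, highest score first.

    Each node belongs to at most one complex; seeds are taken in descending
    node-score order (ties broken by node name ascending) and complexes must
    contain a ``k_core``-core after post-processing.
    """
    scores = mcode_node_scores(network, params)
    assigned: set[str] = set()
    complexes: list[MCODEComplex] = []
    for seed in sorted(scores, key=lambda n: (-scores[n], n)):
        if seed in assigned or scores[seed] <= 0.0:
            continue
        threshold = scores[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop()
            for neighbor in network.neighbors(current):
                if neighbor in members or neighbor in assigned:
                    continue
                if scores[neighbor] >= threshold:
                    members.add(neighbor)
                    frontier.append(neighbor)
        assigned |= members

        final = set(members)
        if params.haircut:
            final = _two_core_trim(network, final)
        if params.fluff:
            for node in sorted(members):
                closed = set(network.neighbors(node)) | {node}
                if _density(network.subgraph(closed)) > params.fluff_density_cutoff:
                    final |= closed - assigned
        if len(final) < 2:
            continue
        induced = network.subgraph(final)
        if not nx.is_connected(induced):
            # keep the seed's component only
            final = nx.node_connected_component(induced, seed) if seed in final else set()
            if len(final) < 2:
                continue
            induced = network.subgraph(final)
        if max(nx.core_number(induced).values()) < params.k_core:
            continue
        complexes.append(
            MCODEComplex(
                members=frozenset(final),
                score=_density(induced) * induced.number_of_nodes(),
                seed=seed,
            )
        )
    complexes.sort(key=lambda c: (-c.score, c.seed))
    return complexes
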