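"""Hypergeometric over-representation testing and correlation clustering.

Each term is tested with the upper tail of the hypergeometric distribution
(probability of observing at least k query genes in a term of size K when
drawing n genes from a universe of N), with Benjamini-Hochberg adjustment
reported alongside the raw p-values.  Correlation clustering cuts an
average-linkage dendrogram on the distance 1 - correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, canonical_gene

__all__ = [
    "EnrichmentResult",
    "hypergeometric_upper",
    "bh_adjust",
    "enrich",
    "correlation_clusters",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome.

    k = overlap, K = term size, n = query size, N = universe size, p the
    raw upper-tail probability and p_adj its BH adjustment.
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool
    overlap_genes: frozenset[str]


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), evaluated stably."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P[X >= k]; scipy works in log space internally.
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def enrich(
    query: Iterable[str],
    terms: Iterable[GeneSet],
    universe: Iterable[str] | None = None,
    p_cutoff: float = 0.005,
) -> list[EnrichmentResult]:
    """Test every term against the query, sorted by raw p ascending.

    The universe defaults to the union of all term genes.  Query genes
    outside the universe are dropped with a warning; terms are intersected
    with the universe; terms with no overlap (k = 0) are omitted.  Results
    with p < ``p_cutoff`` (default 0.005) are flagged significant; the BH
    column is always reported.
    """
    terms = list(terms)
    if universe is None:
        universe_set = set().union(*(t.genes for t in terms)) if terms else set()
    else:
        universe_set = {canonical_gene(g) for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = {canonical_gene(g) for g in query}
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query_set -= outside

    N = len(universe_set)
    n = len(query_set)
    rows: list[tuple[GeneSet, frozenset[str], int, float]] = []
    for term in terms:
        term_genes = term.genes & universe_set
        overlap = frozenset(term_genes & query_set)
        if not overlap:
            continue
        p = hypergeometric_upper(len(overlap), len(term_genes), n, N)
        rows.append((term, frozenset(term_genes), len(overlap), p))

    adjusted = bh_adjust([p for *_, p in rows])
    results = [
        EnrichmentResult(
            term_id=term.id,
            term_name=term.name,
            k=k,
            K=len(term_genes),
            n=n,
            N=N,
            p=p,
            p_adj=p_adj,
            significant=p < p_cutoff,
            overlap_genes=frozenset(g for g in term_genes if g in query_set),
        )
        for (term, term_genes, k, p), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def correlation_clusters(
    matrix: np.ndarray, genes: Sequence[str], n_clusters: int
) -> dict[str, int]:
    """Partition genes by average-linkage hierarchical clustering on the
    distance 1 - correlation, cut to ``n_clusters``.

    Cluster ids are renumbered 1..n in order of each cluster's first gene,
    so the partition is equivariant under permutations of the gene order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if matrix.shape[0] != len(genes):
        raise ValueError("gene list length must match matrix dimension")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("correlation matrix is not symmetric")
    if not 1 <= n_clusters <= len(genes):
        raise ValueError("n_clusters must be between 1 and the number of genes")

    order = np.argsort(np.asarray(genes, dtype=object))
    sorted_genes = [genes[i] for i in order]
    distance = 1.0 - matrix[np.ix_(order, order)]
    np.fill_diagonal(distance, 0.0)
    condensed = squareform(distance, checks=False)
    tree = linkage(condensed, method="average")
    raw_labels = fcluster(tree, t=n_clusters, criterion="maxclust")

    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for gene, raw in zip(sorted_genes, raw_labels):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        assignment[gene] = relabel[raw]
    return assignment
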