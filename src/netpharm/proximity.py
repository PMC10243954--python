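"""Network proximity between two gene sets, with a random-group null.

The separation index of Menche et al. is

    s_AB = d_AB - (d_AA + d_BB) / 2,

where d_AB is the mean over members of each set of the shortest-path
distance to the *closest* member of the other set, and d_AA (d_BB) the mean
distance of each member to its closest same-set neighbor.  s_AB < 0 means
the two sets occupy overlapping network neighborhoods.  The null model
samples random gene groups of matched size and reports the mean and
standard deviation of their index against the fixed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ProximityResult",
    "closest_distance_between",
    "within_distance",
    "proximity_index",
    "null_control",
]


@dataclass(frozen=True)
class ProximityResult:
    """Eq. quantities s_AB, d_AB, d_AA, d_BB plus an optional null summary."""

    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float
    null_mean: float | None = None
    null_sd: float | None = None
    n_null: int = 0
    seed: int | None = None


DistanceMap = dict[str, dict[str, int]]


def _distances_from(network: nx.Graph, sources: set[str], cache: DistanceMap | None) -> DistanceMap:
    result: DistanceMap = {}
    for source in sources:
        if cache is not None and source in cache:
            result[source] = cache[source]
        else:
            result[source] = nx.single_source_shortest_path_length(network, source)
            if cache is not None:
                cache[source] = result[source]
    return result


def _check_members(network: nx.Graph, members: set[str], label: str) -> None:
    missing = sorted(m for m in members if m not in network)
    if missing:
        raise ValueError(f"{label}: node(s) not in network: {', '.join(missing)}")


def closest_distance_between(
    network: nx.Graph,
    set_a: set[str],
    set_b: set[str],
    _cache: DistanceMap | None = None,
) -> float:
    """d_AB: average over all members of both sets of the unweighted
    shortest-path distance to the closest member of the opposite set.

    A gene belonging to both sets contributes distance 0.  Raises when a
    member cannot reach the opposite set.
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    _check_members(network, set_a, "set_a")
    _check_members(network, set_b, "set_b")
    dist_a = _distances_from(network, set_a, _cache)
    dist_b = _distances_from(network, set_b, _cache)

    total = 0.0
    unreachable: list[str] = []
    for a in set_a:
        reach = [dist_a[a][b] for b in set_b if b in dist_a[a]]
        if not reach:
            unreachable.append(a)
            continue
        total += min(reach)
    for b in set_b:
        reach = [dist_b[b][a] for a in set_a if a in dist_b[b]]
        if not reach:
            unreachable.append(b)
            continue
        total += min(reach)
    if unreachable:
        raise ValueError(
            f"node(s) unreachable from the other set: {', '.join(sorted(set(unreachable)))}"
        )
    return total / (len(set_a) + len(set_b))


def within_distance(
    network: nx.Graph, set_a: set[str], _cache: DistanceMap | None = None
) -> float:
    """d_AA: mean distance of each member to its closest *other* member."""
    if len(set_a) < 2:
        raise ValueError("within-set distance needs at least 2 genes")
    _check_members(network, set_a, "set")
    dist = _distances_from(network, set_a, _cache)
    total = 0.0
    for a in set_a:
        reach = [dist[a][other] for other in set_a if other != a and other in dist[a]]
        if not reach:
            raise ValueError(f"node {a!r} unreachable from the rest of its set")
        total += min(reach)
    return total / len(set_a)


def proximity_index(
    network: nx.Graph,
    set_a: set[str],
    set_b: set[str],
    _cache: DistanceMap | None = None,
) -> ProximityResult:
    """s_AB = d_AB - (d_AA + d_BB) / 2."""
    d_ab = closest_distance_between(network, set_a, set_b, _cache)
    d_aa = within_distance(network, set_a, _cache)
    d_bb = within_distance(network, set_b, _cache)
    return ProximityResult(
        s_ab=d_ab - (d_aa + d_bb) / 2.0, d_ab=d_ab, d_aa=d_aa, d_bb=d_bb
    )


def null_control(
    network: nx.Graph,
    set_a: set[str],
    group_size: int,
    n_groups: int = 50,
    seed: int = 0,
    eligible: set[str] | None = None,
) -> tuple[float, float, list[float]]:
    """Random-group null for the proximity index.

    Samples ``n_groups`` gene groups of ``group_size`` uniformly without
    replacement from ``eligible`` (default: all network nodes outside
    ``set_a``), computes each group's s against ``set_a`` and returns the
    null mean, standard deviation and per-group values.  Fully reproducible
    from ``seed``.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    pool = sorted(eligible if eligible is not None else set(network.nodes) - set_a)
    if len(pool) < group_size:
        raise ValueError(
            f"only {len(pool)} eligible nodes for groups of size {group_size}"
        )
    rng = np.random.default_rng(seed)
    cache: DistanceMap = {}
    values: list[float] = []
    for _ in range(n_groups):
        group = set(rng.choice(pool, size=group_size, replace=False).tolist())
        values.append(proximity_index(network, set_a, group, cache).s_ab)
    # the sample standard deviation is undefined for a single group
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return float(np.mean(values)), sd, values
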