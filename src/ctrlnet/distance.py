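"""Anatomical-distance statistics for a connectivity component.

A component of hypoconnected edges is profiled by (a) the share of
long-range (> 75 mm) and inter-network edges, (b) a two-sample t-test of
its edge distances against all remaining region pairs, and (c) a
resampling null: random edge sets constrained to be connected and to
match the component's edge and node counts, drawn from the complete
graph on the atlas (or any restricted edge universe), whose mean
distances form the empirical null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .atlas import EdgeDistanceTable

EdgeSet = list[tuple[int, int]]


class DistanceError(ValueError):
    pass


def _canonical(edges) -> EdgeSet:
    out = []
    seen = set()
    for i, j in edges:
        if i == j:
            raise DistanceError(f"self-edge ({i}, {j}) not allowed")
        e = (min(i, j), max(i, j))
        if e in seen:
            raise DistanceError(f"duplicate edge {e}")
        seen.add(e)
        out.append(e)
    return out


@dataclass
class ComponentDistanceSummary:
    n_edges: int
    n_nodes: int
    mean_distance: float
    distances: np.ndarray = field(repr=False)
    n_long_range: int = 0
    prop_long_range: float = 0.0
    n_inter_network: int = 0
    prop_inter_network: float = 0.0


def component_distance_summary(component, dist: EdgeDistanceTable,
                               distances: np.ndarray | None = None,
                               inter_network: np.ndarray | None = None,
                               ) -> ComponentDistanceSummary:
    """Distance and network profile of an edge set.

    ``distances`` / ``inter_network`` override the atlas-derived values
    per edge (used when an authoritative published distance or category
    column accompanies the component).
    """
    edges = _canonical(component)
    if not edges:
        raise DistanceError("component is empty")
    n = dist.atlas.n_regions
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise DistanceError(f"edge ({i}, {j}) outside the {n}-region atlas")
    if distances is None:
        distances = np.array([dist.distance[i, j] for i, j in edges])
    else:
        distances = np.asarray(distances, dtype=float)
    if inter_network is None:
        inter = np.array([dist.inter_network[i, j] for i, j in edges])
    else:
        inter = np.asarray(inter_network, dtype=bool)
    long_range = distances > 75.0
    nodes = {v for e in edges for v in e}
    return ComponentDistanceSummary(
        n_edges=len(edges),
        n_nodes=len(nodes),
        mean_distance=float(distances.mean()),
        distances=distances,
        n_long_range=int(long_range.sum()),
        prop_long_range=float(long_range.mean()),
        n_inter_network=int(inter.sum()),
        prop_inter_network=float(inter.mean()),
    )


def distance_ttest(component, dist: EdgeDistanceTable) -> tuple[float, float]:
    """Pooled-variance two-sample t of component vs complement distances.

    Returns (t, two-tailed p); sign is component-minus-complement.
    """
    edges = set(_canonical(component))
    if len(edges) < 2:
        raise DistanceError("component needs at least 2 edges")
    comp_d, rest_d = [], []
    for i, j in dist.pairs():
        (comp_d if (i, j) in edges else rest_d).append(dist.distance[i, j])
    if len(rest_d) < 2:
        raise DistanceError("complement needs at least 2 edges")
    t, p = stats.ttest_ind(comp_d, rest_d, equal_var=True)
    if not np.isfinite(t):
        raise DistanceError("degenerate variance in distance samples")
    return float(t), float(p)


def _feasible(m_edges: int, n_nodes: int, n_atlas: int) -> None:
    if n_nodes > n_atlas:
        raise DistanceError(f"n_nodes={n_nodes} exceeds atlas size {n_atlas}")
    if not (n_nodes - 1 <= m_edges <= n_nodes * (n_nodes - 1) // 2):
        raise DistanceError(
            f"no connected graph with {m_edges} edges on {n_nodes} nodes exists"
        )


def sample_connected_edge_set(n_atlas: int, m_edges: int, n_nodes: int,
                              seed=0, universe: EdgeSet | None = None,
                              max_rejections: int = 10**6,
                              _rejections: list | None = None) -> EdgeSet:
    """Draw a connected edge set with exact edge and node counts.

    Growth sampling: start from a uniformly chosen universe edge, then
    repeatedly add a uniformly random unused universe edge incident to
    the current node set; accept the draw iff the final set spans exactly
    ``n_nodes`` nodes, otherwise reject and restart.  ``universe``
    defaults to all pairs of the complete graph on ``n_atlas`` nodes.
    Not exactly uniform over all connected (m, n) subgraphs; see
    :func:`enumerate_connected_edge_sets` for an exhaustive reference on
    tiny universes.
    """
    _feasible(m_edges, n_nodes, n_atlas)
    if universe is None:
        universe = [(i, j) for i in range(n_atlas) for j in range(i + 1, n_atlas)]
    else:
        universe = _canonical(universe)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    u = np.array([e[0] for e in universe])
    v = np.array([e[1] for e in universe])
    for attempt in range(max_rejections):
        chosen = np.zeros(len(universe), dtype=bool)
        in_set = np.zeros(n_atlas, dtype=bool)
        first = int(rng.integers(len(universe)))
        chosen[first] = True
        in_set[u[first]] = in_set[v[first]] = True
        n_in = 2
        ok = True
        for _step in range(m_edges - 1):
            cand = np.flatnonzero((in_set[u] | in_set[v]) & ~chosen)
            if cand.size == 0:
                ok = False
                break
            e = int(cand[rng.integers(cand.size)])
            chosen[e] = True
            for node in (u[e], v[e]):
                if not in_set[node]:
                    in_set[node] = True
                    n_in += 1
            if n_in > n_nodes:
                ok = False
                break
        if ok and n_in == n_nodes:
            if _rejections is not None:
                _rejections.append(attempt)
            idx = np.flatnonzero(chosen)
            return [(int(u[i]), int(v[i])) for i in idx]
    raise DistanceError(
        f"rejection limit {max_rejections} exceeded sampling a connected "
        f"({m_edges}-edge, {n_nodes}-node) set"
    )


def enumerate_connected_edge_sets(universe: EdgeSet, m_edges: int,
                                  n_nodes: int) -> list[EdgeSet]:
    """All connected edge sets with exact counts (tiny universes only)."""
    universe = _canonical(universe)
    out = []
    for combo in combinations(universe, m_edges):
        nodes = {v for e in combo for v in e}
        if len(nodes) != n_nodes:
            continue
        # connectivity by union-find
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for i, j in combo:
            parent[find(i)] = find(j)
        if len({find(v) for v in nodes}) == 1:
            out.append(list(combo))
    return out


@dataclass
class DistanceNullResult:
    observed_mean: float
    null_means: np.ndarray = field(repr=False)
    empirical_p: float = float("nan")
    n_rejected: int = 0


def distance_resampling_test(component, dist: EdgeDistanceTable,
                             n_iter: int = 10_000, seed: int = 0,
                             universe: EdgeSet | None = None,
                             observed_distances: np.ndarray | None = None,
                             ) -> DistanceNullResult:
    """Connected-component-matched resampling null for the mean distance.

    Draws ``n_iter`` random connected edge sets matching the component's
    edge and node counts and compares mean anatomical distances;
    ``empirical_p`` is the fraction of null means strictly larger than
    the observed mean (small p: the component is unusually long-range).
    """
    if n_iter < 1:
        raise DistanceError(f"n_iter must be >= 1, got {n_iter}")
    summary = component_distance_summary(component, dist,
                                         distances=observed_distances)
    rng = np.random.default_rng(seed)
    d = dist.distance
    null_means = np.empty(n_iter)
    rejections: list = []
    for k in range(n_iter):
        edges = sample_connected_edge_set(
            dist.atlas.n_regions, summary.n_edges, summary.n_nodes,
            seed=rng, universe=universe, _rejections=rejections)
        idx = np.array(edges)
        null_means[k] = d[idx[:, 0], idx[:, 1]].mean()
    p = float((null_means > summary.mean_distance).mean())
    return DistanceNullResult(observed_mean=summary.mean_distance,
                              null_means=null_means, empirical_p=p,
                              n_rejected=int(sum(rejections)))
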