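"""Topological measures of binary brain graphs.

Global measures: global efficiency E_glob (mean inverse shortest path
length over ordered node pairs), local efficiency E_loc (mean over nodes
of the global efficiency of each node's neighbour subgraph) and
modularity Q maximized over partitions,

    Q(p) = sum_s [ l_s / L - (d_s / 2L)^2 ],

with l_s the intra-module edge count, d_s the module degree sum and L
the total edge count.  Module detection uses Newman's spectral
(leading-eigenvector) bisection with Kernighan-Lin-style fine-tuning.

Nodal measures: degree k_i, nodal efficiency e_i and betweenness b_i
(sum over unordered pairs m < n, m != i != n, of the fraction of m-n
geodesics passing through i).

Global measures are normalized by the mean of the same measures over
degree-preserving rewired random graphs (1/infinity = 0 for disconnected
pairs throughout; components of disconnected graphs are treated jointly,
with the modularity null term computed on the full graph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import BinaryGraph


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shortest paths and geodesic counts


@dataclass
class ShortestPathData:
    """Hop distances d_ij (inf for disconnected pairs) and geodesic
    counts sigma_mn for every ordered pair."""

    dist: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)

    def pass_through(self, i: int) -> np.ndarray:
        """sigma_mn(i): number of m-n geodesics passing through node i.

        Zero whenever m == i or n == i or the pair is disconnected.
        """
        d, s = self.dist, self.sigma
        with np.errstate(invalid="ignore"):
            on_path = d[:, i][:, None] + d[i, :][None, :] == d
        on_path &= np.isfinite(d)
        out = np.where(on_path, s[:, i][:, None] * s[i, :][None, :], 0.0)
        out[i, :] = 0.0
        out[:, i] = 0.0
        np.fill_diagonal(out, 0.0)
        return out


def shortest_paths(g: BinaryGraph) -> ShortestPathData:
    """BFS-exact hop distances and geodesic counts for all pairs."""
    a = g.adjacency.astype(bool)
    n = g.n_nodes
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        level = 0
        while frontier.any():
            level += 1
            # counts of geodesics arriving from the current frontier
            arriving = sigma[s] @ (a & frontier[:, None])
            newly = (arriving > 0) & np.isinf(dist[s])
            dist[s, newly] = level
            sigma[s, newly] = arriving[newly]
            frontier = newly
    return ShortestPathData(dist=dist, sigma=sigma)


# ---------------------------------------------------------------------------
# global measures


def _efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BinaryGraph, sp: ShortestPathData | None = None) -> float:
    """E_glob: mean of 1/d_ij over ordered pairs (disconnected pairs add 0)."""
    if sp is None:
        sp = shortest_paths(g)
    return _efficiency_from_dist(sp.dist)


def local_efficiency(g: BinaryGraph) -> float:
    """E_loc: mean over nodes of E_glob of the neighbour-induced subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    a = g.adjacency
    n = g.n_nodes
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = BinaryGraph(a[np.ix_(nbrs, nbrs)])
        total += global_efficiency(sub)
    return total / n


def modularity_of_partition(g: BinaryGraph, partition: np.ndarray) -> float:
    """Q of a given node-to-module assignment (0-based integer labels)."""
    partition = np.asarray(partition)
    if partition.shape != (g.n_nodes,):
        raise MetricsError("partition must assign every node")
    a = g.adjacency
    L = g.n_edges
    if L == 0:
        raise MetricsError("modularity undefined for an edgeless graph")
    deg = g.degrees
    q = 0.0
    for s in range(int(partition.max()) + 1):
        members = partition == s
        if not members.any():
            raise MetricsError(f"module {s} is empty")
        l_s = a[np.ix_(members, members)].sum() / 2
        d_s = deg[members].sum()
        q += l_s / L - (d_s / (2 * L)) ** 2
    return float(q)


@dataclass
class ModularityPartition:
    partition: np.ndarray
    q: float

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.partition).size)


def _leading_eigenvector(b: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(b)
    return float(vals[-1]), vecs[:, -1]


def _bisect(b_full: np.ndarray, L: int, nodes: np.ndarray) -> np.ndarray | None:
    """One spectral bisection of the node group, or None if indivisible."""
    bg = b_full[np.ix_(nodes, nodes)]
    # generalized modularity matrix: remove row sums on the diagonal
    bg = bg - np.diag(bg.sum(axis=1))
    lam, u = _leading_eigenvector(bg)
    if lam <= 1e-10:
        return None
    s = np.where(u >= 0, 1.0, -1.0)  # zero components tie toward module 1
    # Kernighan-Lin style fine-tuning: greedy single-node flips
    def dq_of(svec):
        return svec @ bg @ svec / (4.0 * L)
    best_q = dq_of(s)
    improved = True
    while improved:
        improved = False
        moved = np.zeros(len(s), dtype=bool)
        trial = s.copy()
        trail_best_q, trail_best_s = best_q, None
        for _ in range(len(s)):
            gains = np.full(len(s), -np.inf)
            base = trial @ bg
            for v in np.flatnonzero(~moved):
                # flipping v changes dQ by -4 s_v (B s)_v / 4L + 4 B_vv / 4L
                gains[v] = (-trial[v] * base[v] + bg[v, v]) / L
            v = int(np.argmax(gains))
            trial[v] = -trial[v]
            moved[v] = True
            q_now = dq_of(trial)
            if q_now > trail_best_q + 1e-12:
                trail_best_q, trail_best_s = q_now, trial.copy()
        if trail_best_s is not None:
            s, best_q = trail_best_s, trail_best_q
            improved = True
    if best_q <= 1e-10 or np.all(s == s[0]):
        return None
    return s > 0


def _refine(a: np.ndarray, L: int, deg: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Greedy node moves between existing modules until Q stops improving."""
    partition = partition.copy()
    improved = True
    while improved:
        improved = False
        for v in range(len(partition)):
            labels = np.unique(partition)
            current = partition[v]
            if (partition == current).sum() == 1 and labels.size == 2:
                continue  # don't empty a module into a trivial merge loop
            # dQ of moving v from module c to module t:
            #   (e_vt - e_vc)/L - deg_v*(d_t - d_c + deg_v)/(2 L^2)
            best_gain, best_t = 1e-12, None
            e_v = np.array([a[v, partition == t].sum() for t in labels])
            d_mod = np.array([deg[partition == t].sum() for t in labels])
            ci = int(np.flatnonzero(labels == current)[0])
            for ti, t in enumerate(labels):
                if t == current:
                    continue
                gain = (e_v[ti] - e_v[ci]) / L - deg[v] * (
                    d_mod[ti] - (d_mod[ci] - deg[v])) / (2.0 * L * L)
                if gain > best_gain:
                    best_gain, best_t = gain, t
            if best_t is not None:
                partition[v] = best_t
                improved = True
    # relabel compactly in order of first appearance
    _, compact = np.unique(partition, return_inverse=True)
    return compact


def detect_modules(g: BinaryGraph, seed: int = 0) -> ModularityPartition:
    """Maximize Q by recursive spectral bisection plus fine-tuning.

    Deterministic: the spectral recursion and greedy refinement involve
    no random choices; ``seed`` is accepted for interface uniformity.
    """
    del seed
    L = g.n_edges
    if L == 0:
        raise MetricsError("cannot detect modules in an edgeless graph")
    a = g.adjacency.astype(float)
    deg = g.degrees.astype(float)
    b_full = a - np.outer(deg, deg) / (2.0 * L)
    partition = np.zeros(g.n_nodes, dtype=int)
    next_label = 1
    stack = [0]
    while stack:
        label = stack.pop()
        nodes = np.flatnonzero(partition == label)
        if nodes.size < 2:
            continue
        split = _bisect(b_full, L, nodes)
        if split is None:
            continue
        partition[nodes[split]] = next_label
        stack.extend([label, next_label])
        next_label += 1
    partition = _refine(g.adjacency, L, g.degrees, partition)
    return ModularityPartition(partition=partition,
                               q=modularity_of_partition(g, partition))


# ---------------------------------------------------------------------------
# nodal measures


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


def nodal_metrics(g: BinaryGraph, sp: ShortestPathData | None = None) -> NodalMetrics:
    """Degree k_i, nodal efficiency e_i and betweenness b_i per node."""
    if sp is None:
        sp = shortest_paths(g)
    n = g.n_nodes
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp.dist
    np.fill_diagonal(inv, 0.0)
    e = inv.sum(axis=1) / (n - 1)
    btw = np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(n):
            frac = sp.pass_through(i) / sp.sigma
            frac[~np.isfinite(frac)] = 0.0
            btw[i] = np.triu(frac, k=1).sum()
    return NodalMetrics(degree=g.degrees, efficiency=e, betweenness=btw)


# ---------------------------------------------------------------------------
# degree-preserving nulls and normalization


def rewire_null(g: BinaryGraph, n_nulls: int = 100, seed: int = 0,
                swaps_per_edge: int = 10) -> list[BinaryGraph]:
    """Degree-preserving random graphs by double-edge swaps.

    Each null attempts ``swaps_per_edge * n_edges`` swaps; a swap replaces
    edges (a,b),(c,d) with (a,d),(c,b) when this creates neither a
    self-loop nor a multi-edge, leaving every degree unchanged.
    """
    if g.n_edges < 2:
        raise MetricsError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    nulls = []
    any_swapped = False
    for _ in range(n_nulls):
        adj = g.adjacency.astype(bool).copy()
        edges = np.column_stack(np.nonzero(np.triu(adj)))
        m = len(edges)
        attempts = swaps_per_edge * m
        pick = rng.integers(0, m, size=(attempts, 2))
        flip = rng.random(attempts) < 0.5
        for t in range(attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip[t]:
                c, d = d, c
            # propose (a,d) and (c,b)
            if a == d or c == b:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[b, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b] = adj[b, c] = True
            edges[e1] = sorted((a, d))
            edges[e2] = sorted((c, b))
            any_swapped = True
        nulls.append(BinaryGraph(adj.astype(np.int8),
                                 threshold_kind=g.threshold_kind,
                                 threshold_value=g.threshold_value,
                                 subject_id=g.subject_id))
    if not any_swapped:
        warnings.warn("graph too constrained to rewire; returning copies",
                      stacklevel=2)
    return nulls


@dataclass
class GlobalMetrics:
    e_glob: float
    e_loc: float
    q_max: float
    n_modules: int
    density: float
    normalized_e_glob: float = float("nan")
    normalized_e_loc: float = float("nan")
    normalized_q: float = float("nan")


def global_metrics(g: BinaryGraph, seed: int = 0) -> GlobalMetrics:
    sp = shortest_paths(g)
    part = detect_modules(g, seed=seed)
    return GlobalMetrics(
        e_glob=global_efficiency(g, sp),
        e_loc=local_efficiency(g),
        q_max=part.q,
        n_modules=part.n_modules,
        density=g.density,
    )


def normalize_globals(real: GlobalMetrics,
                      nulls: list[GlobalMetrics]) -> GlobalMetrics:
    """Divide each global measure by its mean over the null ensemble."""
    if not nulls:
        raise MetricsError("need at least one null")
    means = {
        "e_glob": float(np.mean([n.e_glob for n in nulls])),
        "e_loc": float(np.mean([n.e_loc for n in nulls])),
        "q_max": float(np.mean([n.q_max for n in nulls])),
    }
    for k, v in means.items():
        if v == 0:
            raise MetricsError(f"null mean of {k} is zero; ratio undefined")
    return GlobalMetrics(
        e_glob=real.e_glob, e_loc=real.e_loc, q_max=real.q_max,
        n_modules=real.n_modules, density=real.density,
        normalized_e_glob=real.e_glob / means["e_glob"],
        normalized_e_loc=real.e_loc / means["e_loc"],
        normalized_q=real.q_max / means["q_max"],
    )


def normalized_global_metrics(g: BinaryGraph, n_nulls: int = 100,
                              seed: int = 0) -> GlobalMetrics:
    """Convenience: metrics of g normalized against rewired nulls."""
    real = global_metrics(g, seed=seed)
    nulls = rewire_null(g, n_nulls=n_nulls, seed=seed)
    null_metrics = [global_metrics(n, seed=seed) for n in nulls]
    return normalize_globals(real, null_metrics)
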