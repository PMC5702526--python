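"""Functional connectivity matrices and binary-graph thresholding.

Connectivity is the pairwise Pearson correlation between regional BOLD
time series.  Negative correlations are rectified to zero before any
graph analysis.  Two complementary thresholding strategies convert the
weighted matrices to binary graphs:

* **correlation thresholding** — one absolute cutoff r0 for every
  subject; edge densities then differ across subjects (absolute
  organization);
* **sparsity thresholding** — a subject-specific cutoff retaining the
  same fraction s of the strongest edges for every subject (relative
  organization at fixed wiring cost).

Threshold values are selected on a 0.01 grid so that every subject's
graph has mean degree above 2*ln(N) and no isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N correlation weights with a zeroed diagonal."""

    weights: np.ndarray
    subject_id: str = ""
    rectified: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectivityError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ConnectivityError("weights must be symmetric")
        if self.rectified and np.any(w < 0):
            raise ConnectivityError("rectified matrix has negative entries")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryGraph:
    """Binary adjacency after thresholding."""

    adjacency: np.ndarray
    threshold_kind: str = "correlation"  # or "sparsity"
    threshold_value: float = float("nan")
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectivityError(f"adjacency must be square, got shape {a.shape}")
        if not np.array_equal(a, a.T):
            raise ConnectivityError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ConnectivityError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ConnectivityError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)


def correlation_matrix(ts: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation of a T x N time-series matrix, diagonal zeroed."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ConnectivityError(f"time series must be 2-D, got shape {ts.shape}")
    T, _n = ts.shape
    if T < 3:
        raise ConnectivityError(f"need at least 3 time points, got {T}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ConnectivityError(f"constant time series at region index(es) {bad}")
    w = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return ConnectivityMatrix(weights=w, subject_id=subject_id, rectified=False)


def rectify_negative(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set negative correlations to zero (entrywise max(w, 0))."""
    return ConnectivityMatrix(
        weights=np.maximum(m.weights, 0.0), subject_id=m.subject_id, rectified=True
    )


def threshold_correlation(m: ConnectivityMatrix, r0: float) -> BinaryGraph:
    """Binarize: edge present iff weight strictly exceeds r0."""
    if r0 < 0:
        raise ConnectivityError(f"correlation threshold must be >= 0, got {r0}")
    a = (m.weights > r0).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a, threshold_kind="correlation", threshold_value=float(r0),
                       subject_id=m.subject_id)


def _ranked_pairs(m: ConnectivityMatrix):
    """Upper-triangle pairs sorted by descending weight; ties broken by
    lexicographic (i, j) order for reproducibility."""
    n = m.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = m.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold_sparsity(m: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Retain exactly round(s * N(N-1)/2) strongest positive edges."""
    if not 0 < s <= 1:
        raise ConnectivityError(f"sparsity must be in (0, 1], got {s}")
    n = m.n_regions
    n_pairs = n * (n - 1) // 2
    k = round(s * n_pairs)
    iu, ju, w = _ranked_pairs(m)
    n_positive = int((w > 0).sum())
    if k > n_positive:
        raise ConnectivityError(
            f"subject {m.subject_id!r}: sparsity {s} requests {k} edges but only "
            f"{n_positive} positive weights exist"
        )
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[:k], ju[:k]] = 1
    a |= a.T
    return BinaryGraph(a, threshold_kind="sparsity", threshold_value=float(s),
                       subject_id=m.subject_id)


def _criteria_ok(g: BinaryGraph) -> bool:
    deg = g.degrees
    n = g.n_nodes
    return deg.mean() > 2 * np.log(n) and deg.min() > 0


@dataclass
class ThresholdSelection:
    """Selected cohort-wide thresholds plus per-subject diagnostics."""

    max_correlation_threshold: float
    min_sparsity_threshold: float
    diagnostics: pd.DataFrame = field(repr=False)


def select_thresholds(cohort: list[ConnectivityMatrix],
                      grid_step: float = 0.01) -> ThresholdSelection:
    """Pick the cohort thresholds on a grid.

    ``max_correlation_threshold``: the largest r0 such that every subject's
    correlation-thresholded graph has mean degree > 2 ln N and no isolated
    nodes.  ``min_sparsity_threshold``: the smallest sparsity s likewise.
    """
    if not cohort:
        raise ConnectivityError("empty cohort")
    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    records = []

    def diag(g, kind, value, subject):
        deg = g.degrees
        records.append({
            "subject_id": subject, "kind": kind, "threshold": value,
            "mean_degree": float(deg.mean()),
            "n_isolated": int((deg == 0).sum()),
        })

    r_best = None
    for r0 in grid:
        graphs = [threshold_correlation(m, r0) for m in cohort]
        for m, g in zip(cohort, graphs):
            diag(g, "correlation", r0, m.subject_id)
        if all(_criteria_ok(g) for g in graphs):
            r_best = float(r0)
        else:
            break
    s_best = None
    n = cohort[0].n_regions
    n_pairs = n * (n - 1) // 2
    for s in grid:
        try:
            graphs = [threshold_sparsity(m, s) for m in cohort]
        except ConnectivityError:
            break
        for m, g in zip(cohort, graphs):
            diag(g, "sparsity", s, m.subject_id)
        if all(_criteria_ok(g) for g in graphs):
            s_best = float(s)
            break
        if round(s * n_pairs) >= n_pairs:
            break
    if r_best is None or s_best is None:
        raise ConnectivityError(
            "no threshold satisfies the mean-degree and no-isolated-node "
            "criteria for every subject"
        )
    return ThresholdSelection(
        max_correlation_threshold=r_best,
        min_sparsity_threshold=s_best,
        diagnostics=pd.DataFrame.from_records(records),
    )


def save_matrix(m: ConnectivityMatrix, path) -> None:
    np.savetxt(path, m.weights, fmt="%.8f", delimiter="\t")


def load_matrix(path, subject_id: str = "", rectified: bool = False) -> ConnectivityMatrix:
    w = np.loadtxt(path, delimiter="\t")
    return ConnectivityMatrix(weights=w, subject_id=subject_id, rectified=rectified)
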