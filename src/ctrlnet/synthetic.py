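"""Synthetic two-group cohorts of regional BOLD-like time series.

The generator emulates what the analysis assumes of preprocessed
resting-state data: zero-mean, band-limited regional time series whose
cross-sectional correlation has block structure by functional network
(higher within than between networks), with a planted hypoconnectivity
effect — a connected set of long-range, inter-network edges whose
correlation is reduced in the patient group — plus demographic,
head-motion and clinical covariates.  Age, gender, IQ and motion carry
no built-in group difference; clinical symptom scores do, and in
patients they co-vary with the subject's planted-edge connectivity.

Temporal smoothness is approximated by an AR(1) process applied per
innovation channel before mixing through the covariance square root; no
explicit band-pass filtering or physiological noise is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, pairwise_distances
from .distance import sample_connected_edge_set


class SyntheticError(ValueError):
    pass


#: pooled demographic / motion distributions (both groups identical)
DEFAULT_COVARIATES = {
    "age_mean": 8.6, "age_sd": 1.8, "age_range": (6.0, 13.0),
    "iq_mean": 119.0, "iq_sd": 12.0, "iq_range": (80.0, 145.0),
    "male_prop": 0.78,
    "motion_max_mean": 0.9, "motion_max_sd": 0.45,
    "motion_rms_mean": 0.25, "motion_rms_sd": 0.10,
    "motion_meanfd_mean": 0.15, "motion_meanfd_sd": 0.06,
}

#: clinical score distributions (0-3 scales), patients elevated
DEFAULT_CLINICAL = {
    "hyperactivity_patient": (1.45, 0.60),
    "hyperactivity_control": (0.40, 0.35),
    "impulsive_patient": (1.54, 0.63),
    "impulsive_control": (0.50, 0.48),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``planted_base_r`` is the control-group correlation on planted
    edges *before* global-signal regression: the planted component
    emulates connections present in most participants but weakened by
    ``effect_delta`` in patients, so its baseline sits above the generic
    between-network level.

    ``global_signal_regression`` removes each subject's mean regional
    signal from every series, as resting-state preprocessing does.  This
    recentres the correlation distribution near zero (producing the
    negative correlations that rectification then removes) and, by
    killing the shared global fluctuation, keeps edgewise statistics
    from moving en bloc across subjects.
    Two inter-subject variability scales act on planted edges:
    ``subject_sd`` is a per-subject scalar offset shared by all planted
    edges (the component-level individual differences that clinical
    scores couple to, correlation ``clinical_rho`` in patients), and
    ``edge_sd`` is independent per-edge, per-subject heterogeneity.  The
    latter keeps single-edge group effects moderate (edgewise t around
    2-4 at the default group sizes) — the regime in which component-level
    aggregation, not any single edge, carries the detection — while
    averaging out of the 30-edge component mean, so subject-level
    discrimination stays high.
    """

    n_patients: int = 46
    n_controls: int = 31
    n_volumes: int = 230
    base_within_network_r: float = 0.45
    base_between_network_r: float = 0.15
    planted_base_r: float = 0.55
    effect_delta: float = 0.25
    global_signal_regression: bool = True
    temporal_ar: float = 0.3
    subject_sd: float = 0.08
    edge_sd: float = 0.12
    clinical_rho: float = 0.4
    planted_edges: list[tuple[int, int]] | None = None  # None -> canonical set
    planted_m_edges: int = 30
    planted_n_nodes: int = 26
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    clinical: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_within_network_r", "base_between_network_r",
                     "planted_base_r", "temporal_ar"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SyntheticError(f"{name}={v} outside [0, 1)")
        if self.n_patients < 1 or self.n_controls < 1:
            raise SyntheticError("both groups need at least one subject")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    timeseries: np.ndarray = field(repr=False)  # T x N
    covariates: dict = field(default_factory=dict)
    clinical: dict = field(default_factory=dict)


#: fixed internal seed so the canonical planted component is a property
#: of the atlas, not of the cohort seed
_PLANT_SEED = 20


def default_planted_component(atlas: Atlas, m_edges: int = 30,
                              n_nodes: int = 26) -> list[tuple[int, int]]:
    """The canonical planted component for an atlas: a connected set of
    ``m_edges`` edges on ``n_nodes`` nodes drawn (deterministically) from
    the long-range inter-network pairs."""
    table = pairwise_distances(atlas)
    universe = [(i, j) for i, j in table.pairs()
                if table.long_range[i, j] and table.inter_network[i, j]]
    if len(universe) < m_edges:
        raise SyntheticError(
            f"atlas has only {len(universe)} long-range inter-network pairs; "
            f"cannot plant {m_edges} edges"
        )
    return sample_connected_edge_set(atlas.n_regions, m_edges, n_nodes,
                                     seed=_PLANT_SEED, universe=universe)


def resolve_planted_edges(atlas: Atlas, config: CohortConfig) -> list[tuple[int, int]]:
    if config.planted_edges is not None:
        return [tuple(sorted(e)) for e in config.planted_edges]
    return default_planted_component(atlas, config.planted_m_edges,
                                     config.planted_n_nodes)


def _nearest_pd(m: np.ndarray, eig_floor: float = 1e-6,
                max_shift: float = 0.15) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and re-symmetrize."""
    vals, vecs = np.linalg.eigh(m)
    if vals[0] >= eig_floor:
        return m
    repaired = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    repaired = (repaired + repaired.T) / 2.0
    if np.abs(repaired - m).max() > max_shift:
        raise SyntheticError(
            f"covariance not repairable: minimum eigenvalue {vals[0]:.4g} "
            f"requires entry shifts above {max_shift}"
        )
    return repaired


def build_group_covariance(atlas: Atlas, config: CohortConfig,
                           group: str) -> np.ndarray:
    """Target cross-sectional covariance (unit variances) for a group."""
    if group not in ("patient", "control"):
        raise SyntheticError(f"unknown group {group!r}")
    nets = atlas.networks
    within = nets[:, None] == nets[None, :]
    cov = np.where(within, config.base_within_network_r,
                   config.base_between_network_r)
    planted_r = config.planted_base_r
    if group == "patient":
        planted_r -= config.effect_delta
    for i, j in resolve_planted_edges(atlas, config):
        cov[i, j] = cov[j, i] = planted_r
    np.fill_diagonal(cov, 1.0)
    return _nearest_pd(cov)


def _ar1_innovations(rng: np.random.Generator, T: int, n: int,
                     phi: float) -> np.ndarray:
    """T x n matrix of independent AR(1) channels with unit marginal variance."""
    e = rng.standard_normal((T, n))
    if phi == 0:
        return e
    x = np.empty_like(e)
    x[0] = e[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + scale * e[t]
    return x


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    return np.clip(out, lo, hi)


def generate_cohort(atlas: Atlas, config: CohortConfig) -> list[SubjectRecord]:
    """Simulate the full cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    planted = resolve_planted_edges(atlas, config)
    cov_by_group = {g: build_group_covariance(atlas, config, g)
                    for g in ("patient", "control")}
    cv, cl = config.covariates, config.clinical
    records = []
    n_total = {"patient": config.n_patients, "control": config.n_controls}
    for group in ("patient", "control"):
        tag = "P" if group == "patient" else "C"
        for k in range(n_total[group]):
            # per-subject offset on planted edges (clinical coupling target)
            eta = float(rng.normal(0.0, config.subject_sd)) if planted else 0.0
            cov = cov_by_group[group]
            if planted:
                eps = rng.normal(0.0, config.edge_sd, size=len(planted))
                cov = cov.copy()
                for (i, j), e in zip(planted, eps):
                    cov[i, j] = cov[j, i] = np.clip(cov[i, j] + eta + e,
                                                    -0.9, 0.9)
                cov = _nearest_pd(cov, max_shift=1.0)
            L = np.linalg.cholesky(cov)
            z = _ar1_innovations(rng, config.n_volumes, atlas.n_regions,
                                 config.temporal_ar)
            ts = z @ L.T
            if config.global_signal_regression:
                g = ts.mean(axis=1)
                beta = (g @ ts) / (g @ g)
                ts = ts - np.outer(g, beta)
            covariates = {
                "age": float(_truncnorm(rng, cv["age_mean"], cv["age_sd"],
                                        *cv["age_range"], size=None)),
                "gender": int(rng.random() < cv["male_prop"]),
                "iq": float(_truncnorm(rng, cv["iq_mean"], cv["iq_sd"],
                                       *cv["iq_range"], size=None)),
                "motion_max": float(max(rng.normal(cv["motion_max_mean"],
                                                   cv["motion_max_sd"]), 0.05)),
                "motion_rms": float(max(rng.normal(cv["motion_rms_mean"],
                                                   cv["motion_rms_sd"]), 0.02)),
                "motion_meanFD": float(max(rng.normal(cv["motion_meanfd_mean"],
                                                      cv["motion_meanfd_sd"]),
                                           0.02)),
            }
            clinical = {}
            z_eta = eta / config.subject_sd if config.subject_sd > 0 else 0.0
            for score in ("hyperactivity", "impulsive"):
                mean, sd = cl[f"{score}_{group}"]
                eps = rng.standard_normal()
                if group == "patient":
                    rho = config.clinical_rho
                    raw = mean + sd * (rho * z_eta + np.sqrt(1 - rho**2) * eps)
                else:
                    raw = mean + sd * eps
                key = ("hyperactivity_index" if score == "hyperactivity"
                       else "impulsive_score")
                clinical[key] = float(np.clip(raw, 0.0, 3.0))
            records.append(SubjectRecord(
                subject_id=f"sub-{tag}{k + 1:03d}", group=group,
                timeseries=ts, covariates=covariates, clinical=clinical))
    return records


def phenotype_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group}
        row.update(r.covariates)
        row.update(r.clinical)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], atlas: Atlas, outdir) -> None:
    """Write per-subject T x N time-series TSVs plus a phenotype CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "\t".join(atlas.labels)
    for r in records:
        np.savetxt(outdir / f"{r.subject_id}_timeseries.tsv", r.timeseries,
                   fmt="%.6f", delimiter="\t", header=header, comments="")
    phenotype_frame(records).to_csv(outdir / "phenotype.csv", index=False)


def read_cohort(atlas: Atlas, directory) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort` (or user-supplied
    files in the same layout)."""
    directory = Path(directory)
    pheno = pd.read_csv(directory / "phenotype.csv")
    clinical_cols = ["hyperactivity_index", "impulsive_score"]
    records = []
    for _, row in pheno.iterrows():
        ts = np.loadtxt(directory / f"{row['subject_id']}_timeseries.tsv",
                        delimiter="\t", skiprows=1)
        if ts.shape[1] != atlas.n_regions:
            raise SyntheticError(
                f"{row['subject_id']}: {ts.shape[1]} columns, expected "
                f"{atlas.n_regions}")
        covs = {c: row[c] for c in pheno.columns
                if c not in ("subject_id", "group", *clinical_cols)}
        clin = {c: row[c] for c in clinical_cols if c in pheno.columns}
        records.append(SubjectRecord(subject_id=row["subject_id"],
                                     group=row["group"], timeseries=ts,
                                     covariates=covs, clinical=clin))
    return records


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of the config with the planted effect switched off."""
    config = config or CohortConfig()
    return replace(config, effect_delta=0.0, **overrides)
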