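"""End-to-end study pipeline.

Sequences the full group analysis on a cohort of regional time series:
connectivity construction and rectification, dual thresholding (with
automatic threshold selection), global and nodal graph metrics with
degree-preserving null normalization, NBS group comparison, anatomical
distance statistics of the NBS component, covariate-controlled
permutation tests on the topological measures, brain-clinical rank
partial correlations and ROC discrimination.  Every stage derives its
seed from the global seed through a fixed counter scheme so stages can
be rerun in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import Atlas, load_atlas, pairwise_distances
from .connectivity import (ConnectivityMatrix, correlation_matrix,
                           rectify_negative, select_thresholds,
                           threshold_correlation, threshold_sparsity)
from .datasets import load_reference_atlas, _DATA
from .distance import (component_distance_summary, distance_resampling_test,
                       distance_ttest)
from .inference import (fdr_correct, permutation_metric_test,
                        rank_partial_correlation, roc_analysis)
from .metrics import (global_metrics, nodal_metrics, normalize_globals,
                      rewire_null)
from .nbs import NbsConfig, component_mean_strength, nbs_test
from .synthetic import (CohortConfig, SubjectRecord, generate_cohort,
                        phenotype_frame, read_cohort, write_cohort)

COVARIATE_COLUMNS = ["age", "gender", "iq", "motion_max", "motion_rms",
                     "motion_meanFD"]

#: hypothesized direction of the controls-minus-patients difference per
#: global measure ('greater': controls larger)
METRIC_TAILS = {
    "density": "greater",
    "e_glob": "greater",
    "e_loc": "greater",
    "q_max": "less",
    "n_modules": "less",
    "normalized_e_glob": "greater",
    "normalized_e_loc": "greater",
    "normalized_q": "less",
}

# stage indices for the seed fan-out
_STAGES = {"simulate": 0, "nbs": 1, "distance": 2, "metrics": 3,
           "inference": 4, "roc": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: (seed * 1000003 + stage_index) mod 2^31."""
    return (seed * 1000003 + _STAGES[stage]) % (2**31)


@dataclass
class PipelineConfig:
    atlas_path: str | None = None          # None -> bundled atlas
    data_dir: str | None = None            # None -> simulate
    outdir: str = "ctrlnet_out"
    cohort: CohortConfig = None            # None -> defaults with seed
    threshold_mode: str = "auto"           # "auto" | "fixed"
    correlation_threshold: float | None = None
    sparsity_threshold: float | None = None
    nbs_n_perm: int = 10_000
    nbs_primary_p: float = 0.05
    nbs_prevalence: float = 0.5
    nbs_tail: str = "controls_greater"
    distance_n_iter: int = 10_000
    inference_n_perm: int = 10_000
    n_nulls: int = 100
    fdr_q: float = 0.05
    covariate_columns: list[str] = field(
        default_factory=lambda: list(COVARIATE_COLUMNS))
    seed: int = 0


@dataclass
class StudyReport:
    thresholds: dict
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    nbs: dict
    distance: dict
    group_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    correlations: pd.DataFrame
    roc: dict
    manifest: dict


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, flush=True)


def build_connectivity(records: list[SubjectRecord]) -> list[ConnectivityMatrix]:
    return [rectify_negative(correlation_matrix(r.timeseries, r.subject_id))
            for r in records]


def _component_edge_frame(component, atlas: Atlas, dist, t_matrix,
                          df: int) -> pd.DataFrame:
    from scipy import stats as _st
    labels = atlas.labels
    nets = atlas.networks
    rows = []
    for i, j in component.edges:
        t = t_matrix[i, j]
        rows.append({
            "regionA": labels[i], "regionB": labels[j],
            "p": float(_st.t.sf(t, df)),
            "distance": float(dist.distance[i, j]),
            "category": f"{nets[i]}-{nets[j]}",
        })
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def run_study(config: PipelineConfig, verbose: bool = True) -> StudyReport:
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    _log("[atlas] loading", verbose)
    atlas = (load_atlas(config.atlas_path) if config.atlas_path
             else load_reference_atlas())
    dist = pairwise_distances(atlas)
    if config.data_dir:
        _log(f"[cohort] reading {config.data_dir}", verbose)
        records = read_cohort(atlas, config.data_dir)
    else:
        cohort_cfg = config.cohort or CohortConfig(
            seed=stage_seed(config.seed, "simulate"))
        _log(f"[cohort] simulating (seed {cohort_cfg.seed})", verbose)
        records = generate_cohort(atlas, cohort_cfg)
        write_cohort(records, atlas, out / "cohort")
    pheno = phenotype_frame(records)
    groups = pheno["group"].to_numpy()
    covs = pheno[config.covariate_columns]

    # --- connectivity & thresholds ---------------------------------------
    _log("[connectivity] correlation matrices", verbose)
    matrices = build_connectivity(records)
    mat_dir = out / "connectivity"
    mat_dir.mkdir(exist_ok=True)
    for m in matrices:
        np.savetxt(mat_dir / f"{m.subject_id}.tsv", m.weights, fmt="%.6f",
                   delimiter="\t")
    if config.threshold_mode == "auto":
        sel = select_thresholds(matrices)
        r0, s0 = sel.max_correlation_threshold, sel.min_sparsity_threshold
        sel.diagnostics.to_csv(out / "threshold_diagnostics.csv", index=False)
    else:
        r0, s0 = config.correlation_threshold, config.sparsity_threshold
        if r0 is None or s0 is None:
            raise ValueError("fixed threshold_mode needs both threshold values")
    thresholds = {"correlation": float(r0), "sparsity": float(s0)}
    _log(f"[thresholds] correlation={r0} sparsity={s0}", verbose)

    graphs = {
        "correlation": [threshold_correlation(m, r0) for m in matrices],
        "sparsity": [threshold_sparsity(m, s0) for m in matrices],
    }

    # --- graph metrics -----------------------------------------------------
    _log(f"[metrics] global/nodal with {config.n_nulls} nulls per graph",
         verbose)
    met_seed = stage_seed(config.seed, "metrics")
    grows, nrows = [], []
    for mode, gs in graphs.items():
        for si, g in enumerate(gs):
            gm = global_metrics(g, seed=met_seed)
            nulls = rewire_null(g, n_nulls=config.n_nulls,
                                seed=met_seed + si)
            gm = normalize_globals(gm, [global_metrics(x, seed=met_seed)
                                        for x in nulls])
            row = {"subject_id": g.subject_id, "mode": mode, **asdict(gm)}
            grows.append(row)
            nm = nodal_metrics(g)
            for node in range(atlas.n_regions):
                nrows.append({
                    "subject_id": g.subject_id, "mode": mode,
                    "node": node, "label": atlas.labels[node],
                    "degree": int(nm.degree[node]),
                    "efficiency": float(nm.efficiency[node]),
                    "betweenness": float(nm.betweenness[node]),
                })
    gdf = pd.DataFrame(grows)
    ndf = pd.DataFrame(nrows)
    gdf.to_csv(out / "global_metrics.csv", index=False)
    ndf.to_csv(out / "nodal_metrics.csv", index=False)

    # --- NBS ---------------------------------------------------------------
    _log(f"[nbs] {config.nbs_n_perm} permutations", verbose)
    nbs_cfg = NbsConfig(primary_p=config.nbs_primary_p,
                        n_perm=config.nbs_n_perm,
                        prevalence=config.nbs_prevalence,
                        tail=config.nbs_tail,
                        seed=stage_seed(config.seed, "nbs"))
    nbs_res = nbs_test(matrices, covs, groups, nbs_cfg)
    significant = nbs_res.significant_components
    nbs_summary = {
        "n_components": len(nbs_res.components),
        "significant": bool(significant),
        "components": [
            {"n_edges": c.size, "n_nodes": c.n_nodes,
             "corrected_p": c.corrected_p,
             "corrected_p_valid": c.corrected_p_valid,
             "edges": [[atlas.labels[i], atlas.labels[j]]
                       for i, j in c.edges]}
            for c in nbs_res.components
        ],
    }
    with open(out / "nbs_result.json", "w") as fh:
        json.dump(nbs_summary, fh, indent=2)

    # the component all downstream stages profile: the largest
    # significant one (None if NBS found nothing significant)
    component = significant[0] if significant else None
    distance_summary: dict = {"computed": False}
    corr_rows: list[dict] = []
    roc_summary: dict = {"computed": False}
    if component is not None:
        edge_df = _component_edge_frame(component, atlas, dist,
                                        nbs_res.t_matrix, nbs_res.df)
        edge_df.to_csv(out / "nbs_component_edges.csv", index=False)

        # --- distance analysis -------------------------------------------
        _log("[distance] component distance profile and resampling null",
             verbose)
        summ = component_distance_summary(component.edges, dist)
        t_d, p_d = distance_ttest(component.edges, dist)
        null = distance_resampling_test(
            component.edges, dist, n_iter=config.distance_n_iter,
            seed=stage_seed(config.seed, "distance"))
        np.savetxt(out / "distance_null_means.csv", null.null_means,
                   fmt="%.4f", header="null_mean_distance", comments="")
        distance_summary = {
            "computed": True,
            "n_edges": summ.n_edges, "n_nodes": summ.n_nodes,
            "mean_distance_mm": summ.mean_distance,
            "prop_long_range": summ.prop_long_range,
            "prop_inter_network": summ.prop_inter_network,
            "ttest_t": t_d, "ttest_p": p_d,
            "resampling_p": null.empirical_p,
        }
        with open(out / "distance_analysis.json", "w") as fh:
            json.dump(distance_summary, fh, indent=2)

        # --- brain-clinical correlations ----------------------------------
        _log("[clinical] rank partial correlations", verbose)
        strengths = np.array([component_mean_strength(m, component)
                              for m in matrices])
        from .inference import InferenceError
        for grp in ("patient", "control"):
            sel_g = groups == grp
            for score in ("hyperactivity_index", "impulsive_score"):
                try:
                    r, p = rank_partial_correlation(
                        strengths[sel_g], pheno.loc[sel_g, score],
                        covs.loc[sel_g])
                except InferenceError as err:
                    _log(f"[clinical] {grp}/{score} skipped: {err}", verbose)
                    r, p = float("nan"), float("nan")
                corr_rows.append({"group": grp, "score": score,
                                  "r": r, "p": p})

        # --- ROC -----------------------------------------------------------
        _log("[roc] component mean strength", verbose)
        roc = roc_analysis(strengths, groups,
                           n_perm=config.inference_n_perm,
                           seed=stage_seed(config.seed, "roc"))
        roc.curve.to_csv(out / "roc_curve.csv", index=False)
        roc_summary = {
            "computed": True, "auc": roc.auc, "p_auc": roc.p_auc,
            "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "n_correct_patients": roc.n_correct_patients,
            "n_correct_controls": roc.n_correct_controls,
        }
    cdf = pd.DataFrame(corr_rows)
    cdf.to_csv(out / "clinical_correlations.csv", index=False)
    with open(out / "roc_result.json", "w") as fh:
        json.dump(roc_summary, fh, indent=2)

    # --- group tests on topological measures ------------------------------
    _log("[inference] permutation tests on global measures", verbose)
    inf_seed = stage_seed(config.seed, "inference")
    test_rows = []
    for mode in graphs:
        sub = gdf[gdf["mode"] == mode].set_index("subject_id")
        sub = sub.loc[pheno["subject_id"]]
        for metric, tail in METRIC_TAILS.items():
            res = permutation_metric_test(
                sub[metric].to_numpy(), groups, covs,
                n_perm=config.inference_n_perm, seed=inf_seed, tail=tail)
            test_rows.append({
                "mode": mode, "metric": metric, "tail": tail,
                "observed_diff": res.observed_diff, "p": res.p,
                "critical_value": res.critical_value,
            })
    tdf = pd.DataFrame(test_rows)
    tdf.to_csv(out / "global_metric_tests.csv", index=False)

    _log("[inference] nodal permutation tests with FDR", verbose)
    nodal_rows = []
    for mode in graphs:
        sub = ndf[ndf["mode"] == mode]
        for metric in ("degree", "efficiency", "betweenness"):
            pvals = []
            for node in range(atlas.n_regions):
                vals = (sub[sub["node"] == node]
                        .set_index("subject_id")[metric]
                        .loc[pheno["subject_id"]].to_numpy())
                if np.ptp(vals) == 0:
                    pvals.append(1.0)
                    continue
                res = permutation_metric_test(
                    vals, groups, covs, n_perm=min(config.inference_n_perm,
                                                   1000),
                    seed=inf_seed + node, tail="two_sided")
                pvals.append(res.p)
            sig = fdr_correct(pvals, q=config.fdr_q)
            for node in range(atlas.n_regions):
                nodal_rows.append({
                    "mode": mode, "metric": metric, "node": node,
                    "label": atlas.labels[node], "p": pvals[node],
                    "fdr_significant": bool(sig[node]),
                })
    ntdf = pd.DataFrame(nodal_rows)
    ntdf.to_csv(out / "nodal_metric_tests.csv", index=False)

    manifest = {
        "ctrlnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "n_subjects": len(records),
        "thresholds": thresholds,
        "elapsed_seconds": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    _log(f"[done] {manifest['elapsed_seconds']} s -> {out}", verbose)
    return StudyReport(thresholds=thresholds, global_metrics=gdf,
                       nodal_metrics=ndf, nbs=nbs_summary,
                       distance=distance_summary, group_tests=tdf,
                       nodal_tests=ntdf, correlations=cdf,
                       roc=roc_summary, manifest=manifest)


def make_fixtures(outdir) -> list[Path]:
    """Write the bundled atlas and reference-component fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("control_atlas_34.csv", "hypoconnectivity_component.csv"):
        target = outdir / name
        target.write_text((_DATA / name).read_text())
        written.append(target)
    return written
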