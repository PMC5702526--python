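"""Group-level inference: permutation tests, FDR, rank partial
correlation and ROC discrimination.

Permutation tests on network measures mirror the NBS covariate
handling: values are residualized against the nuisance covariates by
pooled OLS, group labels are permuted, and the group mean difference
forms the null.  One-tailed p-values use the add-one convention
(b + 1)/(n_perm + 1); the 95th percentile of the null is also reported
as the critical value of the decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nbs import GROUP_A, residualize_edges


class InferenceError(ValueError):
    pass


@dataclass
class PermTestResult:
    observed_diff: float
    null_diffs: np.ndarray = field(repr=False)
    p: float = float("nan")
    critical_value: float = float("nan")
    exhaustive: bool = False


def permutation_metric_test(values, groups, covariates=None,
                            n_perm: int = 10_000, seed: int = 0,
                            tail: str = "greater") -> PermTestResult:
    """Permutation test of the group mean difference of one metric.

    ``observed_diff`` is controls minus patients.  ``tail='greater'``
    tests whether it is larger than chance, ``'less'`` smaller,
    ``'two_sided'`` either.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InferenceError("metric values must be finite")
    groups = np.asarray(groups)
    is_a = groups == GROUP_A
    n_a, n_s = int(is_a.sum()), len(values)
    if n_a < 2 or n_s - n_a < 2:
        raise InferenceError("need at least 2 subjects per group")
    if tail not in ("greater", "less", "two_sided"):
        raise InferenceError(f"unknown tail {tail!r}")
    if covariates is not None:
        values = residualize_edges(values[:, None], covariates)[:, 0]

    def diff(ind):
        return values[ind].mean() - values[~ind].mean()

    observed = diff(is_a)
    n_distinct = comb(n_s, n_a)
    exhaustive = n_perm >= n_distinct
    if exhaustive:
        null = np.empty(n_distinct)
        for k, idx in enumerate(combinations(range(n_s), n_a)):
            ind = np.zeros(n_s, dtype=bool)
            ind[list(idx)] = True
            null[k] = diff(ind)
        # exact p: fraction of the full permutation distribution at least
        # as extreme (the observed labelling is one of them)
        if tail == "greater":
            p = float((null >= observed - 1e-12).mean())
        elif tail == "less":
            p = float((null <= observed + 1e-12).mean())
        else:
            p = float((np.abs(null) >= abs(observed) - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            ind = np.zeros(n_s, dtype=bool)
            ind[rng.choice(n_s, size=n_a, replace=False)] = True
            null[k] = diff(ind)
        if tail == "greater":
            b = int((null >= observed).sum())
        elif tail == "less":
            b = int((null <= observed).sum())
        else:
            b = int((np.abs(null) >= abs(observed)).sum())
        p = (b + 1) / (n_perm + 1)
    critical = float(np.percentile(null, 95))
    return PermTestResult(observed_diff=float(observed), null_diffs=null,
                          p=float(p), critical_value=critical,
                          exhaustive=exhaustive)


def fdr_correct(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise InferenceError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def rank_partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Spearman-style partial correlation.

    x, y and every covariate column are rank-transformed (average ranks
    for ties); the ranked x and y are residualized on the ranked
    covariates (with intercept) and the Pearson correlation of the
    residuals is returned with a t-approximation p-value on
    df = n - k - 2.  A covariate that absorbs x or y entirely yields
    r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InferenceError("constant variable: correlation undefined")
    n = len(x)
    k = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
    if n <= k + 2:
        raise InferenceError(
            f"need more than {k + 2} observations for {k} covariates, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covariates is not None and k > 0:
        rcov = np.column_stack([stats.rankdata(cov[:, c])
                                for c in range(k)])
        rx = residualize_edges(rx[:, None], rcov)[:, 0]
        ry = residualize_edges(ry[:, None], rcov)[:, 0]
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom < 1e-10 * n:
        return 0.0, 1.0
    r = float(rx @ ry / denom)
    df = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    p_auc: float = float("nan")
    n_correct_patients: int = 0
    n_correct_controls: int = 0
    curve: pd.DataFrame = field(default=None, repr=False)


def _auc_mannwhitney(scores, is_patient) -> float:
    """AUC = P(control score > patient score) + 0.5 P(tie): the
    normalized Mann-Whitney U, with tie correction via average ranks."""
    ranks = stats.rankdata(scores)
    n_p = int(is_patient.sum())
    n_c = len(scores) - n_p
    u_c = ranks[~is_patient].sum() - n_c * (n_c + 1) / 2
    return float(u_c / (n_c * n_p))


def roc_analysis(scores, labels, n_perm: int = 10_000,
                 seed: int = 0) -> RocResult:
    """In-sample ROC for discriminating patients from controls.

    Patients are expected to score *low* (the hypoconnectivity
    direction): a subject is classified as a patient when its score is
    below the cutoff.  The cutoff maximizes Youden's J
    (sensitivity + specificity - 1); ties take the smallest cutoff.
    ``p_auc`` is a label-permutation p for AUC (add-one convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_patient = labels != GROUP_A
    n_p, n_c = int(is_patient.sum()), int((~is_patient).sum())
    if n_p == 0 or n_c == 0:
        raise InferenceError("both classes must be present")
    auc = _auc_mannwhitney(scores, is_patient)

    # candidate cutoffs: every observed score plus one above the maximum,
    # classification rule "patient iff score < cutoff"
    cands = np.unique(scores)
    cands = np.append(cands, cands[-1] + 1.0)
    rows = []
    best = None
    for c in cands:
        pred_patient = scores < c
        sens = float((pred_patient & is_patient).sum() / n_p)
        spec = float((~pred_patient & ~is_patient).sum() / n_c)
        rows.append({"cutoff": c, "sensitivity": sens, "specificity": spec})
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best
    # permutation null for the AUC: ranks are label-invariant, so each
    # permuted AUC is a rank-subset sum
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(scores)
    b = 0
    for _ in range(n_perm):
        ctrl = rng.choice(len(scores), size=n_c, replace=False)
        u_c = ranks[ctrl].sum() - n_c * (n_c + 1) / 2
        b += (u_c / (n_c * n_p)) >= auc
    p_auc = (b + 1) / (n_perm + 1)
    return RocResult(
        auc=auc, cutoff=float(cutoff), sensitivity=sens, specificity=spec,
        p_auc=float(p_auc),
        n_correct_patients=int(round(sens * n_p)),
        n_correct_controls=int(round(spec * n_c)),
        curve=pd.DataFrame(rows),
    )
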