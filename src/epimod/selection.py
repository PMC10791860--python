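"""Site selection for pacemaker models: screen, cluster, evaluate, merge.

The model-building pipeline filters candidate CpG sites by absolute Pearson
correlation with age, then by the mean absolute error of a per-site linear
age fit, clusters the surviving sites by the shape of their age-regression
residuals (affinity propagation on negative squared Euclidean distances), and
finally merges the clusters whose cross-validated pacemaker and elastic-net
models both map states to age with MAE below a cutoff (6 years by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .clock import fit_clock, predict_age
from .pacemaker import StateAgeMap, fit_epm, predict_states
from .simulate import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SiteScreenResult",
    "ClusterReport",
    "pcc_filter",
    "mae_screen",
    "cluster_residuals",
    "evaluate_clusters",
    "merge_clusters",
    "variance_filter",
]


@dataclass
class SiteScreenResult:
    """Per-site age-regression screen: correlation, linear fit, residuals."""

    site_id: str
    pcc_with_age: float
    linfit_intercept: float
    linfit_slope: float
    mae: float
    residuals: np.ndarray


@dataclass
class ClusterReport:
    """Cross-validated performance of one residual-shape cluster."""

    cluster_id: int
    site_ids: list[str]
    epm_cv_mae: float
    enet_cv_mae: float
    trend_r2: float


def _age_correlations(matrix: MethylationMatrix, ages: np.ndarray) -> np.ndarray:
    ac = ages - ages.mean()
    age_ss = ac @ ac
    if age_ss == 0.0:
        raise ValueError("ages are constant")
    M = matrix.values
    Mc = M - M.mean(axis=1, keepdims=True)
    site_ss = np.einsum("ij,ij->i", Mc, Mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (Mc @ ac) / np.sqrt(site_ss * age_ss)
    zero_var = site_ss == 0.0
    if np.any(zero_var):
        logger.warning("treating %d zero-variance sites as uncorrelated",
                       int(zero_var.sum()))
        pcc[zero_var] = 0.0
    return pcc


def pcc_filter(matrix: MethylationMatrix, ages, threshold: float = 0.4) -> list[str]:
    """Site ids with |Pearson correlation with age| above the threshold."""
    ages = np.asarray(ages, dtype=float)
    pcc = _age_correlations(matrix, ages)
    keep = np.abs(pcc) > threshold
    logger.info("PCC filter (|r| > %.2f): retained %d / %d sites",
                threshold, int(keep.sum()), matrix.n_sites)
    return [s for s, k in zip(matrix.site_ids, keep) if k]


def mae_screen(matrix: MethylationMatrix, ages,
               mae_threshold: float = 0.025) -> list[SiteScreenResult]:
    """Per-site linear age fits; keep sites whose MAE is below the threshold.

    Residual vectors of the retained sites are stored for residual-shape
    clustering.
    """
    ages = np.asarray(ages, dtype=float)
    pcc = _age_correlations(matrix, ages)
    X = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(X, matrix.values.T, rcond=None)
    resid = matrix.values.T - X @ coef        # samples x sites
    mae = np.mean(np.abs(resid), axis=0)
    results = []
    for i, site in enumerate(matrix.site_ids):
        if mae[i] < mae_threshold:
            results.append(SiteScreenResult(
                site_id=site,
                pcc_with_age=float(pcc[i]),
                linfit_intercept=float(coef[0, i]),
                linfit_slope=float(coef[1, i]),
                mae=float(mae[i]),
                residuals=resid[:, i].copy(),
            ))
    logger.info("MAE screen (< %.3f): retained %d / %d sites",
                mae_threshold, len(results), matrix.n_sites)
    return results


def cluster_residuals(screens: list[SiteScreenResult], preference: float = -2.5,
                      seed: int = 1, damping: float = 0.9,
                      max_iter: int = 1000) -> np.ndarray:
    """Affinity-propagation clustering of the residual vectors.

    Similarity is the negative squared Euclidean distance between residual
    vectors (scikit-learn's 'euclidean' affinity).  On non-convergence every
    site is labelled as its own singleton cluster and the run continues with a
    warning.
    """
    if len(screens) < 2:
        raise ValueError("need at least 2 sites to cluster")
    X = np.stack([s.residuals for s in screens])
    ap = AffinityPropagation(preference=preference, damping=damping,
                             max_iter=max_iter, random_state=seed,
                             affinity="euclidean")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ap.fit(X)
    centers = getattr(ap, "cluster_centers_indices_", None)
    if centers is None or len(centers) == 0 or np.any(ap.labels_ < 0):
        logger.warning("affinity propagation did not converge; "
                       "labelling all %d sites as singletons", len(screens))
        return np.arange(len(screens))
    labels = np.asarray(ap.labels_, dtype=int)
    logger.info("affinity propagation: %d clusters over %d sites",
                len(np.unique(labels)), len(screens))
    return labels


def evaluate_clusters(matrix: MethylationMatrix, ages, labels,
                      screens: list[SiteScreenResult] | None = None,
                      site_ids: list[str] | None = None,
                      min_size: int = 10, folds: int = 5,
                      seed: int = 0) -> list[ClusterReport]:
    """Cross-validated pacemaker and elastic-net models per cluster.

    For every cluster with more than ``min_size`` sites: k-fold CV over
    samples, fitting a pacemaker on the training folds, mapping held-out
    states to years through the sqrt-age trend fit on the training folds, and
    an elastic-net age model on the same splits.  Reports held-out MAEs in
    years plus the trend R^2 of the full-cluster state/age relationship.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels)
    if site_ids is None:
        if screens is None:
            raise ValueError("provide screens or site_ids alongside labels")
        site_ids = [s.site_id for s in screens]
    if len(site_ids) != len(labels):
        raise ValueError("labels length must match site count")

    reports = []
    for cluster_id in np.unique(labels):
        members = [s for s, l in zip(site_ids, labels) if l == cluster_id]
        if len(members) <= min_size:
            continue
        sub = matrix.subset_sites(members)
        if matrix.n_samples < folds:
            logger.warning("cluster %s skipped: %d samples < %d folds",
                           cluster_id, matrix.n_samples, folds)
            continue
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        epm_err, enet_err = [], []
        for train_idx, test_idx in kf.split(np.arange(matrix.n_samples)):
            m_tr = sub.subset_samples(train_idx)
            m_te = sub.subset_samples(test_idx)
            epm = fit_epm(m_tr, ages[train_idx])
            trend = StateAgeMap.fit(epm.states, ages[train_idx])
            mapped = trend.to_age(predict_states(epm, m_te))
            epm_err.append(np.abs(mapped - ages[test_idx]))
            clock = fit_clock(m_tr, ages[train_idx], cv_folds=folds, seed=seed)
            enet_err.append(np.abs(predict_age(clock, m_te) - ages[test_idx]))
        full = fit_epm(sub, ages)
        trend_full = StateAgeMap.fit(full.states, ages)
        reports.append(ClusterReport(
            cluster_id=int(cluster_id),
            site_ids=members,
            epm_cv_mae=float(np.mean(np.concatenate(epm_err))),
            enet_cv_mae=float(np.mean(np.concatenate(enet_err))),
            trend_r2=float(trend_full.r2),
        ))
    logger.info("evaluated %d clusters with > %d sites", len(reports), min_size)
    return reports


def merge_clusters(reports: list[ClusterReport], mae_cutoff: float = 6.0) -> list[str]:
    """Union of sites over clusters whose pacemaker and elastic-net
    cross-validated MAEs are both below the cutoff (in years)."""
    selected = [r for r in reports
                if r.epm_cv_mae < mae_cutoff and r.enet_cv_mae < mae_cutoff]
    if not selected:
        raise ValueError(
            f"no cluster passed the MAE cutoff of {mae_cutoff} years; "
            "consider relaxing the cutoff")
    merged: list[str] = []
    seen = set()
    for r in selected:
        for s in r.site_ids:
            if s not in seen:
                seen.add(s)
                merged.append(s)
    logger.info("merged %d clusters into %d sites", len(selected), len(merged))
    return merged


def variance_filter(matrix: MethylationMatrix, min_variance: float = 0.001) -> list[str]:
    """Site ids with sample variance at or above the threshold (the
    elastic-net branch's pre-filter)."""
    var = matrix.values.var(axis=1)
    keep = var >= min_variance
    logger.info("variance filter (>= %g): retained %d / %d sites",
                min_variance, int(keep.sum()), matrix.n_sites)
    return [s for s, k in zip(matrix.site_ids, keep) if k]
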