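"""End-to-end experiments: the simulation p-value grid and the
build-and-moderate pipeline.

``run_simulation_grid`` sweeps the binary exposure (0.995 to 1.0) and the
health standard deviation (0.0 to 0.01) over 5x5 equally spaced cells.  Each
replicate simulates the benchmark design (61 traits, 400 sites, 500 samples),
splits the samples in half, fits a pacemaker and an elastic-net clock on the
training half, predicts states and ages for the test half and fits the
moderation model ``S = age + sqrt(age) + health + binary`` to both outcomes,
collecting the health- and binary-term p-values.

``run_build_and_moderate`` reproduces the model-building pipeline on a real or
simulated matrix: PCC filter -> per-site MAE screen -> residual affinity
propagation -> cross-validated cluster evaluation -> merge -> final pacemaker
and elastic-net fits -> held-out predictions -> per-batch moderation with
cell-type PCs and sex.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clock import ClockModel, fit_clock, fit_metrics, predict_age
from .moderation import (ModerationResult, build_design, fit_celltype_pca,
                         fit_moderation)
from .pacemaker import EPMModel, StateAgeMap, fit_epm, predict_states
from .selection import (cluster_residuals, evaluate_clusters, mae_screen,
                        merge_clusters, pcc_filter, variance_filter)
from .simulate import (MethylationMatrix, simulate_cohort,
                       simulate_methylation, split_half, table1_design)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "simulate_rep",
    "run_simulation_grid",
    "build_and_moderate",
    "run_build_and_moderate",
    "BuildResult",
]

BINARY_Q_GRID = (0.995, 0.99625, 0.9975, 0.99875, 1.0)
HEALTH_SD_GRID = (0.0, 0.0025, 0.005, 0.0075, 0.01)


@dataclass
class RunConfig:
    """Configuration for the command-line experiments (YAML-serialisable)."""

    mode: str = "simulate-grid"           # simulate-grid | build-moderate
    out_dir: str = "epimod_out"
    matrix_path: str | None = None
    metadata_path: str | None = None
    seed: int = 1
    # grid specification
    n_samples: int = 500
    reps: int = 50
    binary_q_values: tuple[float, ...] = BINARY_Q_GRID
    health_sd_values: tuple[float, ...] = HEALTH_SD_GRID
    total_sites: int | None = None
    # thresholds
    pcc_threshold: float = 0.4
    site_mae_threshold: float = 0.025
    cluster_mae_cutoff: float = 6.0
    variance_threshold: float = 0.001
    alpha: float = 0.05
    preference: float = -2.5
    min_cluster_size: int = 10
    cv_folds: int = 5
    # model settings
    epm_tol: float = 1e-4
    epm_max_iter: int = 100
    l1_ratio: float = 0.75
    grid_enet_alpha: float = 1.0
    use_year_mapped_states: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in ("pcc_threshold", "site_mae_threshold",
                     "cluster_mae_cutoff", "variance_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("binary_q_values", "health_sd_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("binary_q_values", "health_sd_values"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _rep_seed(seed: int, binary_q: float, health_sd: float, rep: int) -> np.random.SeedSequence:
    """Replicate seed derived from the cell coordinates, so a cell's draws do
    not depend on which other cells are run."""
    return np.random.SeedSequence(
        entropy=(int(seed), int(round(binary_q * 1e6)),
                 int(round(health_sd * 1e7)), int(rep)))


def simulate_rep(binary_q: float, health_sd: float, n_samples: int = 500,
                 seed=0, *, total_sites: int | None = None,
                 enet_alpha: float | None = 1.0, l1_ratio: float = 0.75,
                 epm_tol: float = 1e-4, epm_max_iter: int = 100,
                 use_year_mapped_states: bool = False) -> dict:
    """One grid replicate; returns the moderation p-values for both outcomes.

    The health term is omitted from the design when ``health_sd == 0`` (the
    column would be identically zero) and its p-values are reported as NaN.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_design, s_cohort, s_meth, s_split, s_clock = ss.spawn(5)
    design = table1_design(binary_q=binary_q, health_sd=health_sd,
                           n_samples=n_samples, seed=s_design,
                           total_sites=total_sites)
    cohort = simulate_cohort(n_samples, design.age_range, health_sd,
                             design.traits, seed=s_cohort)
    matrix = simulate_methylation(cohort, design.sites, seed=s_meth)
    (m_tr, c_tr), (m_te, c_te) = split_half(matrix, cohort, seed=s_split)

    epm = fit_epm(m_tr, c_tr.ages, tol=epm_tol, max_iter=epm_max_iter)
    states_te = predict_states(epm, m_te)
    if use_year_mapped_states:
        trend = StateAgeMap.fit(epm.states, c_tr.ages)
        states_te = trend.to_age(states_te)
    clock = fit_clock(m_tr, c_tr.ages, alpha=enet_alpha, l1_ratio=l1_ratio,
                      seed=int(s_clock.generate_state(1)[0] % (2 ** 31)))
    ages_te = predict_age(clock, m_te)

    covariates = {}
    if health_sd > 0:
        covariates["health"] = c_te.health
    covariates["binary"] = c_te.binary_status["binary"].to_numpy(dtype=float)
    design_mat = build_design(c_te.ages, covariates)
    res_epm = fit_moderation(states_te, design_mat, outcome_label="epm_state")
    res_clock = fit_moderation(ages_te, design_mat, outcome_label="clock_age")

    def p(res: ModerationResult, term: str) -> float:
        return res.p_value(term) if term in res.terms.index else float("nan")

    return {
        "binary_q": binary_q,
        "health_sd": health_sd,
        "p_epm_binary": p(res_epm, "binary"),
        "p_epm_health": p(res_epm, "health"),
        "p_clock_binary": p(res_clock, "binary"),
        "p_clock_health": p(res_clock, "health"),
    }


def run_simulation_grid(config: RunConfig, write: bool = True):
    """Run the full p-value grid; returns (per-rep frame, summary frame).

    The per-rep frame is tidy: one row per (cell, rep, outcome, term) with the
    p-value; the summary frame holds the mean and sd of the p-values per cell,
    outcome and term.  Failed cells are logged and marked NA.
    """
    rows = []
    t0 = time.time()
    for bq in config.binary_q_values:
        for hs in config.health_sd_values:
            for rep in range(config.reps):
                rep_ss = _rep_seed(config.seed, bq, hs, rep)
                try:
                    res = simulate_rep(
                        bq, hs, config.n_samples, seed=rep_ss,
                        total_sites=config.total_sites,
                        enet_alpha=config.grid_enet_alpha,
                        l1_ratio=config.l1_ratio,
                        epm_tol=config.epm_tol,
                        epm_max_iter=config.epm_max_iter,
                        use_year_mapped_states=config.use_year_mapped_states)
                except Exception:
                    logger.exception("grid cell (q=%g, sd=%g) rep %d failed",
                                     bq, hs, rep)
                    res = {"binary_q": bq, "health_sd": hs,
                           "p_epm_binary": np.nan, "p_epm_health": np.nan,
                           "p_clock_binary": np.nan, "p_clock_health": np.nan}
                for outcome in ("epm", "clock"):
                    for term in ("binary", "health"):
                        rows.append({
                            "binary_q": bq, "health_sd": hs, "rep": rep,
                            "outcome": outcome, "term": term,
                            "p_value": res[f"p_{outcome}_{term}"],
                        })
            logger.info("grid cell (q=%g, sd=%g) done (%.1fs elapsed)",
                        bq, hs, time.time() - t0)
    per_rep = pd.DataFrame(rows)
    summary = (per_rep
               .groupby(["binary_q", "health_sd", "outcome", "term"],
                        as_index=False)["p_value"]
               .agg(mean_p="mean", sd_p="std", n_reps="count"))
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        per_rep.to_csv(out / "grid_pvalues.tsv", sep="\t", index=False,
                       float_format="%.6g")
        summary.to_csv(out / "grid_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        logger.info("grid outputs written to %s", out)
    return per_rep, summary


# ---------------------------------------------------------------------------
# Build-and-moderate pipeline
# ---------------------------------------------------------------------------

@dataclass
class BuildResult:
    """Outputs of the build-and-moderate pipeline."""

    final_site_ids: list[str]
    cluster_reports: list
    epm_model: EPMModel
    clock_model: ClockModel
    trend: StateAgeMap
    moderation: list[ModerationResult]
    metrics: dict = field(default_factory=dict)

    def moderation_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.moderation:
            for term, row in res.terms.iterrows():
                rows.append({
                    "outcome": res.outcome_label, "batch": res.batch,
                    "term": term, "estimate": row["estimate"], "se": row["se"],
                    "t": row["t"], "p": row["p"],
                    "n_samples": res.n_samples,
                    "sex_term_dropped": res.sex_term_dropped,
                })
        return pd.DataFrame(rows)


def build_and_moderate(matrix: MethylationMatrix, metadata: pd.DataFrame,
                       config: RunConfig) -> BuildResult:
    """Run the model-building pipeline and the moderation analysis.

    ``metadata`` is indexed by sample id with an ``age`` column and optional
    ``sex``, ``batch``, ``exposure`` and ``celltype_*`` columns.  Stages run
    on a random half split: screening, clustering and model fits on the
    training half, moderation on held-out predictions.
    """
    if list(metadata.index) != list(matrix.sample_ids):
        metadata = metadata.loc[matrix.sample_ids]
    ages = metadata["age"].to_numpy(dtype=float)
    ss = np.random.SeedSequence((int(config.seed), 17))
    s_split, s_cluster, s_eval, s_clock = ss.spawn(4)

    n = matrix.n_samples
    perm = np.random.default_rng(s_split).permutation(n)
    n_train = (n + 1) // 2
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    m_tr = matrix.subset_samples(train_idx)
    m_te = matrix.subset_samples(test_idx)
    ages_tr, ages_te = ages[train_idx], ages[test_idx]

    def stage(name, fn):
        t0 = time.time()
        out = fn()
        logger.info("stage %-18s %.2fs", name, time.time() - t0)
        return out

    kept = stage("pcc_filter", lambda: pcc_filter(
        m_tr, ages_tr, threshold=config.pcc_threshold))
    if not kept:
        raise RuntimeError("stage 'pcc_filter' retained no sites")
    screens = stage("mae_screen", lambda: mae_screen(
        m_tr.subset_sites(kept), ages_tr,
        mae_threshold=config.site_mae_threshold))
    if len(screens) < 2:
        raise RuntimeError("stage 'mae_screen' retained fewer than 2 sites")
    labels = stage("cluster_residuals", lambda: cluster_residuals(
        screens, preference=config.preference,
        seed=int(s_cluster.generate_state(1)[0] % (2 ** 31))))
    reports = stage("evaluate_clusters", lambda: evaluate_clusters(
        m_tr, ages_tr, labels, screens=screens,
        min_size=config.min_cluster_size, folds=config.cv_folds,
        seed=int(s_eval.generate_state(1)[0] % (2 ** 31))))
    final_sites = stage("merge_clusters", lambda: merge_clusters(
        reports, mae_cutoff=config.cluster_mae_cutoff))

    def fit_final():
        epm = fit_epm(m_tr.subset_sites(final_sites), ages_tr,
                      tol=config.epm_tol, max_iter=config.epm_max_iter)
        trend = StateAgeMap.fit(epm.states, ages_tr)
        enet_sites = variance_filter(m_tr, min_variance=config.variance_threshold)
        clock = fit_clock(m_tr.subset_sites(enet_sites), ages_tr,
                          cv_folds=config.cv_folds, l1_ratio=config.l1_ratio,
                          seed=int(s_clock.generate_state(1)[0] % (2 ** 31)))
        return epm, trend, clock

    epm, trend, clock = stage("final_fits", fit_final)

    def predict():
        states = predict_states(epm, m_te.subset_sites(final_sites))
        pred_ages = predict_age(clock, m_te.subset_sites(clock.site_ids))
        return states, pred_ages

    states_te, pred_ages_te = stage("predict", predict)

    # covariates for the moderation design
    cell_cols = [c for c in metadata.columns if c.startswith("celltype_")]
    covariates_te: dict[str, np.ndarray] = {}
    if cell_cols:
        pca = fit_celltype_pca(metadata.iloc[train_idx][cell_cols])
        pcs = pca.transform(metadata.iloc[test_idx][cell_cols])
        for k in range(3):
            covariates_te[f"cell_pc{k + 1}"] = pcs[:, k]
    if "exposure" in metadata.columns:
        covariates_te["exposure"] = (
            metadata.iloc[test_idx]["exposure"].to_numpy(dtype=float))
    sex_te = (metadata.iloc[test_idx]["sex"].to_numpy()
              if "sex" in metadata.columns else None)
    batches = (metadata.iloc[test_idx]["batch"].astype(str).to_numpy()
               if "batch" in metadata.columns
               else np.array(["all"] * len(test_idx)))

    def moderate():
        results = []
        for batch in pd.unique(batches):
            sel = batches == batch
            covs = {k: v[sel] for k, v in covariates_te.items()}
            dm = build_design(ages_te[sel], covs,
                              sex_labels=sex_te[sel] if sex_te is not None else None)
            results.append(fit_moderation(states_te[sel], dm,
                                          outcome_label="epm_state", batch=batch))
            results.append(fit_moderation(pred_ages_te[sel], dm,
                                          outcome_label="clock_age", batch=batch))
        return results

    moderation_results = stage("moderation", moderate)

    mapped_tr = trend.to_age(epm.states)
    mapped_te = trend.to_age(states_te)
    metrics = {
        "n_sites_final": len(final_sites),
        "epm_train_mae_years": float(np.mean(np.abs(mapped_tr - ages_tr))),
        "epm_test_mae_years": float(np.mean(np.abs(mapped_te - ages_te))),
        "clock_train_r2": fit_metrics(ages_tr, predict_age(
            clock, m_tr.subset_sites(clock.site_ids)))[0],
        "clock_test_r2": fit_metrics(ages_te, pred_ages_te)[0],
    }
    return BuildResult(
        final_site_ids=final_sites, cluster_reports=reports,
        epm_model=epm, clock_model=clock, trend=trend,
        moderation=moderation_results, metrics=metrics,
    )


def run_build_and_moderate(config: RunConfig) -> BuildResult:
    """File-based wrapper: read inputs, run the pipeline, persist outputs.

    Partial outputs are removed if a stage fails.
    """
    if not config.matrix_path or not config.metadata_path:
        raise ValueError("build-moderate mode requires matrix_path and metadata_path")
    matrix = mio.read_matrix(config.matrix_path)
    metadata = mio.read_metadata(config.metadata_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        result = build_and_moderate(matrix, metadata, config)
        cfg_path = out / "config.yaml"
        config.to_yaml(cfg_path)
        written.append(cfg_path)

        epm_path = out / "epm_model.tsv"
        pd.DataFrame({
            "site_id": result.epm_model.site_ids,
            "m0": result.epm_model.m0,
            "rate": result.epm_model.rates,
        }).to_csv(epm_path, sep="\t", index=False, float_format="%.8g")
        written.append(epm_path)

        clock_path = out / "clock_model.tsv"
        pd.DataFrame({
            "site_id": result.clock_model.site_ids,
            "coefficient": result.clock_model.coefficients,
        }).to_csv(clock_path, sep="\t", index=False, float_format="%.8g")
        written.append(clock_path)

        meta_path = out / "model_meta.json"
        with open(meta_path, "w") as fh:
            json.dump({
                "clock_intercept": result.clock_model.intercept,
                "clock_hyper": result.clock_model.hyper,
                "trend": {"a": result.trend.a, "b": result.trend.b,
                          "c": result.trend.c, "r2": result.trend.r2},
                "metrics": result.metrics,
            }, fh, indent=2, sort_keys=True)
        written.append(meta_path)

        res_path = out / "moderation_results.tsv"
        result.moderation_frame().to_csv(res_path, sep="\t", index=False,
                                         float_format="%.6g")
        written.append(res_path)
        logger.info("pipeline outputs written to %s", out)
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
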