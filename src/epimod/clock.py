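"""Penalized-regression epigenetic clock used as the comparison model.

The clock is a standard elastic net regressing chronological age on
methylation beta values (samples x sites).  The optimiser is delegated to
scikit-learn; this module owns the data contract (site alignment, orientation),
the hyper-parameters (l1_ratio = 0.75, selection = 'random'), seeding and the
reporting metrics.  Two solver modes are supported: a fixed penalty
(``alpha=1``, the simulation-benchmark setting) and a cross-validated
regularisation path (``cv_folds=5``, the model-building setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .simulate import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClockModel", "fit_clock", "predict_age", "fit_metrics"]


@dataclass
class ClockModel:
    site_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    hyper: dict = field(default_factory=dict)


def fit_clock(matrix: MethylationMatrix, ages, cv_folds: int = 5,
              l1_ratio: float = 0.75, alpha: float | None = None,
              seed: int = 0) -> ClockModel:
    """Fit the elastic-net age model.

    With ``alpha`` given, a fixed-penalty ``ElasticNet`` is fit; otherwise the
    penalty is chosen by ``ElasticNetCV`` over ``cv_folds`` folds.
    Deterministic under ``seed`` (coordinate descent uses random coefficient
    selection).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape != (matrix.n_samples,):
        raise ValueError("ages length must match sample count")
    X = matrix.values.T
    if alpha is not None:
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                         selection="random", random_state=seed)
        hyper = {"alpha": alpha, "l1_ratio": l1_ratio, "cv_folds": None,
                 "seed": seed}
    else:
        if matrix.n_samples < cv_folds:
            raise ValueError(
                f"need at least cv_folds={cv_folds} samples, "
                f"got {matrix.n_samples}")
        est = ElasticNetCV(cv=cv_folds, l1_ratio=l1_ratio,
                           selection="random", random_state=seed)
        hyper = {"alpha": None, "l1_ratio": l1_ratio, "cv_folds": cv_folds,
                 "seed": seed}
    est.fit(X, ages)
    if alpha is None:
        hyper["alpha_selected"] = float(est.alpha_)
    logger.info("clock fit on %d sites x %d samples (%d nonzero coefficients)",
                matrix.n_sites, matrix.n_samples,
                int(np.count_nonzero(est.coef_)))
    return ClockModel(
        site_ids=list(matrix.site_ids),
        coefficients=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_),
        hyper=hyper,
    )


def predict_age(model: ClockModel, matrix_new: MethylationMatrix) -> np.ndarray:
    """Predicted ages ``X @ beta + intercept`` with site alignment checks."""
    if matrix_new.site_ids != model.site_ids:
        missing = sorted(set(model.site_ids) - set(matrix_new.site_ids))
        if missing:
            raise KeyError(
                f"matrix is missing {len(missing)} model sites, e.g. {missing[:5]}")
        matrix_new = matrix_new.subset_sites(model.site_ids)
    return matrix_new.values.T @ model.coefficients + model.intercept


def fit_metrics(true_ages, predictions) -> tuple[float, float]:
    """(R^2, MAE) of age predictions."""
    y = np.asarray(true_ages, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("true ages are constant; R^2 is undefined")
    r2 = 1.0 - float(np.sum((y - p) ** 2)) / ss_tot
    mae = float(np.mean(np.abs(y - p)))
    return r2, mae
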