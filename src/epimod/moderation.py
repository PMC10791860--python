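"""Moderation analysis: which factors shift the epigenetic state or age?

Given per-sample outcomes (pacemaker states or clock-predicted ages) the
moderation model is an ordinary least-squares fit

    S_j = b0 + b1 * age + b2 * sqrt(age) + covariates ... [+ sex]

with classical standard errors and two-sided t-tests per term.  The sqrt(age)
term absorbs the concave age trend of methylation so that moderator terms
(health, binary group status, cell-type principal components, exposure)
capture genuine acceleration or deceleration.  The sex term is dropped when
the cohort is more than 70% female, mirroring the rule used for heavily
sex-imbalanced studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CovariatePCA",
    "DesignMatrix",
    "ModerationResult",
    "fit_celltype_pca",
    "build_design",
    "fit_moderation",
    "significance_summary",
]

FEMALE_DROP_THRESHOLD = 0.7


@dataclass
class CovariatePCA:
    """3-component PCA of cell-type fractions, fit on training samples only."""

    components: np.ndarray      # 3 x n_types orthonormal loadings
    mean: np.ndarray
    explained_variance: np.ndarray
    feature_names: list[str]

    def transform(self, fractions) -> np.ndarray:
        F = _as_fraction_array(fractions, self.feature_names)
        return (F - self.mean) @ self.components.T


def _as_fraction_array(fractions, feature_names=None) -> np.ndarray:
    if isinstance(fractions, pd.DataFrame):
        if feature_names is not None:
            fractions = fractions.loc[:, feature_names]
        return fractions.to_numpy(dtype=float)
    return np.asarray(fractions, dtype=float)


def fit_celltype_pca(fractions_train) -> CovariatePCA:
    """Fit the 3-component cell-type PCA on training fractions."""
    names = (list(fractions_train.columns)
             if isinstance(fractions_train, pd.DataFrame) else None)
    F = _as_fraction_array(fractions_train)
    if F.shape[0] < 4:
        raise ValueError("need at least 4 training samples")
    if F.shape[1] < 3:
        raise ValueError("need at least 3 cell types")
    centered = F - F.mean(axis=0)
    if np.linalg.matrix_rank(centered) < 3:
        raise ValueError("cell-type fractions have rank < 3; PCA is degenerate")
    pca = PCA(n_components=3).fit(F)
    if names is None:
        names = [f"celltype_{t}" for t in range(F.shape[1])]
    return CovariatePCA(
        components=np.asarray(pca.components_, dtype=float),
        mean=np.asarray(pca.mean_, dtype=float),
        explained_variance=np.asarray(pca.explained_variance_, dtype=float),
        feature_names=names,
    )


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame
    sex_term_dropped: bool = False


def _encode_sex(sex_labels) -> np.ndarray:
    """0/1 female indicator from labels ('F'/'M', 'female'/'male' or 0/1)."""
    arr = np.asarray(sex_labels)
    if arr.dtype.kind in "biuf":
        vals = arr.astype(float)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("numeric sex labels must be 0/1 (1 = female)")
        return vals
    out = np.empty(arr.shape, dtype=float)
    for i, v in enumerate(arr):
        s = str(v).strip().lower()
        if s in ("f", "female", "1"):
            out[i] = 1.0
        elif s in ("m", "male", "0"):
            out[i] = 0.0
        else:
            raise ValueError(f"unrecognised sex label {v!r}")
    return out


def build_design(ages, covariates: Mapping[str, Sequence[float]] | None = None,
                 sex_labels=None,
                 female_drop_threshold: float = FEMALE_DROP_THRESHOLD) -> DesignMatrix:
    """Moderation design matrix: intercept, age, sqrt(age), covariates, sex.

    Covariates keep their declared order.  The sex column (1 = female) is
    appended unless the female proportion exceeds ``female_drop_threshold``,
    in which case it is dropped and the decision recorded.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    cols = {"intercept": np.ones_like(ages), "age": ages,
            "sqrt_age": np.sqrt(ages)}
    for name, values in (covariates or {}).items():
        arr = np.asarray(values)
        if arr.dtype.kind not in "biuf":
            raise ValueError(f"covariate {name!r} is not numeric")
        if arr.shape != ages.shape:
            raise ValueError(f"covariate {name!r} length mismatch")
        cols[name] = arr.astype(float)
    dropped = False
    if sex_labels is not None:
        female = _encode_sex(sex_labels)
        if female.mean() > female_drop_threshold:
            dropped = True
            logger.info("sex term dropped: female proportion %.2f > %.2f",
                        female.mean(), female_drop_threshold)
        else:
            cols["sex"] = female
    return DesignMatrix(matrix=pd.DataFrame(cols), sex_term_dropped=dropped)


@dataclass
class ModerationResult:
    """One fitted moderation model; per-term estimates, SEs and p-values."""

    outcome_label: str
    terms: pd.DataFrame          # index term, columns estimate/se/t/p
    n_samples: int
    sex_term_dropped: bool = False
    batch: str = "all"

    def p_value(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    """Name the columns involved in a rank deficiency via pivoted QR."""
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return []
    # greedily keep independent columns; the rest are the collinear ones
    kept: list[int] = []
    for j in range(A.shape[1]):
        trial = A[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
    return [c for i, c in enumerate(X.columns) if i not in kept]


def fit_moderation(outcome, design: DesignMatrix,
                   outcome_label: str = "outcome",
                   batch: str = "all") -> ModerationResult:
    """OLS moderation fit with classical SEs and two-sided t-test p-values."""
    y = np.asarray(outcome, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match design")
    if y.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n_samples > n_terms + 1")
    bad = _collinear_terms(X)
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues,
         "p": fit.pvalues},
        index=list(X.columns),
    )
    return ModerationResult(
        outcome_label=outcome_label, terms=terms, n_samples=int(y.shape[0]),
        sex_term_dropped=design.sex_term_dropped, batch=batch,
    )


def significance_summary(results: Sequence[ModerationResult], alpha: float = 0.05,
                         n_models_for_bonferroni: int | None = None) -> pd.DataFrame:
    """Count, per term, how many models reach significance.

    With ``n_models_for_bonferroni`` set, the threshold is ``alpha / n``
    (e.g. 0.05 / 13 ~ 0.0038); otherwise ``alpha`` is used directly.
    """
    threshold = alpha
    if n_models_for_bonferroni is not None:
        threshold = alpha / n_models_for_bonferroni
    counts: dict[str, list[int]] = {}
    for res in results:
        for term, p in res.terms["p"].items():
            sig, tot = counts.setdefault(term, [0, 0])
            counts[term] = [sig + int(p < threshold), tot + 1]
    return pd.DataFrame(
        [(t, sig, tot, threshold) for t, (sig, tot) in counts.items()],
        columns=["term", "n_significant", "n_models", "threshold"],
    ).set_index("term")
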