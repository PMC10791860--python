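"""Epigenetic pacemaker: latent-state modelling of methylation trajectories.

Each site's methylation is modelled as linear in a shared latent per-sample
epigenetic state::

    m_ij = m0_i + r_i * s_j + eps_ij

where ``m0_i`` is the site's initial methylation, ``r_i`` its rate of change
and ``s_j`` the sample's epigenetic state.  Unlike an age-prediction clock,
the state need not be linear in chronological age, so nonlinear methylation
trajectories and non-age moderators are absorbed into ``s_j`` rather than
discarded as error.

Fitting is a conditional expectation-maximisation (block coordinate descent on
the total squared error): starting from ``s_j = age_j``, alternate (1) per-site
ordinary least squares of methylation on the current states and (2) the
per-sample closed-form state update

    s_j = sum_i r_i (m_ij - m0_i) / sum_i r_i^2

which is the exact least-squares minimiser of the per-sample SSE.  Each half
step can only lower the total SSE, so the error trace is non-increasing.  The
model is identifiable only up to the affine anchoring supplied by the age
initialisation (scaling states by ``c`` and rates by ``1/c`` leaves the fit
unchanged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EPMModel",
    "StateAgeMap",
    "fit_site_models",
    "update_states",
    "fit_epm",
    "predict_states",
    "model_error",
]

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100


@dataclass
class EPMModel:
    """Fitted pacemaker model: per-site lines, per-sample states, diagnostics."""

    m0: np.ndarray
    rates: np.ndarray
    states: np.ndarray
    n_iter: int
    error_trace: np.ndarray
    site_ids: list[str]
    sample_ids: list[str]


def fit_site_models(matrix: MethylationMatrix, states) -> tuple[np.ndarray, np.ndarray]:
    """Per-site OLS intercepts and slopes of methylation on the states."""
    s = np.asarray(states, dtype=float)
    if s.shape != (matrix.n_samples,):
        raise ValueError("states length must match sample count")
    centered = s - s.mean()
    denom = centered @ centered
    if denom == 0.0:
        raise ValueError("states are constant; per-site slopes are undefined")
    M = matrix.values
    rates = (M @ centered) / denom
    m0 = M.mean(axis=1) - rates * s.mean()
    return m0, rates


def update_states(matrix: MethylationMatrix, m0, rates) -> np.ndarray:
    """Closed-form least-squares state update holding site models fixed."""
    m0 = np.asarray(m0, dtype=float)
    rates = np.asarray(rates, dtype=float)
    r2 = rates @ rates
    if r2 == 0.0:
        raise ValueError("all site rates are zero; states are undetermined")
    return rates @ (matrix.values - m0[:, None]) / r2


def model_error(matrix: MethylationMatrix, model: EPMModel,
                states=None) -> tuple[float, float]:
    """(SSE, MAE) between observed and modelled methylation values."""
    s = model.states if states is None else np.asarray(states, dtype=float)
    predicted = model.m0[:, None] + np.outer(model.rates, s)
    resid = matrix.values - predicted
    return float(np.sum(resid ** 2)), float(np.mean(np.abs(resid)))


def _sse(M: np.ndarray, m0: np.ndarray, rates: np.ndarray, s: np.ndarray) -> float:
    resid = M - m0[:, None] - np.outer(rates, s)
    return float(np.sum(resid ** 2))


def fit_epm(matrix: MethylationMatrix, ages, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER,
            init_states=None) -> EPMModel:
    """Fit the pacemaker by conditional EM.

    States are initialised at the chronological ages (``init_states``
    overrides, e.g. for anchoring experiments) and the site-fit / state-update
    alternation runs until the relative SSE reduction falls below ``tol`` or
    ``max_iter`` is reached.
    """
    ages = np.asarray(ages, dtype=float)
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 sites")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if ages.shape != (matrix.n_samples,):
        raise ValueError("ages length must match sample count")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages contain non-finite values")
    if np.ptp(ages) == 0.0:
        raise ValueError("ages are constant; the state scale cannot be anchored")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("matrix contains non-finite values")

    s = np.array(ages if init_states is None else init_states, dtype=float)
    M = matrix.values
    trace: list[float] = []
    prev = np.inf
    m0 = rates = None
    for it in range(1, max_iter + 1):
        m0, rates = fit_site_models(matrix, s)
        if np.max(np.abs(rates)) < 1e-14:    # all sites flat up to round-off
            raise ValueError("degenerate fit: every site rate is zero")
        s = update_states(matrix, m0, rates)
        sse = _sse(M, m0, rates, s)
        trace.append(sse)
        if sse <= 1e-24 * M.size:    # exact fit up to round-off
            break
        if prev < np.inf and (prev - sse) / prev < tol:
            break
        prev = sse
    n_iter = len(trace)
    logger.info("EPM converged in %d iterations (SSE %.4g)", n_iter, trace[-1])
    return EPMModel(
        m0=m0, rates=rates, states=s, n_iter=n_iter,
        error_trace=np.asarray(trace),
        site_ids=list(matrix.site_ids),
        sample_ids=list(matrix.sample_ids),
    )


def predict_states(model: EPMModel, matrix_new: MethylationMatrix) -> np.ndarray:
    """Epigenetic states for unseen samples: one state update with the
    trained site models held fixed."""
    if matrix_new.site_ids != model.site_ids:
        missing = sorted(set(model.site_ids) - set(matrix_new.site_ids))
        if missing:
            raise KeyError(
                f"matrix is missing {len(missing)} model sites, e.g. {missing[:5]}")
        matrix_new = matrix_new.subset_sites(model.site_ids)
    return update_states(matrix_new, model.m0, model.rates)


@dataclass
class StateAgeMap:
    """Optional map between epigenetic states and a year-denominated axis.

    Fits ``state = a + b * age + c * sqrt(age)`` on training data; inverting
    the fit maps a state to an "EPM age" in years, used when reporting
    state-to-age mean absolute errors.  ``r2`` is the coefficient of
    determination of the trend fit (states against the age trend).
    """

    a: float
    b: float
    c: float
    r2: float
    u_range: tuple[float, float]

    @classmethod
    def fit(cls, states, ages) -> "StateAgeMap":
        states = np.asarray(states, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative")
        u = np.sqrt(ages)
        X = np.column_stack([np.ones_like(ages), ages, u])
        coef, *_ = np.linalg.lstsq(X, states, rcond=None)
        fitted = X @ coef
        ss_res = float(np.sum((states - fitted) ** 2))
        ss_tot = float(np.sum((states - states.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return cls(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                   r2=r2, u_range=(float(u.min()), float(u.max())))

    def expected_state(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return self.a + self.b * ages + self.c * np.sqrt(ages)

    def to_age(self, states) -> np.ndarray:
        """Invert the trend: solve b*u^2 + c*u + (a - s) = 0 for u = sqrt(age).

        The real non-negative root closest to the training sqrt-age range is
        taken; when the discriminant is negative the vertex is used.  Results
        are clamped to age >= 0.
        """
        s = np.atleast_1d(np.asarray(states, dtype=float))
        mid = 0.5 * (self.u_range[0] + self.u_range[1])
        if abs(self.b) < 1e-12:
            if abs(self.c) < 1e-12:
                raise ValueError("degenerate state-age trend (b = c = 0)")
            u = (s - self.a) / self.c
        else:
            disc = self.c ** 2 + 4.0 * self.b * (s - self.a)
            sqrt_disc = np.sqrt(np.clip(disc, 0.0, None))
            r1 = (-self.c + sqrt_disc) / (2.0 * self.b)
            r2_ = (-self.c - sqrt_disc) / (2.0 * self.b)
            # prefer the non-negative root nearest the training range
            u = np.where(
                np.abs(np.clip(r1, 0, None) - mid) <= np.abs(np.clip(r2_, 0, None) - mid),
                r1, r2_)
            u = np.where(disc < 0, -self.c / (2.0 * self.b), u)
        u = np.clip(u, 0.0, None)
        return u ** 2
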