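"""Weighted gamma GLM with log link, and the REML leverage adjustment.

If the mean-model coefficients were known, each squared residual
``e_i^2`` would be ``phi_i * chi^2_1`` — gamma distributed with mean
``phi_i`` and scale parameter 2 — so the per-record residual variance is
estimated by a gamma GLM on the squared residuals with a log link.
Because the residuals are *predicted*, ``E[e_hat_i^2] < phi_i``; using
the response ``e_hat_i^2 / (1 - h_i)`` with prior weights
``(1 - h_i)/2`` (h_i the augmented-model leverages) restores
unbiasedness and makes the whole scheme deliver REML rather than ML
estimates.  The gamma scale of 2 is absorbed into those weights; no
separate scale parameter is estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

logger = logging.getLogger(__name__)

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-10
#: cap for the deviance of an exactly-zero response (zero weight upstream)
DEVIANCE_CAP = 1e10


@dataclass
class GammaFit:
    """Result of a weighted gamma GLM fit (log link)."""

    coef: np.ndarray
    fitted: np.ndarray
    deviance_components: np.ndarray
    working_weights: np.ndarray
    converged: bool
    n_iter: int


def deviance_components(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Per-observation gamma deviance d_i = 2[-log(y_i/mu_i) + (y_i-mu_i)/mu_i].

    Zero iff ``y_i == mu_i``.  ``y_i = 0`` has infinite limit; it is
    capped (such records carry zero weight upstream).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    pos = y > 0
    d = np.full(y.shape, DEVIANCE_CAP)
    d[pos] = 2.0 * (-np.log(y[pos] / mu[pos]) + (y[pos] - mu[pos]) / mu[pos])
    return np.maximum(d, 0.0)  # guard tiny negative round-off at y == mu


def reml_adjusted_response(
    sq_residuals: np.ndarray, leverages: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leverage-corrected dispersion response and prior weights.

    Returns ``(e^2/(1-h), (1-h)/2)``.  Leverages must already be clipped
    below 1 (see :func:`dhglm.wls.clip_leverages`); a record with h at
    the cap keeps a vanishing weight instead of being dropped.
    """
    e2 = np.asarray(sq_residuals, dtype=float)
    h = np.asarray(leverages, dtype=float)
    if np.any(e2 < 0):
        raise ValueError("squared residuals must be non-negative")
    if np.any(h < 0) or np.any(h >= 1.0):
        raise ValueError("leverages must lie in [0, 1) after clipping")
    return e2 / (1.0 - h), (1.0 - h) / 2.0


def fit_gamma_glm(
    y: np.ndarray,
    X: np.ndarray,
    prior_weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = MAX_IRLS_ITER,
    tol: float = IRLS_TOL,
) -> GammaFit:
    """Weighted gamma GLM with log link, fitted by IRLS.

    For the log link the working weight equals the prior weight
    ((dmu/deta)^2 / V(mu) = 1), so the IRLS weight matrix is fixed and
    only the working response ``eta + (y - mu)/mu`` is iterated.  Zero
    responses are allowed only with zero prior weight and are floored so
    the log link is defined; non-convergence is flagged, not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = np.ones(n) if prior_weights is None else np.asarray(
        prior_weights, dtype=float).ravel()
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("prior weights must be non-negative")
    if np.count_nonzero(w) < p:
        raise ValueError(f"need at least {p} records with positive weight")
    if np.any(y < 0):
        raise ValueError("responses must be non-negative")
    if np.any((y == 0) & (w > 0)):
        active = y[w > 0]
        if np.all(active == 0):
            raise ValueError("all responses with positive weight are zero")
        floor = 1e-12 * active.mean()
        y = np.maximum(y, floor)
    if np.all(y[w > 0] == 0):
        raise ValueError("all responses with positive weight are zero")

    mu = np.maximum(y, 1e-10 * y[w > 0].mean())
    eta = np.log(mu)
    Xw = X * w[:, None]
    A = Xw.T @ X
    try:
        c_low = sla.cho_factor(A)
        solve = lambda b: sla.cho_solve(c_low, b)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
        solve = lambda b: Ainv @ b
        logger.warning("singular gamma-GLM normal equations; pseudo-inverse used")

    coef = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta - off + (y - mu) / mu
        new = solve(Xw.T @ z)
        delta = np.max(np.abs(new - coef)) if it > 1 else np.inf
        coef = new
        eta = X @ coef + off
        mu = np.exp(np.clip(eta, -700, 700))
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("gamma GLM IRLS did not converge in %d iterations", max_iter)
    return GammaFit(
        coef=coef,
        fitted=mu,
        deviance_components=deviance_components(y, mu),
        working_weights=w,
        converged=converged,
        n_iter=it,
    )
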