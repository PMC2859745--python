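"""Random-effect variance updates from leverage-adjusted BLUP summaries.

At the REML optimum the variance of a normal random effect satisfies
``sigma_u2 = sum(u_hat_j^2) / sum(1 - h_j)`` — the closed form of an
intercept-only weighted gamma GLM (log link) on ``u_hat_j^2/(1-h_j)``
with weights ``(1-h_j)/2``, where ``h_j`` are the last q leverages of
the augmented system and ``1-h_j`` is the BLUP reliability.  The same
estimator applied to the gamma deviance components of the dispersion
pseudo-records yields the variance of the dispersion random effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: lower floor keeping the augmented covariance positive definite
VARIANCE_FLOOR = 1e-8


@dataclass
class VarianceEstimate:
    """A variance-component estimate with its effective information."""

    value: float
    n_levels: int
    effective_df: float
    at_floor: bool = False


def _ratio_estimate(num: np.ndarray, leverages: np.ndarray,
                    floor: float) -> VarianceEstimate:
    num = np.asarray(num, dtype=float).ravel()
    h = np.asarray(leverages, dtype=float).ravel()
    if num.size != h.size:
        raise ValueError("numerator and leverage lengths disagree")
    if np.any(h < 0) or np.any(h >= 1.0):
        raise ValueError("leverages must lie in [0, 1) after clipping")
    edf = float(np.sum(1.0 - h))
    if edf <= 1e-6:
        raise ValueError("all leverages at cap: no information for this variance")
    value = float(np.sum(num)) / edf
    at_floor = value < floor
    if at_floor:
        logger.info("variance estimate %.3g at floor %.1g", value, floor)
        value = floor
    return VarianceEstimate(value=value, n_levels=num.size,
                            effective_df=edf, at_floor=at_floor)


def estimate_variance_from_blups(
    u_hat: np.ndarray, leverages_q: np.ndarray, floor: float = VARIANCE_FLOOR
) -> VarianceEstimate:
    """sigma_u2 = sum(u_hat_j^2) / sum(1 - h_j) for a mean-part random term."""
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    return _ratio_estimate(u_hat**2, leverages_q, floor)


def estimate_dispersion_variance(
    d_d: np.ndarray, leverages_d: np.ndarray, floor: float = VARIANCE_FLOOR
) -> VarianceEstimate:
    """sigma_d2 = sum(d_dj) / sum(1 - h_dj) for a dispersion random term.

    ``d_d`` holds either the gamma deviance components of the
    pseudo-records (h-likelihood variant) or their squared scaled
    residuals ``u_d_hat^2`` (PQL variant).
    """
    d_d = np.asarray(d_d, dtype=float).ravel()
    if np.any(d_d < 0):
        raise ValueError("deviance components must be non-negative")
    return _ratio_estimate(d_d, leverages_d, floor)
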