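"""Independent oracles used by the tests.

Deliberately brute-force and separate from the package's augmented-WLS
path: dense restricted-likelihood maximization for variance components,
direct numerical maximization of (penalized) gamma likelihoods, and the
hand-tabulated relationship matrix method.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize as opt


def restricted_loglik(y, X, Z, sigma_u2, sigma_e2) -> float:
    """REML log-likelihood of a one-random-term LMM, dense and direct."""
    n = y.size
    V = sigma_u2 * (Z @ Z.T) + sigma_e2 * np.eye(n)
    cF = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(cF)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    return -0.5 * (logdetV + logdetX + quad)


def reml_fit(y, X, Z, x0=(0.0, 0.0)) -> tuple[float, float]:
    """Maximize the restricted likelihood over (sigma_u2, sigma_e2)."""
    Zd = np.asarray(Z.todense()) if hasattr(Z, "todense") else np.asarray(Z)

    def nll(logs):
        return -restricted_loglik(y, X, Zd, np.exp(logs[0]), np.exp(logs[1]))

    res = opt.minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12,
                                "maxiter": 4000, "maxfev": 4000})
    assert res.success or res.fun < nll(np.asarray(x0)) - 1e-10
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


def gamma_glm_loglik(coef, y, X, w, offset=0.0) -> float:
    """Weighted gamma log-quasi-likelihood with log link (scale absorbed)."""
    eta = X @ coef + offset
    return float(np.sum(w * (-y * np.exp(-eta) - eta)))


def gamma_glm_fit(y, X, w) -> np.ndarray:
    """Direct numerical maximizer of the weighted gamma quasi-likelihood."""
    res = opt.minimize(lambda c: -gamma_glm_loglik(c, y, X, w),
                       np.zeros(X.shape[1]), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 20000})
    return res.x


def penalized_gamma_fit(y, Xd, Zd, w, sigma_d2) -> np.ndarray:
    """Maximize the gamma quasi-likelihood penalized by u'u/(2 sigma_d2)."""
    Zdd = np.asarray(Zd.todense()) if hasattr(Zd, "todense") else np.asarray(Zd)
    p, q = Xd.shape[1], Zdd.shape[1]
    C = np.hstack([Xd, Zdd])

    def nobj(c):
        return -(gamma_glm_loglik(c, y, C, w)
                 - 0.5 * np.sum(c[p:] ** 2) / sigma_d2)

    res = opt.minimize(nobj, np.zeros(p + q), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 10000})
    return res.x


def tabular_relationship(records) -> tuple[np.ndarray, dict]:
    """Additive relationship matrix by the classic tabular method.

    ``records``: (animal, sire, dam) with "0" for unknown, parents first.
    """
    ids = [a for a, _, _ in records]
    idx = {a: i for i, a in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for i, (a, s, d) in enumerate(records):
        si = idx.get(s) if s != "0" else None
        di = idx.get(d) if d != "0" else None
        for j in range(i):
            aij = 0.0
            if si is not None:
                aij += 0.5 * A[j, si]
            if di is not None:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None
                         else 0.0)
    return A, idx
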