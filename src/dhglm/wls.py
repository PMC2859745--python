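"""Augmented weighted least squares = Henderson's mixed-model equations.

The linear mixed model ``y = X b + Z u + e`` with ``Var(e) = diag(phi)``
and ``Var(u) = diag(sigma_u2)`` is solved as one weighted least-squares
problem on the augmented design

    T = [[X, Z],       y_a = [y,      Sigma_a = diag(phi,
         [0, I_q]]            0]                 sigma_u2)

whose normal equations are exactly Henderson's mixed-model equations.
The hat matrix ``H = T (T' Sigma_a^-1 T)^- T' Sigma_a^-1`` yields the
leverages: the first n diagonal entries are the data leverages ``h_i``
feeding the REML correction of squared residuals, and for the last q
entries ``1 - h_j`` is the reliability of the BLUP of ``u_j``.

For the common case of mutually orthogonal random-effect columns (a
single one-hot grouping factor), the random-by-random block of the
normal equations is diagonal and everything is computed through a p x p
Schur complement in O(n p^2); otherwise a dense pseudo-inverse path is
used, which also absorbs rank-deficient fixed designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: leverages are clipped into [0, 1 - LEVERAGE_CAP_EPS] before any
#: division by (1 - h); a record at the cap is numerically neutralized
#: (weight ~ 0) rather than dropped.
LEVERAGE_CAP_EPS = 1e-8


@dataclass
class AugmentedSystem:
    """Mean-model (or linearized dispersion-model) augmented system.

    Parameters
    ----------
    X : (n, p) dense fixed-effects design.
    Z : (n, q) sparse/dense random-effects incidence (possibly
        relationship-folded), or None for a fixed-effects-only model.
    y : (n,) response.
    phi : (n,) per-record residual variances (first n entries of the
        Sigma_a diagonal).
    sigma_u2 : per-column random-effect variances — scalar or (q,)
        vector (last q entries of the Sigma_a diagonal).
    """

    X: np.ndarray
    Z: sp.spmatrix | np.ndarray | None
    y: np.ndarray
    phi: np.ndarray
    sigma_u2: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.phi = np.asarray(self.phi, dtype=float).ravel()
        n = self.y.size
        if self.X.shape[0] != n or self.phi.size != n:
            raise ValueError("X, y and phi row counts disagree")
        q = 0 if self.Z is None else self.Z.shape[1]
        if self.Z is not None and self.Z.shape[0] != n:
            raise ValueError("Z and y row counts disagree")
        self.sigma_u2 = np.broadcast_to(
            np.asarray(self.sigma_u2, dtype=float), (q,)
        ).copy()
        for name, arr in (("X", self.X), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
        if not np.all(np.isfinite(self.phi)) or np.any(self.phi <= 0):
            raise ValueError("phi must be strictly positive and finite")
        if q and (np.any(~np.isfinite(self.sigma_u2)) or np.any(self.sigma_u2 <= 0)):
            raise ValueError("sigma_u2 must be strictly positive and finite")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    @property
    def T(self) -> sp.csr_matrix:
        """Stacked augmented design ((n+q) x (p+q))."""
        top = sp.hstack(
            [sp.csr_matrix(self.X)]
            + ([sp.csr_matrix(self.Z)] if self.Z is not None else []),
            format="csr",
        )
        if self.q == 0:
            return top
        bottom = sp.hstack(
            [sp.csr_matrix((self.q, self.p)), sp.eye(self.q, format="csr")],
            format="csr",
        )
        return sp.vstack([top, bottom], format="csr")

    @property
    def y_a(self) -> np.ndarray:
        """Augmented response: data over pseudo-records E(u) = 0."""
        return np.concatenate([self.y, np.zeros(self.q)])

    @property
    def sigma_a(self) -> np.ndarray:
        """Diagonal of the augmented covariance."""
        return np.concatenate([self.phi, self.sigma_u2])


@dataclass
class WlsSolution:
    """Solution of an augmented system.

    ``delta`` stacks (b, u); ``hat_diag`` holds the n data leverages then
    the q pseudo-record leverages; ``residuals`` are y - X b - Z u.
    """

    delta: np.ndarray
    hat_diag: np.ndarray
    residuals: np.ndarray
    rank: int
    used_pinv: bool = False

    def split(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        return self.delta[:p], self.delta[p:]


def _quadform_rows(R: np.ndarray, solve) -> np.ndarray:
    """Row-wise r' S^{-1} r given a solver for S x = b."""
    return np.einsum("ij,ij->i", R, solve(R.T).T)


def solve_augmented(system: AugmentedSystem) -> WlsSolution:
    """Solve the augmented WLS problem and return solutions + leverages.

    Minimizes (y_a - T delta)' Sigma_a^-1 (y_a - T delta); the normal
    equations coincide with Henderson's mixed-model equations, and
    ``hat_diag`` holds the diagonal of
    ``T (T' Sigma_a^-1 T)^- T' Sigma_a^-1``.
    """
    n, p, q = system.n, system.p, system.q
    X, y, w = system.X, system.y, 1.0 / system.phi
    Z = None if q == 0 else sp.csr_matrix(system.Z)

    Xw = X * w[:, None]
    A = X.T @ Xw                      # p x p
    rhs_x = Xw.T @ y
    if q == 0:
        try:
            c, low = sla.cho_factor(A)
            solve = lambda B: sla.cho_solve((c, low), B)
            used_pinv = False
            rank = p
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
            solve = lambda B: Ainv @ B
            used_pinv = True
            rank = np.linalg.matrix_rank(A)
            logger.warning("singular fixed-effects normal equations; pseudo-inverse used")
        b = solve(rhs_x)
        h = w * _quadform_rows(X, solve)
        resid = y - X @ b
        return WlsSolution(delta=b, hat_diag=np.clip(h, 0.0, 1.0),
                           residuals=resid, rank=rank, used_pinv=used_pinv)

    Zw = Z.multiply(w[:, None]).tocsr()
    B = np.asarray((Zw.T @ X).T)      # p x q
    Mzz = (Zw.T @ Z).tocoo()          # q x q
    rhs_z = Zw.T @ y
    off_diag = np.any(Mzz.row != Mzz.col) and np.any(
        Mzz.data[Mzz.row != Mzz.col] != 0.0
    )

    if not off_diag:
        # Schur-complement fast path: random block diagonal.
        d = np.zeros(q)
        np.add.at(d, Mzz.row[Mzz.row == Mzz.col], Mzz.data[Mzz.row == Mzz.col])
        d += 1.0 / system.sigma_u2
        C = B / d                     # p x q
        S = A - C @ B.T
        try:
            c, low = sla.cho_factor(S)
        except np.linalg.LinAlgError:
            return _solve_dense(system, w)
        solve = lambda Bm: sla.cho_solve((c, low), Bm)
        b = solve(rhs_x - C @ rhs_z)
        u = (rhs_z - B.T @ b) / d
        # data leverages: h_i = w_i [ (x_i - C z_i)' S^-1 (x_i - C z_i) + z_i' D^-1 z_i ]
        R = X - np.asarray(Z @ C.T)
        zDz = np.asarray(Z.multiply(Z) @ (1.0 / d)).ravel()
        h_data = w * (_quadform_rows(R, solve) + zDz)
        # pseudo-record leverages: h_j = M^-1[p+j, p+j] / sigma_u2_j
        CS = solve(C)                 # S^-1 C
        h_aug = (1.0 / d + np.einsum("ij,ij->j", C, CS)) / system.sigma_u2
        delta = np.concatenate([b, u])
        resid = y - X @ b - np.asarray(Z @ u).ravel()
        h = np.clip(np.concatenate([h_data, h_aug]), 0.0, 1.0)
        return WlsSolution(delta=delta, hat_diag=h, residuals=resid, rank=p + q)

    return _solve_dense(system, w)


def _solve_dense(system: AugmentedSystem, w: np.ndarray) -> WlsSolution:
    """Dense generalized-inverse path (general Z, rank-deficient X)."""
    n, p, q = system.n, system.p, system.q
    G = np.hstack([system.X, np.asarray(
        system.Z.todense() if sp.issparse(system.Z) else system.Z)])
    M = (G * w[:, None]).T @ G
    M[p:, p:] += np.diag(1.0 / system.sigma_u2)
    rhs = (G * w[:, None]).T @ system.y
    Minv = np.linalg.pinv(M, hermitian=True)
    delta = Minv @ rhs
    h_data = w * np.einsum("ij,jk,ik->i", G, Minv, G)
    h_aug = np.diag(Minv)[p:] / system.sigma_u2
    resid = system.y - G @ delta
    rank = int(np.linalg.matrix_rank(M))
    if rank < p + q:
        logger.warning("rank-deficient augmented design (rank %d < %d); "
                       "pseudo-inverse used", rank, p + q)
    h = np.clip(np.concatenate([h_data, h_aug]), 0.0, 1.0)
    return WlsSolution(delta=delta, hat_diag=h, residuals=resid,
                       rank=rank, used_pinv=rank < p + q)


def hat_diagonal_weighted(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leverages of a weighted fixed-effects model: diag X (X'WX)^- X'W.

    Used by the fixed-effects-only dispersion path; falls back to a
    pseudo-inverse (logged) when X'WX is singular.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = np.asarray(w, dtype=float).ravel()
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    A = (X * w[:, None]).T @ X
    try:
        c, low = sla.cho_factor(A)
        solve = lambda B: sla.cho_solve((c, low), B)
    except np.linalg.LinAlgError:
        logger.warning("singular X'WX in hat_diagonal_weighted; pseudo-inverse used")
        Ainv = np.linalg.pinv(A)
        solve = lambda B: Ainv @ B
    return np.clip(w * _quadform_rows(X, solve), 0.0, 1.0)


def clip_leverages(h: np.ndarray) -> np.ndarray:
    """Clip leverages to at most 1 - LEVERAGE_CAP_EPS before 1/(1-h) use."""
    return np.minimum(h, 1.0 - LEVERAGE_CAP_EPS)
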