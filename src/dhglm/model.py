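"""The DHGLM estimator: random effects in both mean and residual variance.

Model.  Conditional on random effects ``u`` (mean part) and ``u_d``
(dispersion part), the trait is normal::

    y | u, u_d ~ N(X b + Z u,  diag(phi)),   log(phi) = X_d b_d + Z_d u_d,
    u ~ N(0, I sigma_u2),  u_d ~ N(0, I sigma_d2),  cov(u, u_d) = 0.

Correlated (pedigree) effects are folded into the incidence matrices so
each random vector is i.i.d.  Fitting iterates between

1. Henderson's mixed-model equations for (b, u), written as one
   augmented weighted least-squares problem, with leverages h;
2. ``sigma_u2 = sum(u_hat^2) / sum(1 - h_j)``;
3. a gamma GLM/GLMM with log link on the REML-adjusted squared
   residuals ``e_hat^2/(1-h_i)`` with weights ``(1-h_i)/2`` for
   (b_d, u_d), itself an augmented IRLS with pseudo-records shrinking
   u_d to 0 with variance sigma_d2;
4. ``sigma_d2`` from the pseudo-record deviances (h-likelihood variant)
   or their squared scaled residuals (PQL variant, the default);
5. new weights ``W = diag(exp(-X_d b_d - Z_d u_d))``;

until the largest change in any variance component drops below ``tol``.
With an intercept-only fixed dispersion the loop collapses to exact
REML for the ordinary linear mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .design import (FixedDesign, RandomDesign, build_fixed_design,
                     build_random_design, rebuild_fixed_design)
from .gamma import deviance_components, fit_gamma_glm, reml_adjusted_response
from .pedigree import (Pedigree, RelationshipFactor, build_relationship_factor,
                       fold_relationship, read_pedigree)
from .varcomp import (VARIANCE_FLOOR, estimate_dispersion_variance,
                      estimate_variance_from_blups)
from .wls import (AugmentedSystem, WlsSolution, clip_leverages,
                  hat_diagonal_weighted, solve_augmented)

logger = logging.getLogger(__name__)

#: a variance component exceeding this multiple of var(y) flags divergence
DIVERGENCE_FACTOR = 1e8
#: leverage above this marks a record as contributing no information
LEVERAGE_FLAG = 0.99


@dataclass
class DispersionFit:
    """Converged augmented gamma fit of the dispersion part."""

    coef: np.ndarray
    ranef: np.ndarray
    hat_diag: np.ndarray          # length n + q_d
    pseudo_deviances: np.ndarray  # gamma deviances of the q_d pseudo-records
    record_deviances: np.ndarray  # gamma deviances of the n data records
    eta: np.ndarray               # linear predictor for the data records
    converged: bool
    n_iter: int


def fit_dispersion_part(
    y_d: np.ndarray,
    weights: np.ndarray,
    X_d: np.ndarray,
    Z_d,
    sigma_d2,
    inner_tol: float = 1e-8,
    inner_max_iter: int = 50,
    start: np.ndarray | None = None,
) -> DispersionFit:
    """Gamma GLMM (log link) on dispersion responses via augmented IRLS.

    The fixed point solves the IRLS normal equations of the augmented
    system with working response ``eta + (y_d - mu)/mu``, data weights
    ``weights`` (working weight = prior weight under the log link) and
    pseudo-records holding ``u_d`` toward 0 with variance ``sigma_d2``;
    the pseudo-record response is a vector of ones, i.e. zero on the
    linear scale, matching ``E(u_d) = 0``.  At convergence this
    maximizes the weighted gamma quasi-likelihood penalized by
    ``u_d'u_d / (2 sigma_d2)``.

    The iteration itself takes Newton steps (observed information, with
    step halving on the penalized objective), which stay fast for the
    wildly dispersed chi-square-type responses that squared residuals
    produce; the leverages are then read off one final solve with the
    standard expected-information (prior) weights at the converged
    coefficients, where the score vanishes and the solution is a fixed
    point of plain IRLS.
    """
    y_d = np.asarray(y_d, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(y_d < 0):
        raise ValueError("dispersion responses must be non-negative")
    w = np.maximum(w, 1e-12 * max(w.max(), 1.0))
    ybar = y_d[y_d > 0].mean() if np.any(y_d > 0) else 1.0
    y_d = np.maximum(y_d, 1e-12 * ybar)

    p, q = X_d.shape[1], Z_d.shape[1]
    sigma_d2 = np.broadcast_to(np.asarray(sigma_d2, dtype=float), (q,))

    def linpred(coef: np.ndarray) -> np.ndarray:
        return np.clip(X_d @ coef[:p] + np.asarray(Z_d @ coef[p:]).ravel(),
                       -700, 700)

    def objective(coef: np.ndarray) -> float:
        eta = linpred(coef)
        return float(np.sum(w * (-y_d * np.exp(-eta) - eta))
                     - 0.5 * np.sum(coef[p:] ** 2 / sigma_d2))

    if start is not None and np.asarray(start).size == p + q:
        coef = np.asarray(start, dtype=float).copy()
    else:
        coef = np.zeros(p + q)
        coef[0] = np.log(np.average(y_d, weights=w))  # intercept at weighted mean
    converged = False
    it = 0
    obj = objective(coef)
    for it in range(1, inner_max_iter + 1):
        eta = linpred(coef)
        mu = np.exp(eta)
        # Newton step as WLS: observed weights w*y/mu, response eta + (y-mu)/y
        sol = solve_augmented(AugmentedSystem(
            X=X_d, Z=Z_d, y=eta + (y_d - mu) / y_d,
            phi=mu / (w * y_d), sigma_u2=sigma_d2))
        step = sol.delta - coef
        new = sol.delta
        new_obj = objective(new)
        n_halve = 0
        while not (new_obj >= obj - 1e-12) and n_halve < 30:
            step *= 0.5
            new = coef + step
            new_obj = objective(new)
            n_halve += 1
        delta = np.max(np.abs(new - coef))
        coef, obj = new, new_obj
        if delta < inner_tol:
            converged = True
            break
    if not converged:
        logger.warning("dispersion Newton iteration did not converge in %d "
                       "iterations", inner_max_iter)
    # expected-information (prior-weight) system at the optimum: same
    # coefficients, and the hat matrix the REML corrections are built on
    eta = linpred(coef)
    mu = np.exp(eta)
    sol = solve_augmented(AugmentedSystem(
        X=X_d, Z=Z_d, y=eta + (y_d - mu) / mu, phi=1.0 / w,
        sigma_u2=sigma_d2))
    b, u = sol.split(p)
    eta = linpred(sol.delta)
    mu = np.exp(eta)
    # pseudo-record gamma deviance: response 1 against fitted exp(u_j)
    d_pseudo = 2.0 * (u + np.exp(-np.clip(u, -700, 700)) - 1.0)
    return DispersionFit(
        coef=b,
        ranef=u,
        hat_diag=sol.hat_diag,
        pseudo_deviances=np.maximum(d_pseudo, 0.0),
        record_deviances=deviance_components(y_d, mu),
        eta=eta,
        converged=converged,
        n_iter=it,
    )


@dataclass
class _RandomBlock:
    term: str
    Z: object                      # csr or dense ndarray (folded)
    levels: list
    rf: RelationshipFactor | None  # set when pedigree-folded
    sl: slice                      # columns within the stacked Z


class DHGLM(BaseEstimator):
    """Double hierarchical GLM for heteroskedastic linear mixed models.

    Parameters
    ----------
    response : str
        Column of the phenotype table holding the trait (ignored when an
        explicit ``y`` is passed to :meth:`fit`).
    mean_fixed, disp_fixed : sequence of str
        Fixed-effect columns for the mean / log residual-variance linear
        predictors.  An intercept is always included; numeric columns
        enter as covariates, others as treatment-coded factors.
    mean_random, disp_random : sequence of str
        Grouping columns receiving i.i.d. normal random effects.
    pedigree : Pedigree, RelationshipFactor or path, optional
        Additive relationship source for terms named in ``pedigree_for``;
        their incidence matrices are folded with the Cholesky factor L of
        the relationship matrix (animal model).
    variant : {"pql", "hlik"}
        How ``sigma_d2`` is updated: from squared scaled residuals of the
        adjusted dependent variable (PQL, default) or from the gamma
        deviance components (h-likelihood style).
    tol : float
        Outer convergence threshold on the largest absolute change of
        any variance component (default 1e-5).
    max_iter : int
        Outer iteration cap (default 100).
    relaxation : float
        Step factor on variance updates (1.0 = plain iteration).
    variance_floor : float
        Lower bound keeping variances positive.

    Attributes
    ----------
    coef_, disp_coef_ : pandas.Series of fixed effects (mean / dispersion).
    ranef_, disp_ranef_ : dict of term -> pandas.Series of BLUPs (original,
        i.e. pedigree-correlated, scale for folded terms).
    sigma_u2_, sigma_d2_ : dict of term -> variance estimate.
    phi_ : per-record fitted residual variance.
    leverages_, disp_leverages_ : augmented-model leverages (n + q).
    reliability_ : dict of term -> per-level BLUP reliability 1 - h_j.
    trajectory_ : per-iteration variance components (DataFrame).
    converged_, diverged_, n_iter_ : outer-loop status.
    """

    def __init__(
        self,
        response: str | None = None,
        mean_fixed=(),
        mean_random=(),
        disp_fixed=(),
        disp_random=(),
        pedigree=None,
        pedigree_for=(),
        variant: str = "pql",
        tol: float = 1e-5,
        max_iter: int = 100,
        inner_tol: float = 1e-8,
        inner_max_iter: int = 50,
        variance_floor: float = VARIANCE_FLOOR,
        relaxation: float = 1.0,
    ):
        self.response = response
        self.mean_fixed = mean_fixed
        self.mean_random = mean_random
        self.disp_fixed = disp_fixed
        self.disp_random = disp_random
        self.pedigree = pedigree
        self.pedigree_for = pedigree_for
        self.variant = variant
        self.tol = tol
        self.max_iter = max_iter
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.variance_floor = variance_floor
        self.relaxation = relaxation

    # ------------------------------------------------------------------
    def _base_factor(self) -> RelationshipFactor:
        ped = self.pedigree
        if ped is None:
            raise ValueError("pedigree_for given but no pedigree supplied")
        if isinstance(ped, RelationshipFactor):
            return ped
        if isinstance(ped, (str, Path)):
            ped = read_pedigree(ped)
        if isinstance(ped, Pedigree):
            return build_relationship_factor(ped)
        raise TypeError(f"unsupported pedigree type {type(ped).__name__}")

    def _random_blocks(self, data: pd.DataFrame, terms) -> list[_RandomBlock]:
        blocks: list[_RandomBlock] = []
        for term in terms:
            if term in self.pedigree_for:
                rf = self._base_factor()
                ids = [str(v) for v in pd.unique(data[term])]
                missing = [i for i in ids if i not in rf.id_index]
                if missing:
                    logger.warning(
                        "%d phenotyped id(s) absent from pedigree for %r; "
                        "added as founders", len(missing), term)
                    rf = rf.extended(missing)
                coded = data[term].astype(str)
                rd = build_random_design(
                    data.assign(**{term: coded}), term, level_order=rf.ids)
                Z = fold_relationship(rd.Z, rf)
                blocks.append(_RandomBlock(term, Z, rf.ids, rf, slice(0, 0)))
            else:
                rd = build_random_design(data, term)
                blocks.append(_RandomBlock(term, rd.Z, rd.levels, None, slice(0, 0)))
        start = 0
        for b in blocks:
            b.sl = slice(start, start + b.Z.shape[1])
            start += b.Z.shape[1]
        return blocks

    @staticmethod
    def _stack(blocks: list[_RandomBlock]):
        if not blocks:
            return None
        mats = [b.Z for b in blocks]
        if any(isinstance(m, np.ndarray) for m in mats):
            return np.hstack([np.asarray(
                m.todense() if sp.issparse(m) else m) for m in mats])
        return sp.hstack(mats, format="csr")

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "DHGLM":
        """Fit the model to a phenotype table.

        ``X`` is a DataFrame holding the response, fixed-effect and
        grouping columns; ``y`` optionally overrides the response column.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of phenotype records")
        data = X.reset_index(drop=True)
        if y is not None:
            yvec = np.asarray(y, dtype=float).ravel()
        else:
            if self.response is None:
                raise ValueError("either response= or an explicit y is required")
            if self.response not in data.columns:
                raise KeyError(f"response column {self.response!r} not in data")
            yvec = data[self.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(yvec)):
            raise ValueError("response contains non-finite values")
        n = yvec.size
        if self.variant not in ("pql", "hlik"):
            raise ValueError("variant must be 'pql' or 'hlik'")

        fd_m = build_fixed_design(data, self.mean_fixed)
        fd_d = build_fixed_design(data, self.disp_fixed)
        if n < fd_m.matrix.shape[1] + 1:
            raise ValueError("need at least p + 1 records")
        mblocks = self._random_blocks(data, self.mean_random)
        dblocks = self._random_blocks(data, self.disp_random)
        Zm, Zd = self._stack(mblocks), self._stack(dblocks)
        Xm, Xd = fd_m.matrix, fd_d.matrix

        var_y = float(np.var(yvec, ddof=1)) if n > 1 else 1.0
        var_y = max(var_y, self.variance_floor)
        phi = np.ones(n) if self.variant == "pql" else np.full(n, var_y)
        sigma_u2 = {b.term: 0.1 * var_y for b in mblocks}
        sigma_d2 = {b.term: 0.1 * var_y for b in dblocks}

        def expand(blocks, values):
            if not blocks:
                return 0.0
            return np.concatenate(
                [np.full(b.Z.shape[1], values[b.term]) for b in blocks])

        traj: list[dict] = []
        prev: np.ndarray | None = None
        converged = diverged = False
        sol = dfit = gfit = None
        h = h_d = None
        it = 0
        for it in range(1, self.max_iter + 1):
            # --- mean part: Henderson MME as augmented WLS -------------
            sol = solve_augmented(
                AugmentedSystem(X=Xm, Z=Zm, y=yvec, phi=phi,
                                sigma_u2=expand(mblocks, sigma_u2)))
            b, u = sol.split(Xm.shape[1])
            h = clip_leverages(sol.hat_diag)
            for blk in mblocks:
                est = estimate_variance_from_blups(
                    u[blk.sl], h[n:][blk.sl], floor=self.variance_floor)
                sigma_u2[blk.term] += self.relaxation * (
                    est.value - sigma_u2[blk.term])

            # --- dispersion part: gamma GLM(M) on adjusted e^2 ---------
            y_disp, w_disp = reml_adjusted_response(sol.residuals**2, h[:n])
            if dblocks:
                dfit = fit_dispersion_part(
                    y_disp, w_disp, Xd, Zd, expand(dblocks, sigma_d2),
                    inner_tol=self.inner_tol,
                    inner_max_iter=self.inner_max_iter,
                    start=(np.concatenate([dfit.coef, dfit.ranef])
                           if dfit is not None else None))
                h_d = clip_leverages(dfit.hat_diag)
                for blk in dblocks:
                    num = (dfit.pseudo_deviances[blk.sl]
                           if self.variant == "hlik"
                           else dfit.ranef[blk.sl] ** 2)
                    est = estimate_dispersion_variance(
                        num, h_d[n:][blk.sl], floor=self.variance_floor)
                    sigma_d2[blk.term] += self.relaxation * (
                        est.value - sigma_d2[blk.term])
                eta_d = dfit.eta
            else:
                gfit = fit_gamma_glm(y_disp, Xd, prior_weights=w_disp)
                eta_d = np.clip(Xd @ gfit.coef, -700, 700)
                h_d = clip_leverages(hat_diagonal_weighted(Xd, np.maximum(
                    w_disp, 1e-12 * max(w_disp.max(), 1.0))))
            phi = np.exp(np.clip(eta_d, -700, 700))
            phi = np.maximum(phi, self.variance_floor)

            comps = np.array(
                [*sigma_u2.values(), *sigma_d2.values(), float(np.mean(phi))])
            traj.append({"iteration": it,
                         **{f"sigma_u2[{t}]": v for t, v in sigma_u2.items()},
                         **{f"sigma_d2[{t}]": v for t, v in sigma_d2.items()},
                         "mean_phi": float(np.mean(phi))})
            if np.any(comps > DIVERGENCE_FACTOR * var_y):
                diverged = True
                logger.error("variance component diverged at iteration %d", it)
                break
            if prev is not None and np.max(np.abs(comps - prev)) < self.tol:
                converged = True
                break
            prev = comps

        # ------------------------------------------------------------------
        self.n_records_ = n
        self.coef_ = pd.Series(b, index=fd_m.names, name="estimate")
        self.sigma_u2_ = {t: float(v) for t, v in sigma_u2.items()}
        self.sigma_d2_ = {t: float(v) for t, v in sigma_d2.items()}
        self.ranef_ = {}
        self.ranef_iid_ = {}
        self.reliability_ = {}
        for blk in mblocks:
            u_blk = u[blk.sl]
            self.ranef_iid_[blk.term] = u_blk
            vals = blk.rf.L @ u_blk if blk.rf is not None else u_blk
            self.ranef_[blk.term] = pd.Series(vals, index=blk.levels)
            self.reliability_[blk.term] = pd.Series(
                1.0 - sol.hat_diag[n:][blk.sl], index=blk.levels)
        if dblocks:
            self.disp_coef_ = pd.Series(dfit.coef, index=fd_d.names,
                                        name="estimate")
            self.disp_ranef_ = {}
            self.disp_reliability_ = {}
            for blk in dblocks:
                u_blk = dfit.ranef[blk.sl]
                vals = blk.rf.L @ u_blk if blk.rf is not None else u_blk
                self.disp_ranef_[blk.term] = pd.Series(vals, index=blk.levels)
                self.disp_reliability_[blk.term] = pd.Series(
                    1.0 - dfit.hat_diag[n:][blk.sl], index=blk.levels)
            self.disp_leverages_ = dfit.hat_diag
        else:
            self.disp_coef_ = pd.Series(gfit.coef, index=fd_d.names,
                                        name="estimate")
            self.disp_ranef_ = {}
            self.disp_reliability_ = {}
            self.disp_leverages_ = h_d
        self.phi_ = phi
        self.leverages_ = sol.hat_diag
        self.residuals_ = sol.residuals
        self.fitted_ = yvec - sol.residuals
        self.trajectory_ = pd.DataFrame(traj)
        self.converged_ = bool(converged)
        self.diverged_ = bool(diverged)
        self.n_iter_ = it
        self._fd_m, self._fd_d = fd_m, fd_d
        self._mblocks, self._dblocks = mblocks, dblocks
        if not converged and not diverged:
            logger.warning("DHGLM did not converge in %d outer iterations",
                           self.max_iter)
        return self

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted mean X b + Z u for new records (unseen levels -> 0)."""
        self._check_fitted()
        data = X.reset_index(drop=True)
        out = rebuild_fixed_design(data, self._fd_m) @ self.coef_.to_numpy()
        for blk in self._mblocks:
            series = self.ranef_[blk.term]
            keys = data[blk.term].astype(str) if blk.rf is not None else data[blk.term]
            out += keys.map(series).fillna(0.0).to_numpy()
        return out

    def predict_variance(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted residual variance exp(X_d b_d + Z_d u_d) for new records."""
        self._check_fitted()
        data = X.reset_index(drop=True)
        eta = rebuild_fixed_design(data, self._fd_d) @ self.disp_coef_.to_numpy()
        for blk in self._dblocks:
            series = self.disp_ranef_[blk.term]
            keys = data[blk.term].astype(str) if blk.rf is not None else data[blk.term]
            eta += keys.map(series).fillna(0.0).to_numpy()
        return np.exp(eta)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("this DHGLM instance is not fitted yet")


@dataclass
class LeverageReport:
    """Per-record and per-level leverage diagnostics."""

    records: pd.DataFrame
    levels: pd.DataFrame


def leverage_report(model: DHGLM) -> LeverageReport:
    """Diagnostics: data leverages with no-information flags, reliabilities.

    A record with leverage above 0.99 (e.g. the sole member of its own
    fixed-effect class) adds essentially no information to the model and
    is flagged.
    """
    model._check_fitted()
    n = model.n_records_
    records = pd.DataFrame({
        "record": np.arange(n),
        "leverage": model.leverages_[:n],
        "phi": model.phi_,
        "no_information": model.leverages_[:n] > LEVERAGE_FLAG,
    })
    rows = []
    for part, rel, ran in (
        ("mean", model.reliability_, model.ranef_),
        ("dispersion", model.disp_reliability_, model.disp_ranef_),
    ):
        for term, series in rel.items():
            for level, r in series.items():
                rows.append({"part": part, "term": term, "level": level,
                             "blup": float(ran[term][level]),
                             "reliability": float(r)})
    levels = pd.DataFrame(
        rows, columns=["part", "term", "level", "blup", "reliability"])
    return LeverageReport(records=records, levels=levels)


def fit_dhglm(data: pd.DataFrame, response: str, **params) -> DHGLM:
    """Thin functional wrapper: build a :class:`DHGLM` and fit it."""
    return DHGLM(response=response, **params).fit(data)
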