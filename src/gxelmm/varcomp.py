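"""Restricted maximum likelihood estimation of variance components.

Fits the variance structure of

    y ~ N(X0 b,  sum_k sigma_k^2 V_k  +  sigma_e^2 I)

for one relatedness matrix (V = K; the classic polygenic model) or two
(V_1 = K, V_2 = K^D; the two-random-effect GxE model) by
average-information (AI) REML with a single expectation-maximization
warm-up step, the scheme popularized by GCTA. Fixed effects X0 under the
null contain an intercept, the environmental exposure and any user
covariates — the tested variant is absent, so components are estimated
once per phenotype and reused for every variant (the EMMAX strategy).

With a single relatedness matrix the problem is rotated by the
eigenvectors of K once, which makes every iteration O(n p^2); the
two-matrix case uses dense Cholesky factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .types import ExposureVector, KinshipMatrix, PhenotypeVector, aligned

__all__ = [
    "VarianceComponents",
    "fit_reml",
    "variance_fractions",
    "restricted_loglik",
]


@dataclass
class VarianceComponents:
    """REML variance-component estimates with curvature-based uncertainty.

    ``cov`` is the inverse average-information matrix at the optimum;
    ``boundary`` flags components clamped at the non-negativity floor.
    """

    names: list[str]
    sigma2: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    boundary: np.ndarray
    n: int
    n_fixed: int

    @property
    def total(self) -> float:
        return float(self.sigma2.sum())

    @property
    def fractions(self) -> np.ndarray:
        """Each component's share of total phenotypic variance."""
        return self.sigma2 / self.total

    def fraction_cov(self) -> np.ndarray:
        """Delta-method covariance of the variance fractions."""
        s, S = self.sigma2, self.total
        J = (np.eye(len(s)) * S - np.outer(s, np.ones(len(s)))) / S**2
        return J @ self.cov @ J.T

    def component(self, name: str) -> float:
        return float(self.sigma2[self.names.index(name)])


def _design(
    y: PhenotypeVector,
    exposure: ExposureVector | None,
    covariates: np.ndarray | None,
    include_exposure: bool,
):
    cols = [np.ones(len(y.samples))]
    if exposure is not None and include_exposure:
        cols.append(exposure.values)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(y.samples):
            covariates = covariates.T
        cols.extend(covariates.T)
    return np.column_stack(cols)


def fit_reml(
    y: PhenotypeVector,
    kinships: list[KinshipMatrix] | KinshipMatrix,
    exposure: ExposureVector | None = None,
    covariates: np.ndarray | None = None,
    include_exposure: bool = True,
    tol: float = 1e-6,
    gtol: float = 1e-4,
    max_iter: int = 50,
) -> VarianceComponents:
    """AI-REML fit of (sigma_k^2 for each kinship, sigma_e^2).

    ``covariates`` (if given) must be aligned to the common sample order
    of ``y``, ``kinships`` and ``exposure`` (the order of ``y`` restricted
    to shared IDs). Samples with missing phenotype are dropped.
    Non-convergence within ``max_iter`` is flagged on the result, not
    raised; a covariance that cannot be kept positive definite raises.
    """
    if isinstance(kinships, KinshipMatrix):
        kinships = [kinships]
    objs = [y, *kinships] + ([exposure] if exposure is not None else [])
    al = aligned(*objs)
    y = al[0]
    kin = list(al[1 : 1 + len(kinships)])
    exposure = al[-1] if exposure is not None else None

    keep = np.isfinite(y.values)
    if not keep.all():
        ids = [s for s, k in zip(y.samples, keep) if k]
        y = y.reindex(ids)
        kin = [K.reindex(ids) for K in kin]
        exposure = exposure.reindex(ids) if exposure is not None else None
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, float))
            if covariates.shape[0] == len(keep):
                covariates = covariates[keep]
            else:
                covariates = covariates[:, keep].T

    X = _design(y, exposure, covariates, include_exposure)
    n, p = X.shape
    q = len(kin) + 1
    if n <= p + q:
        raise ValueError(f"need n > {p + q} samples, have {n}")

    names = []
    for K in kin:
        names.append({"genetic": "genetic", "gxe": "gxe"}[K.role])
    names.append("residual")

    if len(kin) == 1:
        res = _ai_reml_diag(y.values, X, kin[0].values, tol, gtol, max_iter)
    else:
        res = _ai_reml_dense(
            y.values, X, [K.values for K in kin], tol, gtol, max_iter
        )
    return VarianceComponents(names=names, n=n, n_fixed=p, **res)


# ---------------------------------------------------------------------------
# dense path (any number of relatedness matrices)
# ---------------------------------------------------------------------------

def _dense_ll(theta, y, X, Vs):
    """Restricted log-likelihood only (cheap; used for step control)."""
    Sigma = _sigma_of(theta, Vs)
    c = cho_factor(Sigma, lower=True, check_finite=False)
    ld_sigma = 2.0 * np.log(np.diag(c[0])).sum()
    SiX = cho_solve(c, X, check_finite=False)
    Siy = cho_solve(c, y, check_finite=False)
    XtSiX = X.T @ SiX
    sign, ld_xx = np.linalg.slogdet(XtSiX)
    if sign <= 0:
        raise LinAlgError("X' Sigma^-1 X not positive definite")
    Py = Siy - SiX @ np.linalg.solve(XtSiX, X.T @ Siy)
    return -0.5 * (ld_sigma + ld_xx + y @ Py)


def _sigma_of(theta, Vs):
    Sigma = theta[-1] * np.eye(Vs[0].shape[0])
    for t, V in zip(theta[:-1], Vs):
        Sigma += t * V
    return Sigma


def _dense_state(theta, y, X, Vs):
    n = len(y)
    Sigma = _sigma_of(theta, Vs)
    c = cho_factor(Sigma, lower=True, check_finite=False)
    ld_sigma = 2.0 * np.log(np.diag(c[0])).sum()
    Si = cho_solve(c, np.eye(n), check_finite=False)
    XtSi = X.T @ Si
    XtSiX = XtSi @ X
    sign, ld_xx = np.linalg.slogdet(XtSiX)
    if sign <= 0:
        raise LinAlgError("X' Sigma^-1 X not positive definite")
    P = Si - XtSi.T @ np.linalg.solve(XtSiX, XtSi)
    Py = P @ y
    ll = -0.5 * (ld_sigma + ld_xx + y @ Py)
    VPy = [V @ Py for V in Vs] + [Py]
    traces = [np.sum(P * V) for V in Vs] + [np.trace(P)]
    quads = [Py @ v for v in VPy]
    grad = np.array([-0.5 * (t - qd) for t, qd in zip(traces, quads)])
    PVPy = [P @ v for v in VPy]
    q = len(VPy)
    AI = np.empty((q, q))
    for k in range(q):
        for l in range(k, q):
            AI[k, l] = AI[l, k] = 0.5 * (VPy[k] @ PVPy[l])
    return ll, grad, AI, np.array(quads), np.array(traces)


def _ai_reml_dense(y, X, Vs, tol, gtol, max_iter):
    return _ai_reml_run(
        len(Vs) + 1,
        y,
        lambda th: _dense_state(th, y, X, Vs),
        lambda th: _dense_ll(th, y, X, Vs),
        tol, gtol, max_iter,
    )


# ---------------------------------------------------------------------------
# diagonal path (single relatedness matrix, eigen-rotated)
# ---------------------------------------------------------------------------

def _diag_state_builder(y, X, K):
    lam, U = np.linalg.eigh(K)
    yt = U.T @ y
    Xt = U.T @ X
    vs = [lam, np.ones_like(lam)]

    def core(theta):
        w = theta[0] * lam + theta[1]
        if w.min() <= 0:
            raise LinAlgError("covariance not positive definite")
        Si = 1.0 / w
        SiX = Xt * Si[:, None]
        XtSiX = Xt.T @ SiX
        sign, ld_xx = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            raise LinAlgError("X' Sigma^-1 X not positive definite")
        XtSiX_inv = np.linalg.inv(XtSiX)
        Siy = Si * yt
        Py = Siy - SiX @ (XtSiX_inv @ (Xt.T @ Siy))
        ll = -0.5 * (np.log(w).sum() + ld_xx + yt @ Py)
        return w, Si, SiX, XtSiX_inv, Py, ll

    def ll_only(theta):
        return core(theta)[-1]

    def state(theta):
        w, Si, SiX, XtSiX_inv, Py, ll = core(theta)

        def P_dot(v):
            Siv = Si * v
            return Siv - SiX @ (XtSiX_inv @ (Xt.T @ Siv))

        traces = []
        for vk in vs:
            A = Xt.T @ (SiX * (Si * vk)[:, None])
            traces.append((Si * vk).sum() - np.trace(XtSiX_inv @ A))
        VPy = [vk * Py for vk in vs]
        quads = [Py @ v for v in VPy]
        grad = np.array([-0.5 * (t - qd) for t, qd in zip(traces, quads)])
        PVPy = [P_dot(v) for v in VPy]
        AI = np.empty((2, 2))
        for k in range(2):
            for l in range(k, 2):
                AI[k, l] = AI[l, k] = 0.5 * (VPy[k] @ PVPy[l])
        return ll, grad, AI, np.array(quads), np.array(traces)

    return state, ll_only


def _ai_reml_diag(y, X, K, tol, gtol, max_iter):
    state, ll_only = _diag_state_builder(y, X, K)
    return _ai_reml_run(2, y, state, ll_only, tol, gtol, max_iter)


# ---------------------------------------------------------------------------
# shared optimizer loop
# ---------------------------------------------------------------------------

def _ai_reml_run(q, y, state_fn, ll_fn, tol, gtol, max_iter):
    n = len(y)
    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    floor = 1e-6 * vary
    theta = np.full(q, vary / q)
    ll, grad, AI, quads, traces = state_fn(theta)
    converged = False
    n_iter = 0
    def try_direction(delta):
        """Backtracking line search; returns (theta, ll) or None."""
        step = 1.0
        for _ in range(12):
            prop = np.maximum(theta + step * delta, floor)
            try:
                new_ll = ll_fn(prop)
            except (LinAlgError, np.linalg.LinAlgError):
                new_ll = -np.inf
            if np.isfinite(new_ll) and new_ll >= ll - 1e-10:
                return prop, new_ll
            step *= 0.5
        return None

    for it in range(1, max_iter + 1):
        n_iter = it
        em_delta = theta**2 * (quads - traces) / n
        if it == 1:
            # one EM warm-up step: robust far from the optimum
            accepted = try_direction(em_delta)
        else:
            # active-set quasi-Newton step: components pinned at the
            # non-negativity floor with an inward-pointing gradient are
            # held fixed and the AI system is solved on the rest
            pinned = (theta <= floor * (1 + 1e-9)) & (grad < 0)
            free = ~pinned
            ai_delta = np.zeros(q)
            try:
                ai_delta[free] = np.linalg.solve(
                    AI[np.ix_(free, free)], grad[free]
                )
            except np.linalg.LinAlgError:
                ai_delta[free] = grad[free] / np.maximum(
                    np.diag(AI)[free], 1e-12
                )
            accepted = try_direction(ai_delta)
            if accepted is None:
                # EM ascends the restricted likelihood monotonically;
                # use it when the quasi-Newton step cannot improve
                accepted = try_direction(em_delta)
        if accepted is None:
            converged = True  # no ascent direction improves: stationary
            break
        theta, _ = accepted
        prev_ll = ll
        ll, grad, AI, quads, traces = state_fn(theta)
        # pinned components keep a non-zero inward gradient; exclude them
        # from the first-order convergence test
        pinned = (theta <= floor * (1 + 1e-9)) & (grad < 0)
        free_grad = np.abs(grad[~pinned]).max() if (~pinned).any() else 0.0
        if abs(ll - prev_ll) < tol and free_grad < gtol:
            converged = True
            break
    boundary = theta <= floor * (1 + 1e-9)
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((q, q), np.nan)
        se = np.full(q, np.nan)
    return dict(
        sigma2=theta,
        se=se,
        cov=cov,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
    )


def variance_fractions(vc: VarianceComponents) -> pd.DataFrame:
    """Per-component variance fractions with delta-method standard errors."""
    if vc.total <= 0:
        raise ValueError("total variance is zero; fractions undefined")
    fc = vc.fraction_cov()
    return pd.DataFrame(
        {
            "component": vc.names,
            "sigma2": vc.sigma2,
            "se": vc.se,
            "fraction": vc.fractions,
            "fraction_se": np.sqrt(np.maximum(np.diag(fc), 0.0)),
        }
    )


def restricted_loglik(
    y: np.ndarray, X: np.ndarray, kinships: list[np.ndarray], sigma2: np.ndarray
) -> float:
    """Restricted log-likelihood of y ~ N(Xb, sum_k s2_k V_k + s2_e I).

    ``sigma2`` lists the kinship components in order with the residual
    variance last. Exposed so external code (and the test suite's grid
    oracles) can evaluate the same objective the optimizer maximizes.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    return float(_dense_ll(np.asarray(sigma2, float), y, X, [np.asarray(K, float) for K in kinships]))
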