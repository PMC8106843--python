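"""Random-intercept logistic regression by adaptive Gauss–Hermite quadrature.

The model is a two-level hierarchical logit: binary outcomes ``y_ij`` for
individuals ``j`` nested in regions ``g`` with

    logit P(y_ij = 1 | b_g) = x_ij' beta + b_g,      b_g ~ N(0, sigma^2).

The marginal log-likelihood integrates the region intercepts out with
adaptive Gauss–Hermite quadrature: nodes are centred and scaled at each
region's conditional posterior mode and curvature, the fixed-node objective
is maximised by a damped Newton iteration with analytic gradients and an
analytic fixed-effect Hessian (the log-sigma row is finite-differenced),
and the adaptation is refreshed until the log-likelihood stabilises.

Standard errors: the model-based covariance is the inverse observed
information of the marginal likelihood; the robust covariance is a cluster
sandwich, conditional on the fitted random-intercept variance, with
per-cluster scores obtained from the exact decomposition of the marginal
score ``dll_g/dbeta = E[sum_j x_ij (y_ij - p_ij(b)) | data]`` — the
posterior-expected conditional scores, which sum over clusters within a
region to the region's marginal score.  With sigma ~ 0 and singleton
clusters this reduces to the familiar HC0 heteroskedasticity-robust
estimator for a plain logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit, log_expit

__all__ = ["MixedLogitFit", "fit_random_intercept_logit", "SeparationError"]

_LOG_SIGMA_MIN = np.log(1e-8)
_LOG_SIGMA_MAX = np.log(10.0)


class SeparationError(RuntimeError):
    """Raised when a covariate perfectly separates the outcome."""


@dataclass
class MixedLogitFit:
    """Fitted random-intercept logit."""

    params: np.ndarray  # fixed effects
    sigma: float  # random-intercept SD
    cov_robust: np.ndarray  # cluster sandwich, fixed effects
    cov_model: np.ndarray  # inverse observed information, fixed effects
    param_names: list[str]
    llf: float
    converged: bool
    n_obs: int
    n_groups: int
    n_clusters: int
    eb_modes: np.ndarray = field(repr=False)  # empirical-Bayes region intercepts

    @property
    def bse_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    @property
    def bse_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))


def _group_starts(codes: np.ndarray) -> np.ndarray:
    """reduceat start indices for sorted group codes."""
    return np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])


def _posterior_modes(
    y: np.ndarray,
    eta: np.ndarray,
    g_idx: np.ndarray,
    starts: np.ndarray,
    sigma: float,
    b0: np.ndarray,
    n_iter: int = 30,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group conditional posterior mode and curvature (scalar Newton)."""
    b = b0.copy()
    for _ in range(n_iter):
        p = expit(eta + b[g_idx])
        score = np.add.reduceat(y - p, starts) - b / sigma**2
        curv = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / sigma**2
        step = score / curv
        b += step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(eta + b[g_idx])
    curv = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / sigma**2
    return b, curv


def fit_random_intercept_logit(
    y,
    X,
    groups,
    clusters=None,
    *,
    param_names: list[str] | None = None,
    n_quad: int = 9,
    start: np.ndarray | None = None,
    start_logsigma: float = np.log(0.25),
    tol: float = 1e-8,
    max_outer: int = 30,
) -> MixedLogitFit:
    """Maximum-likelihood fit of the two-level random-intercept logit.

    Parameters
    ----------
    y, X : array-like
        Binary outcome (n,) and fixed-effect design matrix (n, p) with
        intercept column included by the caller.
    groups : array-like
        Region identifiers defining the random intercepts.
    clusters : array-like, optional
        Identifiers (e.g. mother ids) for the robust sandwich.  Defaults to
        one cluster per observation (heteroskedasticity-robust).
    n_quad : int
        Number of adaptive Gauss–Hermite nodes (>= 7 recommended).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    g_codes, g_uniques = _factorize(groups)
    if len(g_uniques) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    cl_codes = np.arange(n) if clusters is None else _factorize(clusters)[0]
    if param_names is None:
        param_names = [f"x{i}" for i in range(p)]

    # sort by group so per-group sums are contiguous reduceat slices
    order = np.argsort(g_codes, kind="stable")
    ys, Xs, gs, cls = y[order], X[order], g_codes[order], cl_codes[order]
    starts = _group_starts(gs)
    n_groups = len(starts)

    z, wq = hermegauss(n_quad)  # probabilists' nodes: int f(z) e^{-z^2/2} dz
    log_wq = np.log(wq)
    sign = 2.0 * ys - 1.0

    if start is None:
        beta = _plain_logit_start(ys, Xs, param_names)
    else:
        beta = np.asarray(start, dtype=float).copy()
    theta = np.r_[beta, float(np.clip(start_logsigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))]

    def build_nodes(theta):
        beta, logsig = theta[:-1], theta[-1]
        sigma = float(np.exp(logsig))
        eta = Xs @ beta
        modes, curv = _posterior_modes(ys, eta, gs, starts, sigma, np.zeros(n_groups))
        s = 1.0 / np.sqrt(curv)  # (G,)
        b_nodes = modes[:, None] + s[:, None] * z[None, :]  # (G, K)
        # substitution b = m + s z gives int g(b) db ~= sum_k s w_k e^{z_k^2/2} g(b_gk);
        # the N(0, sigma^2) prior stays inside the objective so sigma remains free
        log_c = np.log(s)[:, None] + log_wq[None, :] + 0.5 * z[None, :] ** 2
        return b_nodes, log_c, modes

    state: dict = {}

    def negll_grad(theta, b_nodes, log_c, keep_state=False):
        beta, logsig = theta[:-1], theta[-1]
        sigma = float(np.exp(logsig))
        eta = Xs @ beta
        lp = eta[:, None] + b_nodes[gs]  # (n, K)
        ll_obs = log_expit(sign[:, None] * lp)
        S = np.add.reduceat(ll_obs, starts, axis=0)  # (G, K)
        log_phi = -0.5 * np.log(2.0 * np.pi) - logsig - 0.5 * (b_nodes / sigma) ** 2
        A = S + log_c + log_phi
        Amax = A.max(axis=1, keepdims=True)
        expA = np.exp(A - Amax)
        denom = expA.sum(axis=1)
        ll = float((Amax[:, 0] + np.log(denom)).sum())
        W = expA / denom[:, None]  # posterior node weights (G, K)
        pbar = (expit(lp) * W[gs]).sum(axis=1)
        grad_beta = Xs.T @ (ys - pbar)
        grad_logsig = float((W * ((b_nodes / sigma) ** 2 - 1.0)).sum())
        if keep_state:
            state["W"], state["pbar"], state["lp"] = W, pbar, lp
        return -ll, -np.r_[grad_beta, grad_logsig]

    def hess_bb(theta, b_nodes, log_c):
        """Analytic observed information of the fixed-effect block."""
        f, g = negll_grad(theta, b_nodes, log_c, keep_state=True)
        W, lp = state["W"], state["lp"]
        pk = expit(lp)  # (n, K)
        v = (W[gs] * pk * (1.0 - pk)).sum(axis=1)
        H_cond = Xs.T @ (Xs * v[:, None])
        rk = ys[:, None] - pk
        Ggk = np.stack(
            [np.add.reduceat(Xs * rk[:, k][:, None], starts, axis=0) for k in range(len(z))],
            axis=1,
        )  # (G, K, p)
        Gbar = (W[:, :, None] * Ggk).sum(axis=1)  # (G, p)
        second = np.einsum("gk,gki,gkj->ij", W, Ggk, Ggk)
        return f, g, H_cond - second + Gbar.T @ Gbar

    def full_hessian(theta, b_nodes, log_c):
        """negll Hessian: analytic beta block, finite-diff log-sigma row."""
        f, g, H_bb = hess_bb(theta, b_nodes, log_c)
        h = 1e-5
        tp, tm = theta.copy(), theta.copy()
        tp[-1] += h
        tm[-1] -= h
        _, gp = negll_grad(tp, b_nodes, log_c)
        _, gm = negll_grad(tm, b_nodes, log_c)
        row = (gp - gm) / (2.0 * h)
        H = np.empty((p + 1, p + 1))
        H[:p, :p] = H_bb
        H[p, :] = row
        H[:, p] = row
        return f, g, H

    def inner_newton(theta, b_nodes, log_c, max_it=40):
        # saddle-free modified Newton: the frozen-node objective can be
        # locally concave in log-sigma away from the adaptation point, so
        # negative curvature directions are flipped before solving
        f, g, H = full_hessian(theta, b_nodes, log_c)
        ok = False
        for _ in range(max_it):
            at_lo = theta[-1] <= _LOG_SIGMA_MIN + 1e-12 and g[-1] > 0
            dim = p if at_lo else p + 1
            if np.max(np.abs(g[:dim])) < 1e-7 * max(1.0, n / 100):
                ok = True
                break
            Hs = 0.5 * (H[:dim, :dim] + H[:dim, :dim].T)
            lam, Q = np.linalg.eigh(Hs)
            lam = np.maximum(np.abs(lam), 1e-8 * max(1.0, np.abs(lam).max()))
            step = np.zeros(p + 1)
            step[:dim] = -Q @ ((Q.T @ g[:dim]) / lam)
            slope = float(g[:dim] @ step[:dim])  # < 0 by construction
            t = 1.0
            for _bt in range(40):
                cand = theta + t * step
                cand[-1] = np.clip(cand[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
                fc, _ = negll_grad(cand, b_nodes, log_c)
                if fc <= f + 1e-4 * t * slope or fc <= f - 1e-12 * abs(f):
                    theta = cand
                    break
                t *= 0.5
            else:  # no acceptable step found: at numerical precision
                ok = True
                break
            f, g, H = full_hessian(theta, b_nodes, log_c)
            if np.max(np.abs(theta[:p])) > 25.0:
                break
        return theta, f, ok

    prev_f = np.inf
    prev_theta = theta.copy() + np.inf
    converged = False
    for outer in range(max_outer):
        b_nodes, log_c, modes = build_nodes(theta)
        theta, f, inner_ok = inner_newton(theta, b_nodes, log_c)
        # stop when the objective or the parameters stabilise across
        # re-adaptations (node positions can keep the objective wiggling at
        # the last decimals even when theta has stopped moving)
        if abs(prev_f - f) < tol * (1.0 + abs(f)) or (
            np.max(np.abs(theta - prev_theta)) < 1e-6
        ):
            converged = inner_ok
            break
        prev_f = f
        prev_theta = theta.copy()

    beta, logsig = theta[:-1], float(theta[-1])
    sigma = float(np.exp(logsig))
    if np.any(np.abs(beta) > 20.0):
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"covariate {param_names[j]!r} appears to separate the outcome "
            f"(|coef| = {abs(beta[j]):.1f})"
        )

    # final adaptation for curvature/score quantities
    b_nodes, log_c, modes = build_nodes(theta)
    negll, _, H_bb = hess_bb(theta, b_nodes, log_c)
    pbar = state["pbar"]

    cov_model = _psd_inverse(H_bb)

    # cluster sandwich on the supplied clusters
    r = ys - pbar  # exact per-observation marginal score weights
    n_cl = int(cls.max()) + 1
    Sc = np.zeros((n_cl, p))
    np.add.at(Sc, cls, Xs * r[:, None])
    meat = Sc.T @ Sc
    cov_robust = cov_model @ meat @ cov_model

    return MixedLogitFit(
        params=beta.copy(),
        sigma=sigma,
        cov_robust=cov_robust,
        cov_model=cov_model,
        param_names=list(param_names),
        llf=-float(negll),
        converged=bool(converged),
        n_obs=n,
        n_groups=n_groups,
        n_clusters=n_cl,
        eb_modes=modes,
    )


def _factorize(values) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(values)
    uniques, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.intp), uniques


def _plain_logit_start(y: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    """Newton start from an (unpenalised, lightly ridged) plain logit."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(30):
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None]) + 1e-8 * np.eye(p)
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
        if np.any(np.abs(beta) > 30.0):
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"covariate {names[j]!r} appears to separate the outcome"
            )
    return beta


def _psd_inverse(H: np.ndarray) -> np.ndarray:
    """Inverse of a (near-)symmetric PD information matrix."""
    Hs = 0.5 * (H + H.T)
    try:
        L = np.linalg.cholesky(Hs)
        inv = np.linalg.inv(L)
        return inv.T @ inv
    except np.linalg.LinAlgError:
        return np.linalg.pinv(Hs)
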