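"""Profiled (RE)ML solver for linear mixed models with two correlated
random slopes and no intercepts.

Model, for person g with n_g rows:

    y_g = X_g beta + Z_g b_g + eps_g,
    b_g ~ N(0, sigma^2 * Lambda Lambda'),   eps_g ~ N(0, sigma^2 I),

with Z_g of width 2.  beta and sigma^2 are profiled out analytically;
the optimiser only searches the 3 (2 if diagonal) entries of the relative
covariance factor Lambda (lower triangular, non-negative diagonal).  All
group contributions reduce to 2x2 sufficient statistics via the Woodbury
identity, so one objective evaluation costs O(groups) small-matrix work
regardless of the number of rows — the structure that makes thousands of
fits in the simulation study affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["LMMResult", "fit_lmm_two_slopes"]


@dataclass
class LMMResult:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma: float  # residual SD
    re_cov: np.ndarray  # 2x2 random-slope covariance (response units^2)
    re_sd: np.ndarray  # SDs of the two random slopes
    re_corr: float
    blups: np.ndarray  # n_groups x 2 predicted random effects
    group_labels: np.ndarray
    converged: bool
    reml: bool
    diagonal: bool
    criterion: float  # -2 * restricted/profile log-likelihood (up to const)
    n_rows: int
    n_groups: int


def _suffstats(y, X, Z, codes, n_groups):
    k = X.shape[1]
    A = np.zeros((n_groups, 2, 2))
    B = np.zeros((n_groups, 2, k))
    c = np.zeros((n_groups, 2))
    for j in range(2):
        zj = Z[:, j]
        for l in range(j, 2):
            A[:, j, l] = np.bincount(codes, zj * Z[:, l], minlength=n_groups)
            A[:, l, j] = A[:, j, l]
        for l in range(k):
            B[:, j, l] = np.bincount(codes, zj * X[:, l], minlength=n_groups)
        c[:, j] = np.bincount(codes, zj * y, minlength=n_groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    return A, B, c, XtX, Xty, yty


def _theta_to_lambda(theta, diagonal):
    lam = np.zeros((2, 2))
    if diagonal:
        lam[0, 0], lam[1, 1] = theta
    else:
        lam[0, 0], lam[1, 0], lam[1, 1] = theta
    return lam


def _profile(theta, diagonal, A, B, c, XtX, Xty, yty, n, k, reml):
    """Profiled -2 log-likelihood plus the profiled beta/sigma^2."""
    lam = _theta_to_lambda(theta, diagonal)
    # M_g = I + Lam' A_g Lam  (2x2 per group, vectorised)
    AL = A @ lam  # (G,2,2)
    M = np.einsum("ij,gjl->gil", lam.T, AL)
    M[:, 0, 0] += 1.0
    M[:, 1, 1] += 1.0
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(det <= 0):
        return np.inf, None, None, None, None
    logdet = float(np.log(det).sum())
    Minv = np.empty_like(M)
    Minv[:, 0, 0] = M[:, 1, 1]
    Minv[:, 1, 1] = M[:, 0, 0]
    Minv[:, 0, 1] = -M[:, 0, 1]
    Minv[:, 1, 0] = -M[:, 1, 0]
    Minv /= det[:, None, None]
    # P_g = Lam Minv_g Lam'  so that V_g^-1 = I - Z_g P_g Z_g'
    P = np.einsum("ij,gjl,ml->gim", lam, Minv, lam)
    XtVX = XtX - np.einsum("gji,gjl,glm->im", B, P, B)
    XtVy = Xty - np.einsum("gji,gjl,gl->i", B, P, c)
    ytVy = yty - np.einsum("gj,gjl,gl->", c, P, c)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None, None
    rss = ytVy - XtVy @ beta
    if rss <= 0:
        rss = 1e-300
    dof = n - k if reml else n
    sigma2 = rss / dof
    crit = logdet + dof * np.log(sigma2)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, None, None, None, None
        crit += ld
    return crit, beta, sigma2, XtVX, P


def fit_lmm_two_slopes(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    *,
    reml: bool = True,
    diagonal: bool = False,
) -> LMMResult:
    """Fit the two-random-slope mixed model by profiled (RE)ML.

    Parameters
    ----------
    y, X, Z : arrays
        Response (n,), fixed-effect design (n, k), random-effect design
        (n, 2).  No intercept columns are added.
    groups : array
        Group (person) label per row.
    reml : bool
        Restricted maximum likelihood (default) or plain ML.
    diagonal : bool
        Constrain the random-slope covariance to be diagonal.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n, k = X.shape
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    A, B, c, XtX, Xty, yty = _suffstats(y, X, Z, codes, G)

    args = (diagonal, A, B, c, XtX, Xty, yty, n, k, reml)

    def objective(theta):
        return _profile(theta, *args)[0]

    n_par = 2 if diagonal else 3
    bounds = [(0.0, None)] * 2 if diagonal else [(0.0, None), (None, None), (0.0, None)]
    # multiple deterministic starts guard against the flat region near the
    # boundary (tiny random-effect variances are common here)
    starts = []
    for scale in (1.0, 0.1, 0.01):
        t = np.full(n_par, scale)
        if not diagonal:
            t[1] = 0.0
        starts.append(t)
    starts.append(np.zeros(n_par))
    best = None
    for t0 in starts:
        res = minimize(
            objective,
            t0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    crit, beta, sigma2, XtVX, P = _profile(best.x, *args)
    if beta is None:
        raise RuntimeError("mixed-model profile likelihood degenerate")
    lam = _theta_to_lambda(best.x, diagonal)
    psi_rel = lam @ lam.T
    re_cov = sigma2 * psi_rel
    re_sd = np.sqrt(np.diag(re_cov))
    denom = re_sd[0] * re_sd[1]
    re_corr = float(re_cov[0, 1] / denom) if denom > 0 else 0.0
    beta_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtVX)))
    # BLUPs: b_g = Lam M_g^-1 Lam' (c_g - B_g beta) = P_g (c_g - B_g beta)
    resid2 = c - B @ beta
    blups = np.einsum("gij,gj->gi", P, resid2)
    return LMMResult(
        beta=beta,
        beta_se=beta_se,
        sigma=float(np.sqrt(sigma2)),
        re_cov=re_cov,
        re_sd=re_sd,
        re_corr=re_corr,
        blups=blups,
        group_labels=labels,
        converged=bool(best.success),
        reml=reml,
        diagonal=diagonal,
        criterion=float(crit),
        n_rows=n,
        n_groups=G,
    )
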