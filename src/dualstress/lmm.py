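"""Random-intercept linear mixed models fitted by REML.

The model is ``y = X beta + Z u + eps`` with a single random intercept per
group, ``u ~ N(0, tau2 I)`` and ``eps ~ N(0, sigma2 I)``.  The variance
ratio ``lam = tau2 / sigma2`` is profiled out of the REML criterion with a
one-dimensional search; conditional on ``lam`` everything is closed form.

Two code paths are provided:

* :func:`fit_random_intercept` — general (unbalanced) numeric REML for a
  single response vector.
* :func:`fit_balanced_many` — an exact ANOVA shortcut, vectorised across
  many response vectors that share one design, valid when every group has
  the same size and identical per-group column sums of ``X`` (e.g. a
  cell-means design in which each group contains each cell exactly once).
  In that case GLS coincides with OLS and the ANOVA variance-component
  estimators are the REML estimators (subject to non-negativity).

When the estimated random-intercept variance hits the zero boundary the
fit degrades to ordinary least squares and is flagged ``used_ols``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError

__all__ = [
    "RandomInterceptFit",
    "BalancedManyFit",
    "fit_random_intercept",
    "fit_balanced_many",
    "is_cell_balanced",
    "contrast_f",
    "coef_t",
]

_LAM_FLOOR = 1e-7


@dataclass
class RandomInterceptFit:
    """Result of a single random-intercept REML fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    lam: float
    ddf: int
    n_obs: int
    n_groups: int
    used_ols: bool


@dataclass
class BalancedManyFit:
    """Vectorised fits for ``k`` responses sharing one balanced design.

    ``beta`` is ``(k, p)``; the per-response covariance of ``beta`` is
    ``sigma2[i] * (xtx_inv + gamma[i] * outer(w, w))`` where ``w`` is
    ``xtx_inv @ s`` and ``s`` the (shared) per-group column sums of X.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    lam: np.ndarray
    ddf: np.ndarray
    used_ols: np.ndarray
    n_obs: int
    n_groups: int
    xtx_inv: np.ndarray
    w: np.ndarray
    gamma: np.ndarray


_PENALTY = 1e300  # finite "bad fit" value keeps minimize_scalar well-behaved


def _neg2_reml(lam, m, XtX, Xty, yty, S, gy, n, p):
    c = lam / (1.0 + lam * m)
    A = XtX - (S * c) @ S.T
    b = Xty - S @ (c * gy)
    try:
        beta = np.linalg.solve(A, b)
        sign, logdetA = np.linalg.slogdet(A)
    except np.linalg.LinAlgError:
        return _PENALTY, None, None, None
    if sign <= 0:
        return _PENALTY, None, None, None
    ywy = yty - float(np.sum(c * gy * gy))
    rwr = max(ywy - float(beta @ b), 0.0)
    df = n - p
    sigma2 = rwr / df if df > 0 else np.nan
    if not np.isfinite(sigma2) or sigma2 <= 0:
        return _PENALTY, beta, sigma2, A
    val = df * np.log(sigma2) + float(np.sum(np.log1p(lam * m))) + logdetA
    return val, beta, sigma2, A


def fit_random_intercept(y, X, groups) -> RandomInterceptFit:
    """REML fit of a random-intercept model for one response vector.

    Parameters
    ----------
    y : array-like, shape (n,)
    X : array-like, shape (n, p), full column rank
    groups : array-like, shape (n,)
        Grouping labels for the random intercept.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("y and X have incompatible shapes")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValidationError("non-finite values in y or X")
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need more observations ({n}) than parameters ({p})")
    codes = np.unique(np.asarray(groups), return_inverse=True)[1]
    g = int(codes.max()) + 1
    m = np.bincount(codes).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group column sums of X and group sums of y
    S = np.zeros((p, g))
    np.add.at(S.T, codes, X)
    gy = np.bincount(codes, weights=y, minlength=g)

    def ols() -> RandomInterceptFit:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * np.linalg.inv(XtX)
        return RandomInterceptFit(beta, cov, sigma2, 0.0, 0.0, n - p, n, g, True)

    # unidentifiable random effect: every group a singleton, or one group
    if g <= 1 or g >= n:
        return ols()

    crit0 = _neg2_reml(0.0, m, XtX, Xty, yty, S, gy, n, p)[0]
    res = optimize.minimize_scalar(
        lambda t: _neg2_reml(np.exp(t), m, XtX, Xty, yty, S, gy, n, p)[0],
        bounds=(-12.0, 8.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(np.exp(res.x))
    if not np.isfinite(res.fun) or res.fun >= crit0 or lam_hat < _LAM_FLOOR:
        return ols()

    _, beta, sigma2, A = _neg2_reml(lam_hat, m, XtX, Xty, yty, S, gy, n, p)
    cov = sigma2 * np.linalg.inv(A)
    ddf = max(n - p - (g - 1), 1)
    return RandomInterceptFit(
        beta, cov, sigma2, lam_hat * sigma2, lam_hat, ddf, n, g, False
    )


def is_cell_balanced(X: np.ndarray, codes: np.ndarray) -> bool:
    """True when the balanced ANOVA shortcut of :func:`fit_balanced_many` applies.

    Requires equal group sizes and identical per-group column sums of X
    (each group sees the same slice of the design).
    """
    g = int(codes.max()) + 1
    m = np.bincount(codes)
    if g < 2 or m.min() < 2 or (m != m[0]).any():
        return False
    S = np.zeros((g, X.shape[1]))
    np.add.at(S, codes, X)
    return bool(np.allclose(S, S[0], atol=1e-10))


def fit_balanced_many(Y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> BalancedManyFit:
    """Exact REML (ANOVA form) for many responses on one balanced design.

    Parameters
    ----------
    Y : (k, n) response matrix, one row per response (e.g. probe).
    X : (n, p) shared design; caller must have verified
        :func:`is_cell_balanced`.
    codes : (n,) integer group codes for the random intercept.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    g = int(codes.max()) + 1
    m = n // g
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    B = Y @ X @ XtXi.T                      # (k, p) OLS == GLS here
    R = Y - B @ X.T                         # residuals
    G = np.zeros((n, g))
    G[np.arange(n), codes] = 1.0
    Rbar = (R @ G) / m                      # per-group residual means
    ssg = m * np.sum(Rbar**2, axis=1)
    sst = np.sum(R**2, axis=1)
    ssw = np.maximum(sst - ssg, 0.0)
    dfw = n - p - (g - 1)
    if dfw < 1:
        raise ValidationError("not enough residual degrees of freedom")
    msw = ssw / dfw
    msg = ssg / (g - 1)
    tau2 = (msg - msw) / m
    used_ols = ~(tau2 > 0) | ~(msw > 0)
    tau2 = np.where(used_ols, 0.0, np.maximum(tau2, 0.0))
    sigma2 = np.where(used_ols, sst / (n - p), msw)
    lam = np.where(used_ols, 0.0, np.divide(tau2, sigma2, out=np.zeros_like(tau2), where=sigma2 > 0))
    ddf = np.where(used_ols, n - p, dfw).astype(int)
    s = (X.T @ G)[:, 0]                     # shared per-group column sums
    w = XtXi @ s
    c = lam / (1.0 + lam * m)
    denom = 1.0 - c * g * float(s @ w)
    gamma = np.where(used_ols, 0.0, c * g / denom)
    return BalancedManyFit(B, sigma2, tau2, lam, ddf, used_ols, n, g, XtXi, w, gamma)


def contrast_f(fit: RandomInterceptFit, L: np.ndarray):
    """Wald F-test of ``L @ beta = 0``; returns ``(F, df1, df2, p)``."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    est = L @ fit.beta
    V = L @ fit.cov_beta @ L.T
    try:
        F = float(est @ np.linalg.solve(V, est)) / q
    except np.linalg.LinAlgError:
        return np.nan, q, fit.ddf, np.nan
    p = float(stats.f.sf(F, q, fit.ddf))
    return F, q, fit.ddf, p


def coef_t(fit: RandomInterceptFit):
    """Per-coefficient t statistics and two-sided p-values vs zero."""
    se = np.sqrt(np.diag(fit.cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.ddf)
    return t, se, p
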