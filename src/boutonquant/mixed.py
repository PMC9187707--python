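"""Random-intercept linear mixed model via profiled REML, with Wald F tests.

Model: ``y = X beta + Z u + e`` with one random intercept per group
(subject), ``u ~ N(0, sigma_u^2 I)``, ``e ~ N(0, sigma_e^2 I)``.  Writing
``lambda = sigma_u^2 / sigma_e^2``, the marginal covariance is
``sigma_e^2 (I + lambda Z Z')`` and block-diagonal by group, so GLS solves
reduce to per-group rank-one corrections (Woodbury).  REML is profiled down
to a 1-D search in ``lambda`` over ``[0, inf)``; the boundary
``lambda = 0`` (no subject variance) is reachable exactly, in which case the
fit coincides with ordinary least squares and the REML variance estimate
with the classical mean squared error.

Fixed effects are tested with Wald F statistics.  Denominator degrees of
freedom: ``residual`` (``n - rank(X)``, the granularity used in the study's
reporting) or a Satterthwaite approximation computed from the observed
information of the REML criterion in ``(sigma_u^2, sigma_e^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .errors import DegenerateDesignError


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray  # Cov(beta-hat) at the REML variance estimates
    sigma2_subject: float
    sigma2_residual: float
    lam: float
    n: int
    p: int
    group_sizes: np.ndarray
    X: np.ndarray
    y: np.ndarray
    group_index: np.ndarray  # 0-based group id per row

    @property
    def df_residual(self) -> int:
        return self.n - self.p


def _gls_pieces(lam: float, y: np.ndarray, X: np.ndarray, group_index: np.ndarray,
                n_groups: int):
    """X'WX, X'Wy, y'Wy and log|I + lam ZZ'| for W = (I + lam ZZ')^-1."""
    n_j = np.bincount(group_index, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * n_j)  # per-group Woodbury coefficient
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums
    Sx = np.zeros((n_groups, X.shape[1]))
    np.add.at(Sx, group_index, X)
    Sy = np.zeros(n_groups)
    np.add.at(Sy, group_index, y)
    XtWX = XtX - (Sx * c[:, None]).T @ Sx
    XtWy = Xty - Sx.T @ (c * Sy)
    ytWy = yty - float(Sy @ (c * Sy))
    logdet = float(np.sum(np.log1p(lam * n_j)))
    return XtWX, XtWy, ytWy, logdet


def _profiled_reml(lam: float, y: np.ndarray, X: np.ndarray, group_index: np.ndarray,
                   n_groups: int):
    n, p = X.shape
    XtWX, XtWy, ytWy, logdet = _gls_pieces(lam, y, X, group_index, n_groups)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 1e-300)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    crit = logdet + logdet_xwx + (n - p) * np.log(rss)
    return crit, beta, XtWX, rss


def fit_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                         fix_lambda: float | None = None) -> RandomInterceptFit:
    """Fit the random-intercept model by profiled REML.

    ``fix_lambda`` pins the variance ratio ``sigma_u^2 / sigma_e^2`` instead
    of estimating it; ``fix_lambda=0`` reduces the fit to ordinary least
    squares with the classical mean-squared-error variance estimate.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    _, group_index = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(group_index.max()) + 1
    if n_groups < 2:
        raise DegenerateDesignError(
            "at least 2 subjects are required to estimate the random intercept"
        )
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError("more fixed-effect parameters than rows")

    def crit(lam: float) -> float:
        return _profiled_reml(lam, y, X, group_index, n_groups)[0]

    if fix_lambda is not None:
        if fix_lambda < 0:
            raise DegenerateDesignError("fixed variance ratio must be nonnegative")
        lam_hat = float(fix_lambda)
        _, beta, XtWX, rss = _profiled_reml(lam_hat, y, X, group_index, n_groups)
        sigma2_e = rss / (n - p)
        return RandomInterceptFit(
            beta=beta, cov_beta=sigma2_e * np.linalg.inv(XtWX),
            sigma2_subject=lam_hat * sigma2_e, sigma2_residual=sigma2_e,
            lam=lam_hat, n=n, p=p,
            group_sizes=np.bincount(group_index, minlength=n_groups),
            X=X, y=y, group_index=group_index,
        )

    # coarse log-grid including the boundary, then a bounded refinement
    grid = np.concatenate([[0.0], np.logspace(-6, 6, 49)])
    vals = np.array([crit(g) for g in grid])
    k = int(np.argmin(vals))
    if k == 0:
        lam_hat = 0.0
        # confirm 0 is a local minimum against a tiny positive lambda
        if crit(1e-10) < vals[0]:
            res = optimize.minimize_scalar(crit, bounds=(0.0, grid[1]), method="bounded",
                                           options={"xatol": 1e-12})
            lam_hat = float(res.x)
    else:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        lam_hat = float(res.x)
        if crit(0.0) <= res.fun:
            lam_hat = 0.0

    _, beta, XtWX, rss = _profiled_reml(lam_hat, y, X, group_index, n_groups)
    sigma2_e = rss / (n - p)
    cov_beta = sigma2_e * np.linalg.inv(XtWX)
    n_j = np.bincount(group_index, minlength=n_groups)
    return RandomInterceptFit(
        beta=beta, cov_beta=cov_beta,
        sigma2_subject=lam_hat * sigma2_e, sigma2_residual=sigma2_e,
        lam=lam_hat, n=n, p=p, group_sizes=n_j, X=X, y=y, group_index=group_index,
    )


# ---------------------------------------------------------------------------
# inference


def _minus2_reml(theta: np.ndarray, fit: RandomInterceptFit) -> float:
    """-2 REML log-likelihood at (sigma_u^2, sigma_e^2), unprofiled."""
    s2u, s2e = float(theta[0]), float(theta[1])
    if s2e <= 0 or s2u < 0:
        return np.inf
    lam = s2u / s2e
    n_groups = len(fit.group_sizes)
    XtWX, XtWy, ytWy, logdet = _gls_pieces(lam, fit.y, fit.X, fit.group_index, n_groups)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    n, p = fit.n, fit.p
    return (n - p) * np.log(s2e) + logdet + logdet_xwx + rss / s2e


def _cov_theta(fit: RandomInterceptFit) -> np.ndarray:
    """Asymptotic covariance of the variance estimates (observed information)."""
    theta = np.array([fit.sigma2_subject, fit.sigma2_residual])
    h = np.maximum(1e-7 * np.maximum(theta, fit.sigma2_residual), 1e-10)
    H = np.zeros((2, 2))
    f0 = _minus2_reml(theta, fit)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            fpp = _minus2_reml(theta + ei + ej, fit)
            fpm = _minus2_reml(theta + ei - ej, fit) if theta[j] - h[j] >= 0 else np.nan
            fmp = _minus2_reml(theta - ei + ej, fit) if theta[i] - h[i] >= 0 else np.nan
            fmm = (_minus2_reml(theta - ei - ej, fit)
                   if theta[i] - h[i] >= 0 and theta[j] - h[j] >= 0 else np.nan)
            if np.isnan(fpm) or np.isnan(fmp) or np.isnan(fmm):
                # one-sided at the boundary
                f_i = _minus2_reml(theta + ei, fit)
                f_j = _minus2_reml(theta + ej, fit)
                H[i, j] = H[j, i] = (fpp - f_i - f_j + f0) / (h[i] * h[j])
            else:
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    info = 0.5 * H
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def _contrast_var(theta: np.ndarray, ell: np.ndarray, fit: RandomInterceptFit) -> float:
    s2u, s2e = float(theta[0]), float(theta[1])
    lam = max(s2u, 0.0) / s2e
    XtWX = _gls_pieces(lam, fit.y, fit.X, fit.group_index, len(fit.group_sizes))[0]
    C = s2e * np.linalg.inv(XtWX)
    return float(ell @ C @ ell)


def satterthwaite_df(fit: RandomInterceptFit, ell: np.ndarray,
                     cov_theta: np.ndarray | None = None) -> float:
    """Satterthwaite denominator df for a single contrast ``ell``."""
    theta = np.array([fit.sigma2_subject, fit.sigma2_residual])
    if cov_theta is None:
        cov_theta = _cov_theta(fit)
    h = np.maximum(1e-6 * np.maximum(theta, fit.sigma2_residual), 1e-9)
    g = np.zeros(2)
    for i in range(2):
        ei = np.zeros(2); ei[i] = h[i]
        hi = _contrast_var(theta + ei, ell, fit)
        if theta[i] - h[i] >= 0:
            lo = _contrast_var(theta - ei, ell, fit)
            g[i] = (hi - lo) / (2 * h[i])
        else:
            g[i] = (hi - _contrast_var(theta, ell, fit)) / h[i]
    v = _contrast_var(theta, ell, fit)
    denom = float(g @ cov_theta @ g)
    if denom <= 0:
        return float(fit.df_residual)
    df = 2.0 * v**2 / denom
    return float(np.clip(df, 1.0, fit.df_residual))


def wald_f(fit: RandomInterceptFit, L: np.ndarray,
           df_method: str = "residual") -> tuple[float, int, float, float]:
    """Wald F test of ``L beta = 0``.

    Returns ``(F, df_num, df_den, p)``.  For ``df_method="satterthwaite"``
    the denominator df follows the eigen-contrast decomposition of
    ``L C L'`` (per-contrast Satterthwaite df pooled as in standard
    mixed-model software); for ``"residual"`` it is ``n - rank(X)``.
    """
    L = np.atleast_2d(np.asarray(L, dtype=np.float64))
    q = np.linalg.matrix_rank(L)
    est = L @ fit.beta
    M = L @ fit.cov_beta @ L.T
    F = float(est @ np.linalg.solve(M, est)) / q
    if df_method == "residual":
        df_den = float(fit.df_residual)
    elif df_method == "satterthwaite":
        cov_theta = _cov_theta(fit)
        w, P = np.linalg.eigh(M)
        keep = w > 1e-12 * w.max()
        dfs = []
        for vec in (P[:, keep].T @ L):
            dfs.append(satterthwaite_df(fit, vec, cov_theta))
        dfs = np.asarray(dfs)
        if q == 1:
            df_den = float(dfs[0])
        else:
            e = np.sum([d / (d - 2.0) for d in dfs if d > 2.0])
            df_den = float(2.0 * e / (e - q)) if e > q else float(fit.df_residual)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    p = float(sps.f.sf(F, q, df_den))
    return F, int(q), df_den, p
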