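"""Per-sample linear mixed models.

Two engines fit the sample-wise regressions:

* :func:`fit_random_intercept` — a by-participant random-intercept model
  estimated by profiled maximum likelihood.  For a single variance ratio
  ``lambda = tau^2 / sigma^2`` the GLS solution and the profile
  log-likelihood are closed-form in per-group sufficient statistics, so one
  fit costs a 1-D optimisation over ``lambda`` — fast enough for the
  bootstrap power loop and the null-calibration simulations, which need
  tens of thousands of fits.

* :func:`fit_random_slopes` — statsmodels ``MixedLM`` (ML) with a
  by-participant random intercept and random slopes for the condition
  dummies, the default structure for the headline group analysis.

Both return Wald z p-values per fixed-effect coefficient and the model
log-likelihood (used for releveling-invariance checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats


@dataclass
class LMMFit:
    """Fixed-effect estimates of one per-sample mixed-model fit."""

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    loglik: float
    sigma2: float      # residual variance
    tau2: float        # random-intercept variance
    converged: bool
    nobs: int
    ngroups: int
    names: Sequence[str]

    def coef(self, name: str) -> int:
        return list(self.names).index(name)


def _failed_fit(p: int, names, nobs: int = 0, ngroups: int = 0) -> LMMFit:
    nan = np.full(p, np.nan)
    return LMMFit(nan, nan.copy(), nan.copy(), nan.copy(), np.nan, np.nan,
                  np.nan, False, nobs, ngroups, names)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: Optional[Sequence[str]] = None,
    lam_max: float = 1e5,
) -> LMMFit:
    """ML fit of ``y = X b + u_group + e`` with scalar random intercepts.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effect design matrix (n, p).
    groups
        Group label per row (any hashable dtype).
    names
        Coefficient names; defaults to ``b0..b{p-1}``.
    lam_max
        Upper bound of the profiled variance ratio ``tau^2/sigma^2``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = list(names) if names is not None else [f"b{j}" for j in range(p)]
    codes, _ = pd_factorize(groups)
    G = codes.max() + 1 if n else 0
    if n == 0 or G < 2 or n <= p:
        return _failed_fit(p, names, n, G)

    order = np.argsort(codes, kind="stable")
    Xs, ys, cs = X[order], y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cs) > 0])
    n_g = np.diff(np.r_[starts, n]).astype(float)

    Sxx = np.add.reduceat(Xs[:, :, None] * Xs[:, None, :], starts, axis=0)
    sx = np.add.reduceat(Xs, starts, axis=0)                # (G, p) = X_g' 1
    sxy = np.add.reduceat(Xs * ys[:, None], starts, axis=0)  # (G, p)
    s1y = np.add.reduceat(ys, starts)                        # (G,)
    syy = np.add.reduceat(ys * ys, starts)                   # (G,)

    Sxx_tot = Sxx.sum(axis=0)
    sxy_tot = sxy.sum(axis=0)
    syy_tot = syy.sum()
    outer_sx = sx[:, :, None] * sx[:, None, :]

    def profile(lam: float):
        w = lam / (1.0 + lam * n_g)
        A = Sxx_tot - np.tensordot(w, outer_sx, axes=1)
        c = sxy_tot - (w * s1y) @ sx
        q = syy_tot - np.sum(w * s1y ** 2)
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return np.inf, None
        rss = q - c @ beta
        if rss <= 0:
            rss = max(rss, 1e-12)
        sigma2 = rss / n
        m2ll = (n * np.log(2.0 * np.pi * sigma2) + np.sum(np.log1p(lam * n_g)) + n)
        return m2ll, (beta, A, sigma2)

    def objective(log_lam: float) -> float:
        return profile(np.exp(log_lam))[0]

    try:
        res = optimize.minimize_scalar(
            objective, bounds=(np.log(1e-8), np.log(lam_max)), method="bounded",
            options={"xatol": 1e-6},
        )
        candidates = [float(np.exp(res.x))] if res.success else []
    except Exception:
        candidates = []
    candidates.append(0.0)  # boundary: no group variance
    best_lam, best_m2ll, best_parts = None, np.inf, None
    for lam in candidates:
        m2ll, parts = profile(lam)
        if parts is not None and m2ll < best_m2ll:
            best_lam, best_m2ll, best_parts = lam, m2ll, parts
    if best_parts is None:
        return _failed_fit(p, names, n, G)

    beta, A, sigma2 = best_parts
    try:
        cov = sigma2 * np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return _failed_fit(p, names, n, G)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LMMFit(
        params=beta, bse=se, zvalues=z, pvalues=pvals,
        loglik=-0.5 * best_m2ll, sigma2=sigma2, tau2=best_lam * sigma2,
        converged=True, nobs=n, ngroups=G, names=names,
    )


def fit_random_slopes(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    exog_re: Optional[np.ndarray] = None,
    names: Optional[Sequence[str]] = None,
) -> LMMFit:
    """statsmodels MixedLM (ML) with random intercept + slopes per participant.

    ``exog_re`` defaults to the full fixed-effect design (random intercept
    plus a random slope for every non-intercept column).  Non-convergence is
    flagged, not raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = list(names) if names is not None else [f"b{j}" for j in range(p)]
    codes, _ = pd_factorize(groups)
    G = codes.max() + 1 if n else 0
    if n == 0 or G < 2 or n <= p:
        return _failed_fit(p, names, n, G)
    re = X if exog_re is None else np.asarray(exog_re, dtype=float)
    try:
        with warnings.catch_warnings():
            # boundary (zero) variance estimates warn but are valid fits
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=codes, exog_re=re)
            fit = model.fit(reml=False, maxiter=200)
            if not (getattr(fit, "converged", True) and np.isfinite(fit.llf)):
                retry = model.fit(reml=False, method="powell", maxiter=500)
                if getattr(retry, "converged", False) and np.isfinite(retry.llf):
                    fit = retry
    except Exception:
        return _failed_fit(p, names, n, G)
    converged = bool(getattr(fit, "converged", True)) and bool(np.isfinite(fit.llf))
    params = np.asarray(fit.fe_params, dtype=float)
    se = np.asarray(fit.bse_fe, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if np.any(~np.isfinite(se)):
        converged = False
    tau2 = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re is not None else np.nan
    return LMMFit(
        params=params, bse=se, zvalues=z, pvalues=pvals,
        loglik=float(fit.llf), sigma2=float(fit.scale), tau2=tau2,
        converged=converged, nobs=n, ngroups=G, names=names,
    )


def pd_factorize(values) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for group labels (thin wrapper kept import-light)."""
    import pandas as pd

    codes, uniques = pd.factorize(np.asarray(values))
    return codes.astype(np.int64), np.asarray(uniques)
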