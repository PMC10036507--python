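"""Fast profiled-ML fit of a linear model with one random intercept.

For ``y = X b + Z u + e`` with ``u ~ N(0, s_u^2 I)`` over a single grouping
factor, the likelihood profiles down to a 1-D optimisation over the variance
ratio ``lam = s_u^2 / s_e^2``; each evaluation is a closed-form GLS solve
using group sums (Sherman-Morrison within groups).  This makes the
1000-draw bootstrap loops of the mediation module tractable; it is verified
against statsmodels MixedLM in the test suite.  Wald inference uses the
normal reference distribution, as statsmodels MixedLM does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class RandomInterceptFit:
    params: np.ndarray       # fixed-effect coefficients
    bse: np.ndarray          # standard errors
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2_group: float      # random-intercept variance
    sigma2_resid: float
    llf: float
    aic: float
    n: int
    names: list


def _profile(lam, n, p, XtX, Xty, yty, SX, Sy, ng):
    w = lam / (1.0 + lam * ng)
    XtViX = XtX - (SX * w[:, None]).T @ SX
    XtViy = Xty - SX.T @ (w * Sy)
    yViy = yty - float(w @ Sy**2)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        # singular design (e.g. exactly collinear columns): least-norm solution
        beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
    rss = yViy - 2.0 * beta @ XtViy + beta @ XtViX @ beta
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2)
                 + np.log1p(lam * ng).sum() + n)
    return ll, beta, sigma2, XtViX


def fit_random_intercept(y, X, groups, names=None) -> RandomInterceptFit:
    """Maximum-likelihood random-intercept regression.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effects design (include the intercept column)
    groups : (n,) group labels (any hashable; site IDs)
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    codes, _ = pd_factorize(groups)
    g = codes.max() + 1
    ng = np.bincount(codes, minlength=g).astype(float)
    SX = np.zeros((g, p))
    np.add.at(SX, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=g)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def neg_ll(loglam):
        return -_profile(np.exp(loglam), n, p, XtX, Xty, yty, SX, Sy, ng)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-15.0, 8.0), method="bounded",
                                   options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    # compare against the boundary (no group variance)
    ll0 = _profile(0.0, n, p, XtX, Xty, yty, SX, Sy, ng)[0]
    if ll0 >= -res.fun:
        lam = 0.0
    ll, beta, sigma2, XtViX = _profile(lam, n, p, XtX, Xty, yty, SX, Sy, ng)
    cov = sigma2 * np.linalg.pinv(XtViX)
    bse = np.sqrt(np.abs(np.diag(cov)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse   # nan/inf for degenerate (zero-residual) fits
    pvals = 2.0 * stats.norm.sf(np.abs(tvals))
    aic = -2.0 * ll + 2.0 * (p + 2)  # fixed effects + two variances
    return RandomInterceptFit(
        params=beta, bse=bse, tvalues=tvals, pvalues=pvals,
        sigma2_group=lam * sigma2, sigma2_resid=sigma2, llf=float(ll),
        aic=float(aic), n=n, names=list(names) if names is not None else None)


def pd_factorize(values):
    import pandas as pd
    return pd.factorize(np.asarray(values))
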