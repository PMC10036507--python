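"""Penalized additive spline regression for age prediction.

One smooth term per feature: a clamped cubic B-spline basis for continuous
features, and a saturated indicator basis for low-cardinality ordinal
features (e.g. 4-level PDS items, binary menarche), for which quantile knots
would degenerate.  All term coefficients share a single ridge penalty
``alpha`` chosen by grid search in the surrounding cross-validation; the fit
itself is a closed-form penalized least-squares solve.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted


class AdditiveSplineAgeRegressor(RegressorMixin, BaseEstimator):
    """Additive model ``y = b0 + sum_j f_j(x_j)`` with ridge-penalized bases.

    Parameters
    ----------
    alpha : float
        Shared smoothing/ridge penalty on all basis coefficients.
    df : int
        Basis dimension per continuous feature (>= degree + 1).
    degree : int
        B-spline degree (cubic by default).
    ordinal_max_levels : int
        Features with at most this many distinct training values get a
        saturated indicator basis instead of a spline.
    """

    def __init__(self, alpha: float = 1.0, df: int = 5, degree: int = 3,
                 ordinal_max_levels: int = 5):
        self.alpha = alpha
        self.df = df
        self.degree = degree
        self.ordinal_max_levels = ordinal_max_levels

    # -- basis construction --------------------------------------------------

    def _make_term(self, x: np.ndarray):
        levels = np.unique(x)
        if levels.size == 1:
            return ("constant", None)
        if levels.size <= self.ordinal_max_levels:
            return ("ordinal", levels)
        k = self.degree
        n_interior = max(self.df - k - 1, 0)
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.unique(np.quantile(x, qs))
            interior = interior[(interior > x.min()) & (interior < x.max())]
        else:
            interior = np.array([])
        t = np.r_[[x.min()] * (k + 1), interior, [x.max()] * (k + 1)]
        return ("spline", t)

    def _term_design(self, x: np.ndarray, kind, info) -> np.ndarray:
        if kind == "constant":
            return np.empty((x.shape[0], 0))
        if kind == "ordinal":
            levels = info
            idx = np.abs(x[:, None] - levels[None, :]).argmin(axis=1)
            cols = [(idx == i).astype(float) for i in range(1, levels.size)]
            return np.column_stack(cols)
        t = info
        k = self.degree
        xc = np.clip(x, t[0], t[-1])
        return BSpline.design_matrix(xc, t, k).toarray()

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        self.terms_ = [self._make_term(X[:, j]) for j in range(X.shape[1])]
        blocks = [self._term_design(X[:, j], *self.terms_[j])
                  for j in range(X.shape[1])]
        B = np.hstack(blocks) if blocks else np.empty((X.shape[0], 0))
        self.basis_means_ = B.mean(axis=0)
        Bc = B - self.basis_means_
        self.y_mean_ = float(y.mean())
        p = Bc.shape[1]
        if p == 0:
            self.coef_ = np.empty(0)
        else:
            A = Bc.T @ Bc + (self.alpha + 1e-10) * np.eye(p)
            self.coef_ = np.linalg.solve(A, Bc.T @ (y - self.y_mean_))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        blocks = [self._term_design(X[:, j], *self.terms_[j])
                  for j in range(X.shape[1])]
        B = np.hstack(blocks) if blocks else np.empty((X.shape[0], 0))
        if B.shape[1] == 0:
            return np.full(X.shape[0], self.y_mean_)
        return self.y_mean_ + (B - self.basis_means_) @ self.coef_
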