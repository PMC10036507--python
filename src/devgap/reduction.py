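"""Standardize-then-PCA preprocessing with a cumulative-variance cutoff."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted


class StandardizedPCA(TransformerMixin, BaseEstimator):
    """Center/scale features, then keep the smallest number of principal
    components whose cumulative explained variance reaches ``variance_threshold``.

    Constant (zero-variance) features are dropped with a warning before
    scaling.  With ``variance_threshold=1.0`` all non-degenerate components
    are kept.

    Attributes
    ----------
    n_components_ : int
        Number of components retained.
    explained_variance_ratio_ : ndarray
        Ratios of the retained components.
    kept_features_ : ndarray of int
        Indices of the non-constant input features that were used.
    """

    _EPS = 1e-12

    def __init__(self, variance_threshold: float = 0.90):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        X = check_array(X, ensure_min_samples=2)
        variances = X.var(axis=0)
        keep = variances > self._EPS
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) "
                          "before scaling", UserWarning, stacklevel=2)
        if not keep.any():
            raise ValueError("all features are constant")
        self.kept_features_ = np.flatnonzero(keep)
        self.scaler_ = StandardScaler().fit(X[:, self.kept_features_])
        Z = self.scaler_.transform(X[:, self.kept_features_])
        pca = PCA(svd_solver="full").fit(Z)
        ratios = pca.explained_variance_ratio_
        nondegenerate = ratios > self._EPS
        cum = np.cumsum(ratios)
        if self.variance_threshold >= 1.0 - self._EPS:
            n = int(nondegenerate.sum())
        else:
            n = int(np.searchsorted(cum, self.variance_threshold - 1e-10) + 1)
            n = min(n, int(nondegenerate.sum()))
        self.n_components_ = max(n, 1)
        self.pca_ = pca
        self.components_ = pca.components_[: self.n_components_]
        self.explained_variance_ratio_ = ratios[: self.n_components_]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_components_")
        X = check_array(X)
        Z = self.scaler_.transform(X[:, self.kept_features_])
        return Z @ self.components_.T
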