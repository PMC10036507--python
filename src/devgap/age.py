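"""The normative "X-age" engine.

Fits an age-prediction model on a typically-developing subset under nested,
family-grouped cross-validation; adjusts predictions for the
regression-to-the-mean age bias; and turns predictions into per-participant
developmental gaps (adjusted predicted age minus chronological age).

Two estimator families are provided: ``kernel_pca`` (standardize + PCA to a
cumulative-variance cutoff + RBF support-vector regression; used for brain
age) and ``additive_spline`` (penalized additive splines over pubertal
features; used for the three puberty-age variants: physical, hormonal,
combined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import ParameterGrid
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from ._utils import derive_seed, pearson_r
from .atlas import RegionLobeMap
from .reduction import StandardizedPCA
from .simulate import (DSM_SCALES, FEMALE_PDS_ITEMS, HORMONE_COLUMNS,
                       MALE_PDS_ITEMS, MENARCHE_COLUMN)
from .splines import AdditiveSplineAgeRegressor

log = logging.getLogger(__name__)

DEFAULT_TD_THRESHOLD = 60.0

DEFAULT_KERNEL_GRID = {
    "C": [0.1, 1.0, 10.0, 100.0],
    "gamma_scale": [0.1, 1.0, 10.0],
    "epsilon": [0.01, 0.1],
}
DEFAULT_SPLINE_GRID = {"alpha": [0.01, 0.1, 1.0, 10.0]}


# ---------------------------------------------------------------------------
# cohort subsetting

def select_single_timepoint(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One row per participant, chosen uniformly among that participant's visits."""
    if cohort.empty:
        return cohort.copy()
    rng = np.random.default_rng(seed)
    # stable participant order; uniform pick independent of row order
    picks = []
    for pid, idx in cohort.groupby("participant_id", sort=True).groups.items():
        idx = np.sort(np.asarray(idx))
        picks.append(idx[rng.integers(idx.size)])
    return cohort.loc[sorted(picks)].reset_index(drop=True)


def select_typically_developing(cohort: pd.DataFrame,
                                threshold: float = DEFAULT_TD_THRESHOLD,
                                scales: list[str] | None = None) -> pd.DataFrame:
    """Participants whose every clinical screening score is strictly below
    ``threshold`` (default 60, the non-clinical range).

    Participants with any missing scale value are excluded and logged.
    """
    if cohort.empty:
        return cohort.copy()
    if scales is None:
        scales = [c for c in DSM_SCALES if c in cohort.columns]
    missing = [s for s in scales if s not in cohort.columns]
    if missing or not scales:
        raise ValueError(f"clinical scales not present in cohort: {missing or scales}")
    block = cohort[scales]
    row_ok = (block < threshold).all(axis=1) & block.notna().all(axis=1)
    by_participant = row_ok.groupby(cohort["participant_id"]).all()
    n_missing = int(cohort.groupby("participant_id")[scales].apply(
        lambda g: g.isna().any().any()).sum())
    if n_missing:
        log.info("typically-developing filter: %d participant(s) excluded for "
                 "missing scale values", n_missing)
    keep = cohort["participant_id"].map(by_participant)
    return cohort[keep.astype(bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature sets

FEATURE_SETS = ("brain", "pds_physical", "hormonal", "combined")


def feature_columns_for(feature_set: str, cohort: pd.DataFrame,
                        sex: str | None = None) -> list[str]:
    """Resolve a named feature set against the cohort's columns.

    Puberty feature sets are sex-specific (PDS item sets differ; menarche is
    female-only), so ``sex`` is required for them.
    """
    if feature_set == "brain":
        return [c for c in RegionLobeMap.default().feature_columns()
                if c in cohort.columns]
    if feature_set in ("pds_physical", "hormonal", "combined"):
        if sex not in ("F", "M"):
            raise ValueError(f"feature set {feature_set!r} is sex-specific; "
                             "pass sex='F' or 'M'")
        physical = list(FEMALE_PDS_ITEMS) + [MENARCHE_COLUMN] if sex == "F" \
            else list(MALE_PDS_ITEMS)
        hormonal = list(HORMONE_COLUMNS)
        cols = {"pds_physical": physical, "hormonal": hormonal,
                "combined": physical + hormonal}[feature_set]
        absent = [c for c in cols if c not in cohort.columns]
        if absent:
            raise ValueError(f"cohort lacks feature columns: {absent}")
        return cols
    raise ValueError(f"unknown feature set {feature_set!r}; "
                     f"expected one of {FEATURE_SETS}")


def extract_features(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Feature matrix with hormones log-transformed (strictly positive, skewed)."""
    absent = [c for c in columns if c not in cohort.columns]
    if absent:
        raise ValueError(f"cohort lacks feature columns: {absent}")
    X = cohort[columns].astype(float).copy()
    for h in HORMONE_COLUMNS:
        if h in X.columns:
            X[h] = np.log(X[h])
    return X


# ---------------------------------------------------------------------------
# estimators

class PCAKernelAgeRegressor(BaseEstimator):
    """Standardize + PCA (cumulative-variance cutoff) + RBF-kernel SVR.

    ``gamma_scale`` multiplies the usual 'scale' bandwidth heuristic
    ``1 / (n_components * var(Z))`` computed on the PCA scores.
    """

    def __init__(self, variance_threshold: float = 0.90, C: float = 1.0,
                 gamma_scale: float = 1.0, epsilon: float = 0.1):
        self.variance_threshold = variance_threshold
        self.C = C
        self.gamma_scale = gamma_scale
        self.epsilon = epsilon

    def fit(self, X, y):
        self.reducer_ = StandardizedPCA(self.variance_threshold).fit(X)
        Z = self.reducer_.transform(X)
        gamma = self.gamma_scale / (Z.shape[1] * Z.var())
        self.svr_ = SVR(kernel="rbf", C=self.C, gamma=gamma,
                        epsilon=self.epsilon).fit(Z, y)
        self.n_components_ = self.reducer_.n_components_
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        return self.svr_.predict(self.reducer_.transform(X))


def make_estimator(name: str, variance_threshold: float = 0.90) -> BaseEstimator:
    if name == "kernel_pca":
        return PCAKernelAgeRegressor(variance_threshold=variance_threshold)
    if name == "additive_spline":
        return AdditiveSplineAgeRegressor()
    raise ValueError(f"unknown estimator {name!r}")


def default_grid(name: str) -> dict:
    return {"kernel_pca": DEFAULT_KERNEL_GRID,
            "additive_spline": DEFAULT_SPLINE_GRID}[name]


# ---------------------------------------------------------------------------
# config

@dataclass
class AgeModelConfig:
    """Settings for one normative age model."""

    feature_set: str = "brain"
    estimator: str = "kernel_pca"
    variance_threshold: float = 0.90
    outer_folds: int = 10
    inner_folds: int = 10
    hyper_grid: dict | None = None
    sex_stratified: bool = False   # True for puberty models
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")


# ---------------------------------------------------------------------------
# the engine

class NormativeAgeModel(BaseEstimator):
    """Family-grouped nested-CV age model with RTM bias adjustment.

    ``fit`` expects the training population: typically-developing
    participants, one row (timepoint) each.  Outer folds partition families
    (siblings are never split across train and test); inner folds tune
    hyperparameters on training folds only; preprocessing is refit inside
    every training fold.  Out-of-fold raw predictions for the whole training
    population are retained, the raw age gap is regressed on age
    (coefficients ``rtm_intercept_``, ``rtm_slope_``), and a final model is
    refit on all rows with the modal/median fold-winning hyperparameters.

    Fitted attributes: ``estimator_``, ``rtm_slope_``, ``rtm_intercept_``,
    ``oof_`` (out-of-fold prediction table), ``cv_metadata_`` (fold map and
    per-fold hyperparameters), ``feature_names_``, ``training_participants_``.
    """

    def __init__(self, feature_set: str = "brain", features: list | None = None,
                 estimator: str = "kernel_pca", variance_threshold: float = 0.90,
                 outer_folds: int = 10, inner_folds: int = 10,
                 hyper_grid: dict | None = None, sex: str | None = None,
                 random_state: int = 0):
        self.feature_set = feature_set
        self.features = features
        self.estimator = estimator
        self.variance_threshold = variance_threshold
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.hyper_grid = hyper_grid
        self.sex = sex
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _resolve_features(self, cohort: pd.DataFrame) -> list[str]:
        if self.features is not None:
            return list(self.features)
        return feature_columns_for(self.feature_set, cohort, sex=self.sex)

    def _base_estimator(self) -> BaseEstimator:
        est = make_estimator(self.estimator, self.variance_threshold)
        return est

    def _grid(self) -> list[dict]:
        grid = self.hyper_grid or default_grid(self.estimator)
        return list(ParameterGrid(grid))

    @staticmethod
    def _family_folds(families: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> dict:
        unique = np.sort(np.unique(families))
        if unique.size < n_folds:
            raise ValueError(f"need at least {n_folds} families, "
                             f"got {unique.size}")
        order = rng.permutation(unique.size)
        fold_of = {}
        for fold, chunk in enumerate(np.array_split(unique[order], n_folds)):
            for fam in chunk:
                fold_of[fam] = fold
        return fold_of

    def _tune(self, X: np.ndarray, y: np.ndarray, families: np.ndarray,
              candidates: list[dict], fold_seed: int) -> dict:
        """Inner grouped-CV grid search on the outer-training rows; mean MAE."""
        if len(candidates) == 1:
            return candidates[0]
        n_inner = min(self.inner_folds, np.unique(families).size)
        rng = np.random.default_rng(fold_seed)
        fold_of = self._family_folds(families, n_inner, rng)
        fold_idx = np.array([fold_of[f] for f in families])
        maes = np.zeros(len(candidates))
        for k in range(n_inner):
            tr, te = fold_idx != k, fold_idx == k
            for i, params in enumerate(candidates):
                est = clone(self._base_estimator()).set_params(**params)
                est.fit(X[tr], y[tr])
                maes[i] += np.abs(est.predict(X[te]) - y[te]).mean()
        return candidates[int(np.argmin(maes))]  # ties: first in grid order

    @staticmethod
    def _consensus_params(winners: list[dict], candidates: list[dict]) -> dict:
        """Mode for categorical, median snapped to the grid for numeric."""
        out = {}
        for key in winners[0]:
            vals = [w[key] for w in winners]
            if all(isinstance(v, (int, float)) and not isinstance(v, bool)
                   for v in vals):
                m = median(vals)
                grid_vals = sorted({c[key] for c in candidates})
                out[key] = min(grid_vals, key=lambda g: (abs(g - m), g))
            else:
                out[key] = max(sorted(set(vals), key=str),
                               key=lambda v: sum(w == v for w in vals))
        return out

    # -- sklearn API ---------------------------------------------------------

    def fit(self, cohort: pd.DataFrame, y=None):
        cols = self._resolve_features(cohort)
        X_df = extract_features(cohort, cols)
        rows = X_df.notna().all(axis=1) & cohort["age"].notna()
        n_dropped = int((~rows).sum())
        if n_dropped:
            log.info("nested CV: dropping %d row(s) with missing features", n_dropped)
        data = cohort[rows].reset_index(drop=True)
        X = X_df[rows.values].to_numpy(float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values in training data")
        y_age = data["age"].to_numpy(float)
        families = data["family_id"].to_numpy()

        rng = np.random.default_rng(derive_seed(self.random_state, "cv-outer"))
        fold_of_family = self._family_folds(families, self.outer_folds, rng)
        fold_idx = np.array([fold_of_family[f] for f in families])

        candidates = self._grid()
        oof = np.full(len(data), np.nan)
        fold_params = []
        for k in range(self.outer_folds):
            tr, te = fold_idx != k, fold_idx == k
            params = self._tune(X[tr], y_age[tr], families[tr], candidates,
                                derive_seed(self.random_state, f"cv-inner-{k}"))
            est = clone(self._base_estimator()).set_params(**params)
            est.fit(X[tr], y_age[tr])
            oof[te] = est.predict(X[te])
            fold_params.append(params)

        final_params = self._consensus_params(fold_params, candidates)
        self.estimator_ = clone(self._base_estimator()).set_params(**final_params)
        self.estimator_.fit(X, y_age)

        raw_gap = oof - y_age
        self.rtm_slope_, self.rtm_intercept_ = fit_rtm_correction(y_age, oof)

        self.feature_names_ = cols
        self.final_params_ = final_params
        self.oof_ = pd.DataFrame({
            "participant_id": data["participant_id"].to_numpy(),
            "visit": data["visit"].astype(str).to_numpy()
            if "visit" in data.columns else "baseline",
            "age": y_age,
            "predicted_age_raw": oof,
            "fold": fold_idx,
        })
        self.cv_metadata_ = {
            "fold_of_family": fold_of_family,
            "fold_params": fold_params,
            "final_params": final_params,
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "n_dropped_rows": n_dropped,
        }
        self.training_participants_ = set(self.oof_["participant_id"])
        return self

    # raw (not bias-adjusted) predictions
    def predict_raw(self, cohort: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "estimator_")
        missing = [c for c in self.feature_names_ if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks feature columns: {missing}")
        X_df = extract_features(cohort, self.feature_names_)
        ok = X_df.notna().all(axis=1)
        pred = pd.Series(np.nan, index=cohort.index)
        if ok.any():
            pred[ok] = self.estimator_.predict(X_df[ok].to_numpy(float))
        # training-population rows keep their out-of-fold predictions
        key = cohort["participant_id"].astype(str)
        if "visit" in cohort.columns:
            key = key + "|" + cohort["visit"].astype(str)
            oof_key = (self.oof_["participant_id"].astype(str) + "|"
                       + self.oof_["visit"].astype(str))
        else:
            oof_key = self.oof_["participant_id"].astype(str)
        oof_map = pd.Series(self.oof_["predicted_age_raw"].to_numpy(),
                            index=oof_key)
        oof_map = oof_map[~oof_map.index.duplicated()]
        from_oof = key.map(oof_map)
        return from_oof.combine_first(pred)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """Bias-adjusted predicted age."""
        raw = self.predict_raw(cohort)
        age = cohort["age"].to_numpy(float)
        adj = raw.to_numpy(float) - (self.rtm_intercept_ + self.rtm_slope_ * age)
        return adj

    def gap_table(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Per-row predicted ages and gaps; rows without usable predictions
        (missing feature values outside the training population) are dropped."""
        raw = self.predict_raw(cohort).to_numpy(float)
        age = cohort["age"].to_numpy(float)
        adj = raw - (self.rtm_intercept_ + self.rtm_slope_ * age)
        out = pd.DataFrame({
            "participant_id": cohort["participant_id"].to_numpy(),
            "visit": cohort["visit"].astype(str).to_numpy()
            if "visit" in cohort.columns else "baseline",
            "chronological_age": age,
            "predicted_age_raw": raw,
            "predicted_age_adjusted": adj,
            "gap": adj - age,
        })
        n_bad = int(out["predicted_age_raw"].isna().sum())
        if n_bad:
            log.info("gap table: dropping %d row(s) without predictions", n_bad)
        return out.dropna(subset=["predicted_age_raw"]).reset_index(drop=True)

    transform = gap_table


# ---------------------------------------------------------------------------
# functional wrappers (the operation surface)

def fit_reducer(features, variance_threshold: float = 0.90) -> StandardizedPCA:
    """Center/scale + PCA keeping the smallest component count reaching the
    cumulative-explained-variance threshold."""
    return StandardizedPCA(variance_threshold).fit(np.asarray(features, float))


def nested_cv_fit(cohort: pd.DataFrame, config: AgeModelConfig,
                  sex: str | None = None
                  ) -> tuple[NormativeAgeModel, pd.DataFrame]:
    """Fit the engine per ``config``; returns the fitted model and the
    out-of-fold gap table for the training population."""
    model = NormativeAgeModel(
        feature_set=config.feature_set, estimator=config.estimator,
        variance_threshold=config.variance_threshold,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        hyper_grid=config.hyper_grid, sex=sex, random_state=config.seed)
    model.fit(cohort)
    oof = model.oof_
    adj = (oof["predicted_age_raw"]
           - (model.rtm_intercept_ + model.rtm_slope_ * oof["age"]))
    gaps = pd.DataFrame({
        "participant_id": oof["participant_id"],
        "visit": oof["visit"],
        "chronological_age": oof["age"],
        "predicted_age_raw": oof["predicted_age_raw"],
        "predicted_age_adjusted": adj,
        "gap": adj - oof["age"],
    })
    return model, gaps


def fit_rtm_correction(ages, raw_predictions) -> tuple[float, float]:
    """Least-squares fit of the raw age gap on chronological age.

    Returns ``(slope, intercept)`` of ``raw_gap = intercept + slope * age``.
    """
    ages = np.asarray(ages, float)
    raw = np.asarray(raw_predictions, float)
    if ages.size < 3:
        raise ValueError("need at least 3 training points for the RTM fit")
    if ages.var() == 0:
        raise ValueError("zero age variance: RTM correction is unidentified")
    slope, intercept = np.polyfit(ages, raw - ages, 1)
    return float(slope), float(intercept)


def apply_gap(model: NormativeAgeModel, cohort: pd.DataFrame) -> pd.DataFrame:
    return model.gap_table(cohort)


def model_accuracy(gap_table: pd.DataFrame,
                   predictions: str = "raw") -> tuple[float, float]:
    """(Pearson r between predicted and chronological age, MAE in months).

    Accuracy is computed on the raw model predictions by default: the RTM
    adjustment is a function of age alone, so it cannot add predictive
    information, and judging it against age would make even a constant
    predictor look accurate.  Pass ``predictions='adjusted'`` to evaluate the
    bias-adjusted ages instead.
    """
    if len(gap_table) < 3:
        raise ValueError("need at least 3 rows")
    col = {"raw": "predicted_age_raw",
           "adjusted": "predicted_age_adjusted"}[predictions]
    age = gap_table["chronological_age"]
    r = pearson_r(gap_table[col], age)
    mae_months = float(np.abs(gap_table[col] - age).mean() * 12.0)
    return r, mae_months
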