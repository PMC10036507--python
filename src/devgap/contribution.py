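"""Leave-one-lobe-out / leave-one-region-out contribution analysis.

A unit's (lobe's or region's) contribution to the gap-gap association is the
drop in the association T-statistic when the brain-age model is retrained
without that unit's features: ``delta_t = t_full - t_without``.  Fold
assignments and seeds are held fixed across leave-out iterations, so the
change reflects feature removal rather than resampling noise; PCA is refit
within each iteration at the same variance threshold.  Delta-T values are
magnitudes, not a decomposition: no normalization is applied and they need
not sum to the full-model T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .age import AgeModelConfig, NormativeAgeModel
from .association import fit_gap_association
from .atlas import RegionLobeMap

log = logging.getLogger(__name__)


@dataclass
class ContributionRecord:
    unit: str
    t_full: float
    t_without: float
    delta_t: float


def _fit_brain_gaps(train_cohort: pd.DataFrame, assoc_cohort: pd.DataFrame,
                    features: list[str], config: AgeModelConfig) -> pd.DataFrame:
    model = NormativeAgeModel(
        features=features, estimator=config.estimator,
        variance_threshold=config.variance_threshold,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        hyper_grid=config.hyper_grid, random_state=config.seed)
    model.fit(train_cohort)
    return model.gap_table(assoc_cohort)


def _association_t(brain_gaps, puberty_gaps, assoc_cohort, covariates):
    fit = fit_gap_association(brain_gaps, puberty_gaps, assoc_cohort,
                              covariates=covariates)
    return fit.term("puberty_gap").t_statistic


def leave_one_lobe_out_scan(train_cohort: pd.DataFrame,
                            assoc_cohort: pd.DataFrame,
                            puberty_gaps: pd.DataFrame,
                            lobe_map: RegionLobeMap | None = None,
                            config: AgeModelConfig | None = None,
                            covariates: list[str] | None = None
                            ) -> list[ContributionRecord]:
    """Retrain the brain-age model once per lobe with that lobe's features
    removed; records are sorted by contribution (delta_t) descending."""
    lobe_map = lobe_map or RegionLobeMap.default()
    config = config or AgeModelConfig()
    all_features = [c for c in lobe_map.feature_columns()
                    if c in train_cohort.columns]
    if not all_features:
        raise ValueError("no mapped brain features present in the cohort")
    full_gaps = _fit_brain_gaps(train_cohort, assoc_cohort, all_features, config)
    t_full = _association_t(full_gaps, puberty_gaps, assoc_cohort, covariates)

    records = []
    for lobe in lobe_map.lobes():
        dropped = set(lobe_map.features_in_lobe(lobe)) & set(all_features)
        if not dropped:
            raise ValueError(f"lobe {lobe!r} has no mapped features in the cohort")
        kept = [c for c in all_features if c not in dropped]
        gaps = _fit_brain_gaps(train_cohort, assoc_cohort, kept, config)
        t_wo = _association_t(gaps, puberty_gaps, assoc_cohort, covariates)
        records.append(ContributionRecord(unit=lobe, t_full=t_full,
                                          t_without=t_wo,
                                          delta_t=t_full - t_wo))
        log.info("LOLO %-10s T_without=%.3f  deltaT=%.3f", lobe, t_wo,
                 t_full - t_wo)
    records.sort(key=lambda r: r.delta_t, reverse=True)
    return records


def leave_one_region_out_scan(train_cohort: pd.DataFrame,
                              assoc_cohort: pd.DataFrame,
                              puberty_gaps: pd.DataFrame,
                              config: AgeModelConfig | None = None,
                              granularity: str = "feature",
                              lobe_map: RegionLobeMap | None = None,
                              covariates: list[str] | None = None
                              ) -> list[ContributionRecord]:
    """As the lobe scan, but one iteration per single region-metric column
    (``granularity='feature'``) or per region with all its metrics dropped
    together (``granularity='region'``, hemisphere-specific)."""
    if granularity not in ("feature", "region"):
        raise ValueError("granularity must be 'feature' or 'region'")
    lobe_map = lobe_map or RegionLobeMap.default()
    config = config or AgeModelConfig()
    all_features = [c for c in lobe_map.feature_columns()
                    if c in train_cohort.columns]
    if not all_features:
        raise ValueError("no mapped brain features present in the cohort")
    full_gaps = _fit_brain_gaps(train_cohort, assoc_cohort, all_features, config)
    t_full = _association_t(full_gaps, puberty_gaps, assoc_cohort, covariates)

    if granularity == "feature":
        units = {c: [c] for c in all_features}
    else:
        units = {}
        for c in all_features:
            hemi = c.split("_", 1)[0]
            units.setdefault(f"{hemi}_{lobe_map.region_of(c)}", []).append(c)

    records = []
    for unit, dropped in units.items():
        kept = [c for c in all_features if c not in dropped]
        if not kept:
            raise ValueError(f"removing {unit!r} would leave no features")
        gaps = _fit_brain_gaps(train_cohort, assoc_cohort, kept, config)
        t_wo = _association_t(gaps, puberty_gaps, assoc_cohort, covariates)
        records.append(ContributionRecord(unit=unit, t_full=t_full,
                                          t_without=t_wo,
                                          delta_t=t_full - t_wo))
    records.sort(key=lambda r: r.delta_t, reverse=True)
    return records


def lobar_age_model(cohort: pd.DataFrame, lobe: str,
                    lobe_map: RegionLobeMap | None = None,
                    config: AgeModelConfig | None = None
                    ) -> tuple[NormativeAgeModel, pd.DataFrame]:
    """Brain-age model restricted to one lobe's features (e.g. a subcortical
    brain age for mediation); returns the fitted model and its out-of-fold
    gap table."""
    lobe_map = lobe_map or RegionLobeMap.default()
    config = config or AgeModelConfig()
    features = [c for c in lobe_map.features_in_lobe(lobe)
                if c in cohort.columns]
    if len(features) < 2:
        raise ValueError(f"lobe {lobe!r} has {len(features)} feature(s) in the "
                         "cohort; need at least 2")
    model = NormativeAgeModel(
        features=features, estimator=config.estimator,
        variance_threshold=config.variance_threshold,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        hyper_grid=config.hyper_grid, random_state=config.seed)
    model.fit(cohort)
    return model, model.gap_table(cohort)


def records_frame(records: list[ContributionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def contribution_barplot(records: list[ContributionRecord], path=None, ax=None):
    """Bar chart of delta-T contributions (optional; needs matplotlib)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_frame(records)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(df)), 3.5))
    ax.bar(df["unit"], df["delta_t"])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel(r"$\Delta$T (full $-$ leave-out)")
    ax.tick_params(axis="x", rotation=60)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
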