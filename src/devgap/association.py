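"""Cross-sectional gap-gap association with a site random intercept.

Fits ``brain age gap ~ puberty age gap + age + (1 | site)`` by maximum
likelihood (ML, not REML, so AIC is comparable across the three puberty-age
variants), sex-stratified, after sampling one participant per family.
Benjamini-Hochberg FDR correction is applied across the puberty variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)

PUBERTY_VARIANTS = ("pds_physical", "combined", "hormonal")


@dataclass
class TermEstimate:
    coefficient: float
    standard_error: float
    t_statistic: float
    p_value: float


@dataclass
class LMEFit:
    """Fixed-effect estimates of one mixed (or fallback OLS) fit."""

    outcome_name: str
    term_estimates: dict = field(default_factory=dict)  # term -> TermEstimate
    aic: float = np.nan
    site_variance: float = np.nan
    n_used: int = 0
    method: str = "mixed"   # "mixed" or "ols" (degenerate-site fallback)

    def term(self, name: str) -> TermEstimate:
        return self.term_estimates[name]


def select_one_per_family(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Exactly one participant per family, uniform at random, reproducible."""
    if cohort.empty:
        return cohort.copy()
    rng = np.random.default_rng(seed)
    participants = (cohort[["participant_id", "family_id"]]
                    .drop_duplicates()
                    .sort_values(["family_id", "participant_id"]))
    keep = []
    for fam, grp in participants.groupby("family_id", sort=True):
        ids = grp["participant_id"].to_numpy()
        keep.append(ids[rng.integers(ids.size)])
    return (cohort[cohort["participant_id"].isin(keep)]
            .reset_index(drop=True))


def _extract_fit(res, terms) -> tuple[dict, float]:
    est = {}
    for t in terms:
        est[t] = TermEstimate(
            coefficient=float(res.params[t]),
            standard_error=float(res.bse[t]),
            t_statistic=float(res.tvalues[t]),
            p_value=float(res.pvalues[t]),
        )
    return est, float(res.aic)


def fit_gap_association(brain_gaps: pd.DataFrame, puberty_gaps: pd.DataFrame,
                        cohort: pd.DataFrame,
                        covariates: list[str] | None = None) -> LMEFit:
    """Mixed-model association between the two gaps on joined rows.

    ``brain_gaps`` / ``puberty_gaps`` are gap tables joined 1:1 on
    ``participant_id``; ``cohort`` supplies site (and optional covariates).
    Rows missing any model variable are dropped (listwise).  With fewer than
    3 sites, or a singular site variance, the model falls back to OLS with a
    logged warning.
    """
    covariates = list(covariates or [])
    df = (brain_gaps[["participant_id", "gap", "chronological_age"]]
          .rename(columns={"gap": "brain_gap", "chronological_age": "age"})
          .merge(puberty_gaps[["participant_id", "gap"]]
                 .rename(columns={"gap": "puberty_gap"}), on="participant_id")
          .merge(cohort[["participant_id", "site_id"] + covariates]
                 .drop_duplicates("participant_id"), on="participant_id"))
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n0:
        log.info("association: %d row(s) dropped listwise", n0 - len(df))
    terms = ["puberty_gap", "age"] + covariates
    formula = "brain_gap ~ " + " + ".join(terms)
    n_sites = df["site_id"].nunique()

    if n_sites >= 3:
        import warnings
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                res = smf.mixedlm(formula, df, groups=df["site_id"]).fit(reml=False)
            site_var = float(res.cov_re.iloc[0, 0])
            if res.converged and np.isfinite(res.bse[terms]).all():
                est, aic = _extract_fit(res, terms)
                return LMEFit(outcome_name="brain_gap", term_estimates=est,
                              aic=aic, site_variance=site_var, n_used=len(df),
                              method="mixed")
            log.warning("association: singular/non-converged mixed fit; "
                        "falling back to OLS")
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("association: mixed fit failed (%s); falling back to OLS",
                        exc)
    else:
        log.warning("association: %d site(s) < 3; falling back to OLS", n_sites)

    res = smf.ols(formula, df).fit()
    est, aic = _extract_fit(res, terms)
    return LMEFit(outcome_name="brain_gap", term_estimates=est, aic=aic,
                  site_variance=0.0, n_used=len(df), method="ols")


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def association_report(brain_gaps: pd.DataFrame,
                       puberty_gaps_by_variant: dict,
                       cohort: pd.DataFrame,
                       covariates: list[str] | None = None,
                       q: float = 0.05,
                       sexes=("F", "M")) -> pd.DataFrame:
    """Table of T, FDR-adjusted p, AIC and n: puberty variants x sex.

    Within each sex the three variants are fit on the identical participant
    rows (intersection of rows with all variants' gaps available) so their
    AICs are comparable; BH correction runs across the variants within sex.
    """
    rows = []
    for sex in sexes:
        ids_sex = set(cohort.loc[cohort["sex"] == sex, "participant_id"])
        common = ids_sex & set(brain_gaps["participant_id"])
        for gaps in puberty_gaps_by_variant.values():
            common &= set(gaps.dropna(subset=["gap"])["participant_id"])
        fits = {}
        for variant, gaps in puberty_gaps_by_variant.items():
            fits[variant] = fit_gap_association(
                brain_gaps[brain_gaps["participant_id"].isin(common)],
                gaps[gaps["participant_id"].isin(common)],
                cohort, covariates=covariates)
        p_adj, flags = fdr_adjust(
            [f.term("puberty_gap").p_value for f in fits.values()], q=q)
        for (variant, f), pa, sig in zip(fits.items(), p_adj, flags):
            t = f.term("puberty_gap")
            rows.append({
                "sex": sex, "variant": variant,
                "coefficient": t.coefficient, "T": t.t_statistic,
                "p": t.p_value, "p_fdr": pa, "significant": bool(sig),
                "AIC": f.aic, "n": f.n_used, "method": f.method,
            })
    return pd.DataFrame(rows)
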