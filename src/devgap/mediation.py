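"""Bootstrap mediation of pubertal timing onto mental health via brain age.

Tests whether the baseline brain-age gap mediates the effect of the baseline
puberty-age gap on follow-up mental-health scores, controlling baseline
scores, with a site random intercept in every path model:

* path A:  mediator ~ exposure + age + (1 | site)
* path B:  outcome ~ exposure + mediator + age + baseline outcome + (1 | site)
* path C:  outcome ~ exposure + baseline outcome + age + (1 | site)

The indirect effect (ACME) is ``a * b``, the direct effect (ADE) is model B's
exposure term, and the total effect is model C's exposure term.  Inference is
by nonparametric bootstrap over participants (percentile intervals; p as the
doubled bootstrap tail, floored at 1/n_boot).  In this linear two-equation
system ACME + ADE = total up to mixed-model numerical tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import fit_random_intercept
from ._utils import derive_seed
from .association import fdr_adjust
from .simulate import CBCL_SCALES

log = logging.getLogger(__name__)


@dataclass
class MediationSpec:
    exposure: str = "puberty_gap"
    mediator: str = "brain_gap"
    outcome_scales: list = field(default_factory=lambda: list(CBCL_SCALES))
    covariates: list = field(default_factory=lambda: ["age"])
    grouping: str = "site_id"
    n_boot: int = 1000
    seed: int = 0
    control_baseline: bool = True

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_boot < 100:
            warnings.warn("n_boot < 100 gives unstable percentile intervals",
                          UserWarning, stacklevel=2)


@dataclass
class EffectEstimate:
    effect: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class MediationResult:
    scale: str
    acme: EffectEstimate
    ade: EffectEstimate
    total: EffectEstimate
    prop_mediated: float
    n_used: int
    degenerate: bool = False


@dataclass
class PathEstimates:
    a: float        # exposure -> mediator
    b: float        # mediator -> outcome (adjusted for exposure)
    c_direct: float  # exposure -> outcome, adjusted for mediator (ADE)
    total: float    # exposure -> outcome without the mediator


def build_mediation_frame(cohort: pd.DataFrame, puberty_gaps: pd.DataFrame,
                          brain_gaps: pd.DataFrame, scales=None) -> pd.DataFrame:
    """One row per participant: baseline exposure/mediator/age/site, baseline
    and follow-up outcome scores."""
    scales = list(scales or CBCL_SCALES)
    base = cohort[cohort["visit"].astype(str) == "baseline"]
    fu = cohort[cohort["visit"].astype(str) == "followup"]
    df = (base[["participant_id", "site_id", "age"] + scales]
          .rename(columns={s: f"{s}_baseline" for s in scales})
          .merge(fu[["participant_id"] + scales], on="participant_id",
                 how="inner")
          .merge(puberty_gaps[["participant_id", "gap"]]
                 .rename(columns={"gap": "puberty_gap"}), on="participant_id")
          .merge(brain_gaps[["participant_id", "gap"]]
                 .rename(columns={"gap": "brain_gap"}), on="participant_id"))
    return df.reset_index(drop=True)


def _design(df, cols):
    return np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float)
                                                 for c in cols])


def _paths_arrays(spec, med, out, exp, age_cov, base_out, groups):
    """Fit the three path models on plain arrays; returns PathEstimates."""
    ones = np.ones_like(exp)
    XA = np.column_stack([ones, exp] + age_cov)
    a = fit_random_intercept(med, XA, groups).params[1]
    cols_b = [ones, exp, med] + age_cov
    cols_c = [ones, exp] + age_cov
    if spec.control_baseline:
        cols_b.append(base_out)
        cols_c.append(base_out)
    b_fit = fit_random_intercept(out, np.column_stack(cols_b), groups)
    c_fit = fit_random_intercept(out, np.column_stack(cols_c), groups)
    return PathEstimates(a=float(a), b=float(b_fit.params[2]),
                         c_direct=float(b_fit.params[1]),
                         total=float(c_fit.params[1]))


def fit_mediation_paths(data: pd.DataFrame, scale: str,
                        spec: MediationSpec) -> PathEstimates:
    """Point estimates of paths A, B, C for one outcome scale."""
    df = _complete_rows(data, scale, spec)
    exp = df[spec.exposure].to_numpy(float)
    med = df[spec.mediator].to_numpy(float)
    out = df[scale].to_numpy(float)
    base_out = df[f"{scale}_baseline"].to_numpy(float)
    age_cov = [df[c].to_numpy(float) for c in spec.covariates]
    groups = df[spec.grouping].to_numpy()
    return _paths_arrays(spec, med, out, exp, age_cov, base_out, groups)


def _complete_rows(data, scale, spec):
    cols = [spec.exposure, spec.mediator, scale, f"{scale}_baseline",
            spec.grouping] + spec.covariates
    n0 = len(data)
    df = data.dropna(subset=[c for c in cols if c in data.columns])
    if len(df) < n0:
        log.info("mediation %s: %d row(s) dropped listwise", scale, n0 - len(df))
    return df.reset_index(drop=True)


def _tail_p(draws: np.ndarray, n_boot: int) -> float:
    lo = float(np.mean(draws <= 0.0))
    hi = float(np.mean(draws >= 0.0))
    return float(min(1.0, max(2.0 * min(lo, hi), 1.0 / n_boot)))


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec,
                        scales=None) -> list[MediationResult]:
    """Per-scale bootstrapped ACME / ADE / total effects.

    Resamples participants with replacement (family duplication is assumed
    already removed upstream); site re-enters every refit as a random
    intercept.
    """
    results = []
    for scale in (scales or spec.outcome_scales):
        df = _complete_rows(data, scale, spec)
        n = len(df)
        out = df[scale].to_numpy(float)
        if n == 0 or np.var(out) == 0.0:
            zero = EffectEstimate(0.0, 0.0, 0.0, 1.0)
            results.append(MediationResult(scale=scale, acme=zero, ade=zero,
                                           total=zero, prop_mediated=np.nan,
                                           n_used=n, degenerate=True))
            log.warning("mediation %s: zero-variance outcome; degenerate result",
                        scale)
            continue
        exp = df[spec.exposure].to_numpy(float)
        med = df[spec.mediator].to_numpy(float)
        base_out = df[f"{scale}_baseline"].to_numpy(float)
        age_cov = np.column_stack([df[c].to_numpy(float)
                                   for c in spec.covariates]) \
            if spec.covariates else np.empty((n, 0))
        groups, _ = pd.factorize(df[spec.grouping])

        rng = np.random.default_rng(derive_seed(spec.seed, f"boot-{scale}"))
        acme_d = np.empty(spec.n_boot)
        ade_d = np.empty(spec.n_boot)
        tot_d = np.empty(spec.n_boot)
        for i in range(spec.n_boot):
            idx = rng.integers(0, n, size=n)
            paths = _paths_arrays(
                spec, med[idx], out[idx], exp[idx],
                [age_cov[idx, j] for j in range(age_cov.shape[1])],
                base_out[idx], groups[idx])
            acme_d[i] = paths.a * paths.b
            ade_d[i] = paths.c_direct
            tot_d[i] = paths.total

        def summarize(d):
            lo, hi = np.percentile(d, [2.5, 97.5])
            return EffectEstimate(effect=float(d.mean()), ci_low=float(lo),
                                  ci_high=float(hi),
                                  p_value=_tail_p(d, spec.n_boot))

        acme, ade, tot = summarize(acme_d), summarize(ade_d), summarize(tot_d)
        prop = acme.effect / tot.effect if tot.effect != 0 else np.nan
        results.append(MediationResult(scale=scale, acme=acme, ade=ade,
                                       total=tot, prop_mediated=float(prop),
                                       n_used=n))
    return results


def mediation_report(results: list[MediationResult],
                     q: float = 0.05) -> pd.DataFrame:
    """Scales x effects table with BH-adjusted p-values across every
    scale-by-effect cell of the table (the within-sex correction scope)."""
    if not results:
        raise ValueError("no mediation results to report")
    rows = []
    for r in results:
        rows.append({
            "scale": r.scale,
            "acme": r.acme.effect, "acme_ci_low": r.acme.ci_low,
            "acme_ci_high": r.acme.ci_high, "acme_p": r.acme.p_value,
            "ade": r.ade.effect, "ade_ci_low": r.ade.ci_low,
            "ade_ci_high": r.ade.ci_high, "ade_p": r.ade.p_value,
            "total": r.total.effect, "total_ci_low": r.total.ci_low,
            "total_ci_high": r.total.ci_high, "total_p": r.total.p_value,
            "prop_mediated": r.prop_mediated, "n": r.n_used,
            "degenerate": r.degenerate,
        })
    table = pd.DataFrame(rows)
    raw = np.concatenate([table["acme_p"], table["ade_p"], table["total_p"]])
    adj, flags = fdr_adjust(raw, q=q)
    m = len(table)
    for i, eff in enumerate(("acme", "ade", "total")):
        table[f"{eff}_p_fdr"] = adj[i * m:(i + 1) * m]
        table[f"{eff}_significant"] = flags[i * m:(i + 1) * m]
    return table
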