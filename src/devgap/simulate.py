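"""Synthetic longitudinal cohort generator with known developmental structure.

Emulates the schema and statistical structure of a two-wave early-adolescent
cohort (ages 9-11 at baseline, two-year follow-up): parent-rated Pubertal
Development Scale items, salivary testosterone and DHEA, Desikan-Killiany
regional morphometry plus subcortical volumes, CBCL-style mental-health
scales, family (sibling) clustering and acquisition-site effects.

The latent model, per participant p:

* pubertal-timing offset  delta_p ~ N(0, timing_sd^2) in years
  (positive = earlier-maturing than same-age peers);
* brain-maturation offset delta_b = coupling_beta * delta_p + noise;
* pubertal features are monotone functions of the effective pubertal age
  q = age + delta_p with sex-specific onset (logistic-threshold ordinal
  items, log-normal hormones);
* brain features follow region-specific linear-plus-quadratic trends
  evaluated at age + w_lobe * delta_b + eta_p, where w_lobe distributes the
  coupling across lobes and eta_p is subject-level maturational noise shared
  across all regions (this bounds attainable brain-age accuracy the way
  correlated morphometric variance does in real data);
* follow-up mental-health scores = autocorrelation * baseline
  + path_b * delta_b + path_c * delta_p + noise.

Identical config and seed produce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .atlas import LOBE_LABELS, RegionLobeMap

# ---------------------------------------------------------------------------
# column sets

FEMALE_PDS_ITEMS = ["pds_growth", "pds_body_hair", "pds_skin", "pds_breast"]
MALE_PDS_ITEMS = ["pds_growth", "pds_body_hair", "pds_skin", "pds_facial_hair", "pds_voice"]
PDS_ITEM_COLUMNS = ["pds_growth", "pds_body_hair", "pds_skin", "pds_breast",
                    "pds_facial_hair", "pds_voice"]
MENARCHE_COLUMN = "menarche"
HORMONE_COLUMNS = ["testosterone", "dhea"]

CBCL_SCALES = [
    "cbcl_total", "cbcl_internalizing", "cbcl_externalizing",
    "cbcl_anxious_depressed", "cbcl_withdrawn_depressed", "cbcl_somatic",
    "cbcl_social", "cbcl_thought", "cbcl_attention",
    "cbcl_rule_breaking", "cbcl_aggressive",
]
# DSM-5-oriented screening scales used only to define the typically-developing
# training population (all scores < 60).
DSM_SCALES = [
    "dsm_depression", "dsm_anxiety", "dsm_somatic", "dsm_adhd",
    "dsm_oppositional", "dsm_conduct", "dsm_ocd", "dsm_sct", "dsm_stress",
]

ID_COLUMNS = ["participant_id", "family_id", "site_id", "sex", "visit", "age"]

_DEFAULT_NOISE = {
    "delta_b": 0.5,       # years, residual SD of delta_b given delta_p
    "maturation": 0.9,    # years, shared subject-level brain maturational noise
    "pds": 0.15,          # on the (0,1) latent maturity scale
    "hormone": 0.45,      # log-scale per-assay noise
    "hormone_shared": 0.4,  # log-scale per-person assay-day factor (both hormones)
    "brain": 1.0,         # multiplier on per-feature residual SDs
    "site": 0.3,          # years, SD of site intercepts (scanner analogy)
    "cbcl": 6.0,          # T-score points, follow-up residual
}

# PDS item logistic thresholds on the (0,1) latent maturity scale; chosen so
# the 9-13 year range spans item means of roughly 1.5-3 (early-pubertal).
_PDS_THRESHOLDS = {
    "pds_growth": (0.25, 0.50, 0.75),
    "pds_body_hair": (0.30, 0.55, 0.80),
    "pds_skin": (0.20, 0.45, 0.70),
    "pds_breast": (0.30, 0.55, 0.80),
    "pds_facial_hair": (0.45, 0.65, 0.85),
    "pds_voice": (0.40, 0.60, 0.80),
}
_PDS_ONSET = {"F": 11.0, "M": 12.0}   # years, logistic midpoint of maturity
_PDS_WIDTH = 1.5                      # years, logistic scale

# ln(pg/mL) intercept at effective age 9 and slope per effective year
_HORMONE_PARAMS = {
    ("testosterone", "F"): (3.0, 0.32),
    ("testosterone", "M"): (2.9, 0.45),
    ("dhea", "F"): (3.7, 0.28),
    ("dhea", "M"): (3.6, 0.30),
}

_MENARCHE_MIDPOINT = 12.8  # years
_MENARCHE_WIDTH = 0.5


@dataclass
class SimulationConfig:
    """Generator settings; defaults describe the reference study conditions."""

    n_participants: int = 2000
    sibling_rate: float = 0.3
    n_sites: int = 20
    age_range_baseline: tuple = (9.0, 11.0)
    followup_lag: float = 2.0
    sex_ratio: float = 0.48          # proportion female
    timing_sd: float = 1.0           # SD of delta_p, years
    coupling_beta: float = 0.3       # delta_p -> delta_b, years per year
    path_a: float | None = None      # alias of coupling_beta (kept for symmetry)
    path_b: float = 1.0              # delta_b -> follow-up symptoms, pts/year
    path_c: float = 1.5              # delta_p -> follow-up symptoms (direct)
    mh_autocorrelation: float = 0.6
    lobe_coupling_weights: dict = field(
        default_factory=lambda: {lobe: 1.0 for lobe in LOBE_LABELS})
    noise_sds: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        for name in ("sibling_rate", "sex_ratio", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        if self.timing_sd < 0:
            raise ValueError("timing_sd must be nonnegative")
        lo, hi = self.age_range_baseline
        if not lo < hi:
            raise ValueError("age_range_baseline must be an increasing interval")
        if self.followup_lag <= 0:
            raise ValueError("followup_lag must be positive")
        for lobe, w in self.lobe_coupling_weights.items():
            if w < 0:
                raise ValueError(f"lobe weight for {lobe!r} must be nonnegative")
        merged = dict(_DEFAULT_NOISE)
        merged.update(self.noise_sds)
        bad = [k for k, v in merged.items() if v < 0]
        if bad:
            raise ValueError(f"negative noise SDs: {bad}")
        self.noise_sds = merged

    @property
    def effective_path_a(self) -> float:
        return self.coupling_beta if self.path_a is None else self.path_a


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def pds_latent_maturity(effective_age, sex: str):
    """Deterministic latent maturity in (0,1) at effective pubertal age."""
    return _sigmoid((np.asarray(effective_age, float) - _PDS_ONSET[sex]) / _PDS_WIDTH)


def log_hormone_mean(hormone: str, effective_age, sex: str):
    """Deterministic mean ln concentration (pg/mL) at effective pubertal age."""
    a, b = _HORMONE_PARAMS[(hormone, sex)]
    return a + b * (np.asarray(effective_age, float) - 9.0)


def _ordinalize(latent, thresholds):
    """Map a latent maturity value through fixed thresholds to an ordinal 1-4."""
    out = np.ones_like(latent, dtype=float)
    for t in thresholds:
        out += (latent > t).astype(float)
    return out


@lru_cache(maxsize=4)
def _brain_trend_table(feature_key: tuple) -> pd.DataFrame:
    """Per-feature (mean, slope/yr, quad/yr^2, residual SD), deterministic.

    Magnitudes loosely follow adolescent grey-matter norms: thickness ~2.5 mm
    thinning ~0.02-0.04 mm/yr; cortical volumes/areas declining well under
    2 %/yr; subcortical volumes given a clear maturational trend so that a
    subcortex-only age model is identifiable from 14 features.
    """
    rng = np.random.default_rng(20230309)  # fixed: schema, not simulation, RNG
    rows = []
    canonical_subcortex = {
        "thalamus": 7500.0, "caudate": 3800.0, "putamen": 5200.0,
        "pallidum": 1800.0, "hippocampus": 4200.0, "amygdala": 1700.0,
        "accumbens": 600.0,
    }
    for col in feature_key:
        hemi, rest = col.split("_", 1)
        name, metric = rest.rsplit("_", 1)
        if name in canonical_subcortex:
            mean = canonical_subcortex[name] * (1.0 + 0.05 * rng.standard_normal())
            slope = -0.015 * mean * (0.8 + 0.4 * rng.random())
            quad = -0.001 * mean * rng.random()
            sd = 0.05 * mean
        elif metric == "thickness":
            mean = float(np.clip(2.5 + 0.25 * rng.standard_normal(), 1.8, 3.2))
            slope = -(0.02 + 0.02 * rng.random())
            quad = -0.002 * rng.random()
            sd = 0.12
        elif metric == "volume":
            mean = float(np.clip(np.exp(np.log(8000.0) + 0.5 * rng.standard_normal()),
                                 1500.0, 25000.0))
            slope = -0.012 * mean * (0.5 + rng.random())
            quad = -0.0005 * mean * rng.random()
            sd = 0.08 * mean
        else:  # area
            mean = float(np.exp(np.log(2500.0) + 0.45 * rng.standard_normal()))
            slope = -0.004 * mean * (0.5 + rng.random())
            quad = -0.0002 * mean * rng.random()
            sd = 0.07 * mean
        rows.append((col, mean, slope, quad, sd))
    return pd.DataFrame(rows, columns=["feature", "mean", "slope", "quad", "sd"]
                        ).set_index("feature")


def generate_cohort(config: SimulationConfig,
                    lobe_map: RegionLobeMap | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-wave cohort; returns (cohort, truth) data frames.

    The cohort table has one row per participant-visit; the truth table has
    one row per participant with the latent offsets and the path coefficients
    actually used, for recovery tests.
    """
    lobe_map = lobe_map or RegionLobeMap.default()
    known_lobes = set(lobe_map.lobes())
    unknown = set(config.lobe_coupling_weights) - known_lobes
    if unknown:
        raise ValueError(f"lobe_coupling_weights has labels absent from the "
                         f"region-lobe map: {sorted(unknown)}")

    n = config.n_participants
    ns = config.noise_sds
    rng = np.random.default_rng(config.seed)

    # --- family / site / demographic structure -----------------------------
    n_pairs = int(round(config.sibling_rate * n / 2.0))
    family_idx = np.empty(n, dtype=int)
    family_idx[:2 * n_pairs] = np.repeat(np.arange(n_pairs), 2)
    family_idx[2 * n_pairs:] = n_pairs + np.arange(n - 2 * n_pairs)
    n_families = n_pairs + (n - 2 * n_pairs)
    family_site = rng.integers(0, config.n_sites, size=n_families)
    site_idx = family_site[family_idx]

    participant_id = np.array([f"P{i:05d}" for i in range(n)])
    family_id = np.array([f"F{i:05d}" for i in family_idx])
    site_id = np.array([f"S{i:02d}" for i in site_idx])
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")

    lo, hi = config.age_range_baseline
    age_base = rng.uniform(lo, hi, size=n)
    age_fu = age_base + config.followup_lag

    # --- latent offsets -----------------------------------------------------
    path_a = config.effective_path_a
    delta_p = config.timing_sd * rng.standard_normal(n)
    delta_b = path_a * delta_p + ns["delta_b"] * rng.standard_normal(n)
    eta = ns["maturation"] * rng.standard_normal(n)          # brain-wide
    hshared = ns["hormone_shared"] * rng.standard_normal(n)  # assay-day factor
    menarche_u = rng.random(n)                               # one draw: monotone in q

    feature_cols = lobe_map.feature_columns()
    trends = _brain_trend_table(tuple(feature_cols))
    weights = np.array([config.lobe_coupling_weights.get(lobe_map.lobe_of(c), 0.0)
                        for c in feature_cols])
    site_shift = ns["site"] * rng.standard_normal(config.n_sites)  # years

    # CBCL latent structure: a common problem factor g plus scale-specific parts
    g = rng.standard_normal(n)
    base_scores = {}
    for scale in CBCL_SCALES + DSM_SCALES:
        base_scores[scale] = 50.0 + 8.0 * (0.75 * g + 0.66 * rng.standard_normal(n))

    def visit_block(visit: str, age: np.ndarray) -> pd.DataFrame:
        data = {
            "participant_id": participant_id, "family_id": family_id,
            "site_id": site_id, "sex": sex, "visit": visit, "age": age,
        }
        q = age + delta_p  # effective pubertal age

        # PDS ordinal items (sex-specific item sets) + menarche for females
        for item in PDS_ITEM_COLUMNS:
            vals = np.full(n, np.nan)
            for s, items in (("F", FEMALE_PDS_ITEMS), ("M", MALE_PDS_ITEMS)):
                if item not in items:
                    continue
                mask = sex == s
                latent = (pds_latent_maturity(q[mask], s)
                          + ns["pds"] * rng.standard_normal(mask.sum()))
                vals[mask] = _ordinalize(latent, _PDS_THRESHOLDS[item])
            data[item] = vals
        men = np.full(n, np.nan)
        fem = sex == "F"
        p_men = _sigmoid((q[fem] - _MENARCHE_MIDPOINT) / _MENARCHE_WIDTH)
        men[fem] = (p_men > menarche_u[fem]).astype(float)
        data[MENARCHE_COLUMN] = men

        # hormones, log-normal with shared assay-day factor
        for hormone in HORMONE_COLUMNS:
            ln = np.full(n, np.nan)
            for s in ("F", "M"):
                mask = sex == s
                ln[mask] = log_hormone_mean(hormone, q[mask], s)
            ln += hshared + ns["hormone"] * rng.standard_normal(n)
            data[hormone] = np.exp(ln)

        # brain morphometry: trends evaluated at the effective brain age
        c = (age + eta)[:, None] + np.outer(delta_b, weights) - 11.0
        vals = (trends["mean"].to_numpy()[None, :]
                + trends["slope"].to_numpy()[None, :] * c
                + trends["quad"].to_numpy()[None, :] * c ** 2
                + trends["slope"].to_numpy()[None, :] * site_shift[site_idx][:, None]
                + ns["brain"] * trends["sd"].to_numpy()[None, :]
                * rng.standard_normal((n, len(feature_cols))))
        for j, col in enumerate(feature_cols):
            data[col] = vals[:, j]

        # mental health: baseline scores, then AR(1) + developmental paths
        if visit == "baseline":
            for scale in CBCL_SCALES + DSM_SCALES:
                data[scale] = base_scores[scale]
        else:
            rho = config.mh_autocorrelation
            shift = config.path_b * delta_b + config.path_c * delta_p
            for scale in CBCL_SCALES:
                data[scale] = (50.0 + rho * (base_scores[scale] - 50.0) + shift
                               + ns["cbcl"] * rng.standard_normal(n))
            for scale in DSM_SCALES:
                data[scale] = (50.0 + rho * (base_scores[scale] - 50.0)
                               + ns["cbcl"] * rng.standard_normal(n))
        return pd.DataFrame(data)

    cohort = pd.concat([visit_block("baseline", age_base),
                        visit_block("followup", age_fu)], ignore_index=True)
    cohort["visit"] = pd.Categorical(cohort["visit"], categories=["baseline", "followup"],
                                     ordered=True)
    cohort = (cohort.sort_values(["participant_id", "visit"])
              .reset_index(drop=True))

    truth = pd.DataFrame({
        "participant_id": participant_id,
        "delta_p": delta_p,
        "delta_b": delta_b,
        "path_a": path_a,
        "path_b": config.path_b,
        "path_c": config.path_c,
    })

    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate,
                                    seed=derive_seed(config.seed, "missingness"))
    return cohort, truth


def missingness_eligible_columns(cohort: pd.DataFrame) -> list[str]:
    """Hormone, PDS and brain measurement columns (never demographics)."""
    brain = [c for c in cohort.columns
             if c.startswith(("lh_", "rh_"))]
    pds = [c for c in PDS_ITEM_COLUMNS + [MENARCHE_COLUMN] if c in cohort.columns]
    horm = [c for c in HORMONE_COLUMNS if c in cohort.columns]
    return horm + pds + brain


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mark a proportion of measurement cells missing, completely at random.

    Cells that are structurally absent (e.g. male menarche) stay untouched and
    do not count toward the eligible pool.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = missingness_eligible_columns(out)
    block = out[cols].to_numpy(float)
    eligible = ~np.isnan(block)
    drop = eligible & (rng.random(block.shape) < rate)
    block[drop] = np.nan
    out[cols] = block
    return out


def null_config(**overrides) -> SimulationConfig:
    """Config with all developmental couplings switched off (for calibration)."""
    base = dict(coupling_beta=0.0, path_b=0.0, path_c=0.0)
    base.update(overrides)
    return SimulationConfig(**base)
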