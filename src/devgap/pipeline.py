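"""End-to-end orchestration: simulate -> age models -> gaps -> association
-> contribution -> mediation, from one config with one global seed.

Every stage consumes and produces delimited-text files, so stages can be
rerun independently; a manifest records stage seeds, sample counts after each
filter, accuracy metrics and output checksums.  Rerunning with an identical
config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .age import (AgeModelConfig, model_accuracy, nested_cv_fit,
                  select_single_timepoint, select_typically_developing)
from .association import association_report, select_one_per_family
from .atlas import RegionLobeMap
from .contribution import leave_one_lobe_out_scan, leave_one_region_out_scan, records_frame
from .io import read_cohort, write_table
from .mediation import (MediationSpec, bootstrap_mediation,
                        build_mediation_frame, mediation_report)
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger(__name__)

VARIANT_FEATURE_SETS = {"physical": "pds_physical", "hormonal": "hormonal",
                        "combined": "combined"}

# compact grids that keep the demo pipeline quick; the estimator-level
# defaults in age.py carry the full grids
DEMO_KERNEL_GRID = {"C": [1.0, 10.0], "gamma_scale": [1.0], "epsilon": [0.1]}
DEMO_SPLINE_GRID = {"alpha": [0.1, 1.0, 10.0]}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_path: str | None = None       # external cohort instead of simulating
    brain_model: AgeModelConfig = field(default_factory=lambda: AgeModelConfig(
        feature_set="brain", estimator="kernel_pca", outer_folds=5,
        inner_folds=3, hyper_grid=DEMO_KERNEL_GRID))
    puberty_model: AgeModelConfig = field(default_factory=lambda: AgeModelConfig(
        feature_set="pds_physical", estimator="additive_spline", outer_folds=5,
        inner_folds=3, hyper_grid=DEMO_SPLINE_GRID, sex_stratified=True))
    puberty_variants: tuple = ("physical", "combined", "hormonal")
    covariates: list | None = None
    fdr_q: float = 0.05
    contribution_level: str | None = "lobe"   # "lobe", "region", "feature", None
    lobe_map_path: str | None = None
    mediation_exposure_variant: str = "physical"
    n_boot: int = 1000
    control_baseline: bool = True
    output_dir: str = "devgap-run"
    global_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw.pop("simulation"))
        for key in ("brain_model", "puberty_model"):
            if key in raw:
                kwargs[key] = AgeModelConfig(**raw.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.global_seed
    manifest: dict = {"version": __version__, "global_seed": seed,
                      "stage_seeds": {}, "counts": {}, "accuracy": {},
                      "outputs": {}}

    def stage_seed(name: str) -> int:
        s = derive_seed(seed, name)
        manifest["stage_seeds"][name] = s
        return s

    def emit(df: pd.DataFrame, name: str):
        path = write_table(df, out / name)
        manifest["outputs"][name] = _sha256(path)

    # --- stage 1: cohort ---------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        truth = None
        log.info("pipeline: loaded cohort from %s (%d rows)",
                 config.cohort_path, len(cohort))
    else:
        sim = dataclasses.replace(config.simulation, seed=stage_seed("simulate"))
        cohort, truth = generate_cohort(sim)
        emit(cohort, "cohort.csv")
        emit(truth, "truth.csv")
        log.info("pipeline: simulated %d participants", sim.n_participants)
    manifest["counts"]["cohort_rows"] = int(len(cohort))

    lobe_map = (RegionLobeMap.from_json(config.lobe_map_path)
                if config.lobe_map_path else RegionLobeMap.default())

    # --- stage 2: model population ----------------------------------------
    single = select_single_timepoint(cohort, seed=stage_seed("timepoint"))
    td = select_typically_developing(single)
    manifest["counts"]["single_timepoint"] = int(len(single))
    manifest["counts"]["typically_developing"] = int(len(td))
    log.info("pipeline: %d single-timepoint rows, %d typically developing",
             len(single), len(td))

    baseline = cohort[cohort["visit"].astype(str) == "baseline"]

    # --- stage 3: brain age ------------------------------------------------
    bcfg = dataclasses.replace(config.brain_model, seed=stage_seed("brain-cv"))
    brain_model, brain_oof = nested_cv_fit(td, bcfg)
    r, mae = model_accuracy(brain_oof)
    manifest["accuracy"]["brain"] = {"r": r, "mae_months": mae}
    brain_gaps = brain_model.gap_table(baseline)
    emit(brain_gaps, "brain_gaps.csv")
    log.info("pipeline: brain age r=%.3f MAE=%.1f months", r, mae)

    # --- stage 4: puberty age (three variants, per sex) --------------------
    puberty_gaps: dict[str, pd.DataFrame] = {}
    for variant in config.puberty_variants:
        feature_set = VARIANT_FEATURE_SETS[variant]
        per_sex = []
        for sex in ("F", "M"):
            pcfg = dataclasses.replace(
                config.puberty_model, feature_set=feature_set,
                seed=stage_seed(f"puberty-{variant}-{sex}-cv"))
            model, oof = nested_cv_fit(td[td["sex"] == sex], pcfg, sex=sex)
            r, mae = model_accuracy(oof)
            manifest["accuracy"][f"puberty_{variant}_{sex}"] = {
                "r": r, "mae_months": mae}
            per_sex.append(model.gap_table(baseline[baseline["sex"] == sex]))
        puberty_gaps[variant] = pd.concat(per_sex, ignore_index=True)
        emit(puberty_gaps[variant], f"puberty_gaps_{variant}.csv")

    # --- stage 5: association ---------------------------------------------
    analysis = select_one_per_family(baseline, seed=stage_seed("family"))
    manifest["counts"]["one_per_family"] = int(len(analysis))
    assoc = association_report(
        brain_gaps, {VARIANT_FEATURE_SETS[v]: puberty_gaps[v]
                     for v in config.puberty_variants},
        analysis, covariates=config.covariates, q=config.fdr_q)
    emit(assoc, "association.csv")

    # --- stage 6: contribution --------------------------------------------
    if config.contribution_level:
        ccfg = dataclasses.replace(config.brain_model,
                                   seed=stage_seed("contribution-cv"))
        exp_variant = config.mediation_exposure_variant
        for sex in ("F", "M"):
            rows_sex = analysis[analysis["sex"] == sex]
            pg = puberty_gaps[exp_variant]
            if config.contribution_level == "lobe":
                recs = leave_one_lobe_out_scan(td, rows_sex, pg,
                                               lobe_map=lobe_map, config=ccfg,
                                               covariates=config.covariates)
            else:
                recs = leave_one_region_out_scan(
                    td, rows_sex, pg, config=ccfg,
                    granularity=("region" if config.contribution_level == "region"
                                 else "feature"),
                    lobe_map=lobe_map, covariates=config.covariates)
            emit(records_frame(recs), f"contribution_{sex}.csv")

    # --- stage 7: mediation ------------------------------------------------
    exp_gaps = puberty_gaps[config.mediation_exposure_variant]
    for sex in ("F", "M"):
        frame = build_mediation_frame(
            cohort[cohort["participant_id"].isin(analysis["participant_id"])
                   & (cohort["sex"] == sex)],
            exp_gaps, brain_gaps)
        spec = MediationSpec(n_boot=config.n_boot,
                             control_baseline=config.control_baseline,
                             seed=stage_seed(f"mediation-{sex}"))
        results = bootstrap_mediation(frame, spec)
        report = mediation_report(results, q=config.fdr_q)
        emit(report, f"mediation_{sex}.csv")
        manifest["counts"][f"mediation_{sex}_n"] = int(len(frame))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
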