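"""Delimited-text I/O with data-dictionary sidecars and schema validation.

All tables are plain comma-separated text with a header row; each write adds
a ``<name>.dict.json`` sidecar describing the columns, so real cohort exports
with the same schema can be swapped in for the simulator's output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (CBCL_SCALES, DSM_SCALES, HORMONE_COLUMNS, ID_COLUMNS,
                       MENARCHE_COLUMN, PDS_ITEM_COLUMNS)

_FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    pass


def _column_description(col: str) -> str:
    if col in ID_COLUMNS:
        return {"participant_id": "opaque participant identifier",
                "family_id": "opaque family identifier (siblings share it)",
                "site_id": "acquisition site identifier",
                "sex": "F or M",
                "visit": "baseline or followup",
                "age": "age at visit, years"}[col]
    if col in PDS_ITEM_COLUMNS:
        return "Pubertal Development Scale item, ordinal 1-4 (sex-specific)"
    if col == MENARCHE_COLUMN:
        return "menarche indicator, females only (0/1)"
    if col in HORMONE_COLUMNS:
        return "salivary hormone concentration, pg/mL"
    if col in CBCL_SCALES:
        return "mental-health problem scale, T-score-like"
    if col in DSM_SCALES:
        return "clinical screening scale used for the typically-developing filter"
    if col.startswith(("lh_", "rh_")):
        return "regional brain feature (volume mm^3 / thickness mm / area mm^2)"
    return "column"


def write_table(df: pd.DataFrame, path) -> Path:
    """CSV + data-dictionary JSON sidecar; deterministic byte output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    dictionary = {
        "n_rows": int(len(df)),
        "columns": [{"name": c, "dtype": str(df[c].dtype),
                     "description": _column_description(c)}
                    for c in df.columns],
    }
    with open(path.with_suffix(path.suffix + ".dict.json"), "w") as fh:
        json.dump(dictionary, fh, indent=1)
    return path


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    return write_table(cohort, path)


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Schema-validated load of a cohort table with typed columns."""
    df = pd.read_csv(path, dtype={c: str for c in
                                  ("participant_id", "family_id", "site_id",
                                   "sex", "visit")})
    if validate:
        validate_cohort(df, source=str(path))
    if "visit" in df.columns:
        df["visit"] = pd.Categorical(df["visit"],
                                     categories=["baseline", "followup"],
                                     ordered=True)
    return df


def validate_cohort(df: pd.DataFrame, source: str = "<frame>") -> None:
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {missing}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        lines = (df.index[bad_sex] + 2).tolist()[:5]
        raise SchemaError(f"{source}: invalid sex values at line(s) {lines}")
    bad_visit = ~df["visit"].isin(["baseline", "followup"])
    if bad_visit.any():
        lines = (df.index[bad_visit] + 2).tolist()[:5]
        raise SchemaError(f"{source}: invalid visit labels at line(s) {lines}")
    if not np.issubdtype(df["age"].dtype, np.number):
        raise SchemaError(f"{source}: age column is not numeric")
    for col in PDS_ITEM_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin([1.0, 2.0, 3.0, 4.0])
        if bad.any():
            lines = (vals.index[bad] + 2).tolist()[:5]
            raise SchemaError(f"{source}: {col} outside ordinal range 1-4 "
                              f"at line(s) {lines}")
    for col in HORMONE_COLUMNS:
        if col in df.columns and (df[col].dropna() <= 0).any():
            raise SchemaError(f"{source}: nonpositive {col} values")
    # ages strictly increase across visits within participant
    wide = (df.pivot_table(index="participant_id", columns="visit",
                           values="age", aggfunc="first", observed=False))
    if {"baseline", "followup"}.issubset(wide.columns):
        both = wide.dropna()
        if (both["followup"] <= both["baseline"]).any():
            raise SchemaError(f"{source}: follow-up ages not strictly greater "
                              "than baseline for some participants")
    dup = df.duplicated(subset=["participant_id", "visit"])
    if dup.any():
        raise SchemaError(f"{source}: duplicate (participant, visit) rows")


def save_model_bundle(model, directory) -> Path:
    """Serialized fitted age model plus a JSON metadata sidecar
    (hyperparameters, fold map, RTM coefficients)."""
    import joblib

    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, directory / "model.joblib")
    meta = {
        "format_version": 1,
        "package_version": __version__,
        "feature_names": list(model.feature_names_),
        "estimator": model.estimator,
        "rtm_slope": model.rtm_slope_,
        "rtm_intercept": model.rtm_intercept_,
        "final_params": model.final_params_,
        "fold_of_family": {str(k): int(v) for k, v in
                           model.cv_metadata_["fold_of_family"].items()},
        "fold_params": model.cv_metadata_["fold_params"],
        "n_training_participants": len(model.training_participants_),
    }
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def load_model_bundle(directory):
    import joblib
    return joblib.load(Path(directory) / "model.joblib")


def write_gap_table(gaps: pd.DataFrame, path) -> Path:
    return write_table(gaps, path)


def read_gap_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "visit": str})
    needed = {"participant_id", "gap"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing gap-table column(s): {sorted(missing)}")
    return df
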