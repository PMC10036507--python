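"""Shared fixtures: small synthetic cohorts and fast model configurations.

Model configurations used in tests shrink the cross-validation design and
hyperparameter grids (the statistical machinery is identical; only the search
is smaller) so the whole suite stays fast.
"""

import warnings

import pandas as pd
import pytest

from devgap.age import (AgeModelConfig, select_single_timepoint,
                        select_typically_developing)
from devgap.simulate import SimulationConfig, generate_cohort

FAST_KERNEL_GRID = {"C": [1.0, 10.0], "gamma_scale": [1.0], "epsilon": [0.1]}
FAST_SPLINE_GRID = {"alpha": [0.1, 1.0, 10.0]}


def fast_brain_config(seed=0, **kw) -> AgeModelConfig:
    kw.setdefault("feature_set", "brain")
    kw.setdefault("estimator", "kernel_pca")
    kw.setdefault("outer_folds", 5)
    kw.setdefault("inner_folds", 2)
    kw.setdefault("hyper_grid", FAST_KERNEL_GRID)
    return AgeModelConfig(seed=seed, **kw)


def fast_puberty_config(seed=0, **kw) -> AgeModelConfig:
    kw.setdefault("feature_set", "pds_physical")
    kw.setdefault("estimator", "additive_spline")
    kw.setdefault("outer_folds", 5)
    kw.setdefault("inner_folds", 2)
    kw.setdefault("hyper_grid", FAST_SPLINE_GRID)
    kw.setdefault("sex_stratified", True)
    return AgeModelConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def cohort_and_truth():
    cohort, truth = generate_cohort(SimulationConfig(n_participants=600, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def cohort(cohort_and_truth):
    return cohort_and_truth[0]


@pytest.fixture(scope="session")
def truth(cohort_and_truth):
    return cohort_and_truth[1]


@pytest.fixture(scope="session")
def td_single(cohort) -> pd.DataFrame:
    """Typically-developing, single-timepoint training population."""
    return select_typically_developing(select_single_timepoint(cohort, seed=7))


@pytest.fixture(scope="session")
def baseline(cohort) -> pd.DataFrame:
    return cohort[cohort["visit"].astype(str) == "baseline"].reset_index(drop=True)


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*convergence.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="statsmodels")
        yield
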