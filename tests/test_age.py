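"""Normative age engine: cohort filters, nested CV, RTM adjustment, gaps."""

import numpy as np
import pandas as pd
import pytest

from devgap._utils import pearson_r
from devgap.age import (fit_rtm_correction, model_accuracy,
                        nested_cv_fit, select_single_timepoint,
                        select_typically_developing, feature_columns_for)
from devgap.simulate import DSM_SCALES

from conftest import fast_brain_config, fast_puberty_config


# ---------------------------------------------------------------------------
# timepoint selection

class TestSelectSingleTimepoint:
    def test_one_row_per_participant_from_own_visits(self, cohort):
        out = select_single_timepoint(cohort, seed=3)
        assert len(out) == cohort["participant_id"].nunique()
        assert out["participant_id"].is_unique

    def test_single_visit_participant_keeps_that_visit(self, cohort):
        solo = cohort[cohort.visit == "followup"].head(5)
        out = select_single_timepoint(solo, seed=1)
        pd.testing.assert_frame_equal(out, solo.reset_index(drop=True))

    def test_choice_is_uniform_over_visits(self):
        rows = pd.DataFrame({
            "participant_id": np.repeat([f"P{i}" for i in range(1000)], 2),
            "visit": ["baseline", "followup"] * 1000,
        })
        out = select_single_timepoint(rows, seed=5)
        n_base = (out.visit == "baseline").sum()
        assert abs(n_base - 500) < 4 * np.sqrt(1000 * 0.25)

    def test_reproducible(self, cohort):
        a = select_single_timepoint(cohort, seed=11)
        b = select_single_timepoint(cohort, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_in_empty_out(self, cohort):
        assert select_single_timepoint(cohort.iloc[:0], seed=0).empty


class TestSelectTypicallyDeveloping:
    @staticmethod
    def _mini(scores):
        n = len(scores)
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "visit": "baseline",
        })
        for s in DSM_SCALES:
            df[s] = 40.0
        df[DSM_SCALES[0]] = scores
        return df

    def test_score_just_below_threshold_retained(self):
        out = select_typically_developing(self._mini([59.0]))
        assert len(out) == 1

    def test_any_score_at_or_above_threshold_excluded(self):
        out = select_typically_developing(self._mini([61.0, 60.0, 40.0]))
        assert list(out.participant_id) == ["P2"]

    def test_missing_scale_value_excludes_participant(self):
        out = select_typically_developing(self._mini([np.nan, 45.0]))
        assert list(out.participant_id) == ["P1"]

    def test_empty_cohort(self, cohort):
        assert select_typically_developing(cohort.iloc[:0]).empty

    def test_all_visits_of_retained_participant_kept(self, cohort):
        out = select_typically_developing(cohort)
        counts = out.groupby("participant_id").size()
        assert (counts == 2).all()


# ---------------------------------------------------------------------------
# RTM correction

class TestRTMCorrection:
    def test_three_point_closed_form(self):
        # ages (9,10,11), raw gaps (1,0,-1): OLS slope -1, intercept 10
        slope, intercept = fit_rtm_correction([9, 10, 11], [10.0, 10.0, 10.0])
        assert slope == pytest.approx(-1.0)
        assert intercept == pytest.approx(10.0)

    def test_unbiased_predictor_has_null_coefficients(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(9, 13, 2000)
        raw = ages + rng.normal(0, 1, 2000)
        slope, intercept = fit_rtm_correction(ages, raw)
        assert abs(slope) < 0.05
        assert abs(intercept) < 0.6

    def test_constant_gap_shift_moves_only_intercept(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(9, 13, 50)
        raw = ages + rng.normal(0, 1, 50)
        s0, i0 = fit_rtm_correction(ages, raw)
        s1, i1 = fit_rtm_correction(ages, raw + 0.7)
        assert s1 == pytest.approx(s0)
        assert i1 == pytest.approx(i0 + 0.7)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_rtm_correction([9, 10], [9.5, 10.5])
        with pytest.raises(ValueError):
            fit_rtm_correction([10, 10, 10], [9.5, 10.5, 11.0])


# ---------------------------------------------------------------------------
# nested CV fit

@pytest.fixture(scope="module")
def brain_fit(td_single):
    model, oof_gaps = nested_cv_fit(td_single, fast_brain_config(seed=5))
    return model, oof_gaps


class TestNestedCV:
    def test_families_never_straddle_folds(self, brain_fit, td_single):
        model, _ = brain_fit
        fold_of = model.cv_metadata_["fold_of_family"]
        folds_per_family = (model.oof_
                            .assign(family=td_single.set_index("participant_id")
                                    .loc[model.oof_.participant_id, "family_id"]
                                    .to_numpy())
                            .groupby("family")["fold"].nunique())
        assert (folds_per_family == 1).all()
        assert all(fold_of[f] == folds_per_family.index.map(fold_of)[i]
                   for i, f in enumerate(folds_per_family.index))

    def test_outer_test_sets_partition_training_population(self, brain_fit,
                                                           td_single):
        model, _ = brain_fit
        assert model.oof_["predicted_age_raw"].notna().all()
        assert set(model.oof_.participant_id) == set(td_single.participant_id)
        assert model.oof_.participant_id.is_unique
        assert set(model.oof_.fold) == set(range(5))

    def test_oof_gap_table_matches_rtm_identity(self, brain_fit):
        _, gaps = brain_fit
        np.testing.assert_allclose(
            gaps["gap"],
            gaps["predicted_age_adjusted"] - gaps["chronological_age"])

    def test_rtm_orthogonalizes_gap_and_age_in_training(self, brain_fit):
        _, gaps = brain_fit
        assert abs(pearson_r(gaps["gap"], gaps["chronological_age"])) < 1e-8

    def test_adjustment_preserves_order_at_fixed_age(self, brain_fit, cohort):
        """The RTM adjustment depends on age only, so it cannot reorder
        predictions among rows with identical age."""
        model, _ = brain_fit
        rows = cohort[cohort.visit == "baseline"].head(8).copy()
        rows["age"] = 10.0
        g = model.gap_table(rows)
        raw_order = np.argsort(g["predicted_age_raw"].to_numpy())
        adj_order = np.argsort(g["predicted_age_adjusted"].to_numpy())
        np.testing.assert_array_equal(raw_order, adj_order)

    def test_fewer_families_than_folds_rejected(self, td_single):
        tiny = td_single[td_single.family_id.isin(
            td_single.family_id.unique()[:4])]
        with pytest.raises(ValueError, match="famil"):
            nested_cv_fit(tiny, fast_brain_config(outer_folds=10))

    def test_nonfinite_features_rejected(self, td_single):
        bad = td_single.copy()
        bad.loc[bad.index[0], "lh_insula_volume"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            nested_cv_fit(bad, fast_brain_config())

    def test_missing_feature_columns_named_in_error(self, brain_fit, cohort):
        model, _ = brain_fit
        with pytest.raises(ValueError, match="lh_insula_volume"):
            model.gap_table(cohort.drop(columns=["lh_insula_volume"]))

    def test_same_seed_reproduces_fit(self, td_single):
        _, g1 = nested_cv_fit(td_single, fast_brain_config(seed=9))
        _, g2 = nested_cv_fit(td_single, fast_brain_config(seed=9))
        pd.testing.assert_frame_equal(g1, g2)


class TestGapApplication:
    def test_zero_rtm_coefficients_leave_raw_untouched(self, brain_fit, baseline):
        import copy
        model = copy.deepcopy(brain_fit[0])
        model.rtm_slope_ = 0.0
        model.rtm_intercept_ = 0.0
        g = model.gap_table(baseline)
        np.testing.assert_allclose(g["predicted_age_adjusted"],
                                   g["predicted_age_raw"])

    def test_gap_arithmetic(self, brain_fit, baseline):
        """raw 11.5 y at age 10.0 with intercept 0.5, slope 0 -> gap 1.0 y."""
        import copy
        model = copy.deepcopy(brain_fit[0])
        model.rtm_slope_ = 0.0
        model.rtm_intercept_ = 0.5
        g = model.gap_table(baseline)
        expected = (g["predicted_age_raw"] - 0.5) - g["chronological_age"]
        np.testing.assert_allclose(g["gap"], expected)
        row = pd.Series({"predicted_age_raw": 11.5, "age": 10.0})
        assert (row.predicted_age_raw - 0.5) - row.age == pytest.approx(1.0)

    def test_training_rows_reuse_out_of_fold_predictions(self, brain_fit,
                                                         td_single):
        model, _ = brain_fit
        g = model.gap_table(td_single)
        merged = g.merge(model.oof_, on=["participant_id", "visit"])
        np.testing.assert_allclose(merged["predicted_age_raw_x"],
                                   merged["predicted_age_raw_y"])

    def test_generalizes_beyond_training_population(self, brain_fit, cohort):
        model, _ = brain_fit
        outside = cohort[~cohort.participant_id.isin(
            model.training_participants_)]
        g = model.gap_table(outside)
        assert len(g) == len(outside)
        assert g["predicted_age_raw"].between(5, 20).all()


class TestModelAccuracy:
    @staticmethod
    def _table(ages, preds):
        ages = np.asarray(ages, float)
        preds = np.asarray(preds, float)
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(len(ages))],
            "chronological_age": ages,
            "predicted_age_raw": preds,
            "predicted_age_adjusted": preds,
            "gap": preds - ages,
        })

    def test_perfect_predictions(self):
        r, mae = model_accuracy(self._table([9, 10, 11], [9, 10, 11]))
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(0.0)

    def test_constant_half_year_shift(self):
        r, mae = model_accuracy(self._table([9, 10, 11], [9.5, 10.5, 11.5]))
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(6.0)

    def test_three_point_hand_computation(self):
        r, mae = model_accuracy(self._table([9, 10, 11], [9.5, 10.0, 10.5]))
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(4.0)

    def test_zero_variance_predictions_flagged_not_fatal(self):
        r, mae = model_accuracy(self._table([9, 10, 11], [10, 10, 10]))
        assert np.isnan(r)
        assert mae == pytest.approx(8.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            model_accuracy(self._table([9, 10], [9, 10]))


class TestFeatureSets:
    def test_sex_specific_puberty_sets(self, cohort):
        f = feature_columns_for("pds_physical", cohort, sex="F")
        m = feature_columns_for("pds_physical", cohort, sex="M")
        assert "menarche" in f and "pds_breast" in f
        assert "pds_voice" in m and "menarche" not in m
        combined = feature_columns_for("combined", cohort, sex="F")
        assert set(combined) == set(f) | {"testosterone", "dhea"}

    def test_puberty_sets_require_sex(self, cohort):
        with pytest.raises(ValueError, match="sex"):
            feature_columns_for("hormonal", cohort)

    def test_unknown_set_rejected(self, cohort):
        with pytest.raises(ValueError):
            feature_columns_for("genomic", cohort)


def test_combined_model_fits_at_least_as_well_as_single_sources(td_single):
    """More features, supervised fit: the combined puberty model's in-sample
    r should not fall meaningfully below the single-source models'."""
    rs = {}
    for fs in ("pds_physical", "hormonal", "combined"):
        cfg = fast_puberty_config(feature_set=fs, seed=3)
        model, _ = nested_cv_fit(td_single[td_single.sex == "F"], cfg, sex="F")
        tr = model.oof_
        in_sample = model.estimator_.predict(
            np.column_stack([
                np.log(td_single.loc[td_single.sex == "F", c])
                if c in ("testosterone", "dhea")
                else td_single.loc[td_single.sex == "F", c]
                for c in model.feature_names_]))
        rs[fs] = pearson_r(in_sample, td_single.loc[td_single.sex == "F", "age"])
    assert rs["combined"] >= max(rs["pds_physical"], rs["hormonal"]) - 0.05
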