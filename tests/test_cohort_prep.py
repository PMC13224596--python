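"""Kidney-function computation, BMR, imputation rules and exclusion cascade."""

import numpy as np
import pandas as pd
import pytest

from dietkidney.cohort_prep import (
    EGFRParams,
    ExclusionThresholds,
    apply_exclusions,
    compute_bmr,
    compute_egfr,
    flag_healthy_plus,
    impute_menstrual_status,
    invert_egfr,
    simple_impute,
)
from dietkidney.synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort


class TestEGFR:
    @pytest.mark.parametrize("scr,age,sex,expected", [
        (0.9, 40.0, "male", 110.7),     # hand evaluation of the closed form
        (0.7, 50.0, "female", 105.3),
    ])
    def test_worked_values(self, scr, age, sex, expected):
        assert compute_egfr(scr, age, sex) == pytest.approx(expected, abs=0.05)

    def test_level_constant_limit(self):
        # at scr = kappa and age -> 0 both ratio factors and the age factor are 1
        val = compute_egfr(0.9, 1e-12, "male")
        assert val == pytest.approx(142.0, abs=1e-6)

    def test_continuity_at_kappa(self):
        eps = 1e-10
        lo = compute_egfr(0.9 - eps, 45, "male")
        hi = compute_egfr(0.9 + eps, 45, "male")
        assert abs(lo - hi) < 1e-6
        lo_f = compute_egfr(0.7 - eps, 45, "female")
        hi_f = compute_egfr(0.7 + eps, 45, "female")
        assert abs(lo_f - hi_f) < 1e-6

    def test_monotone_decreasing_in_creatinine_and_age(self):
        scr = np.linspace(0.3, 4.0, 200)
        vals = compute_egfr(scr, np.full_like(scr, 50.0), ["male"] * 200)
        assert np.all(np.diff(vals) < 0)
        ages = np.linspace(20, 90, 200)
        vals_a = compute_egfr(np.full_like(ages, 1.0), ages, ["female"] * 200)
        assert np.all(np.diff(vals_a) < 0)

    def test_invert_round_trip(self):
        rng = np.random.default_rng(0)
        egfr = rng.uniform(20, 140, 500)
        age = rng.uniform(20, 80, 500)
        sex = rng.choice(["male", "female"], 500)
        scr = invert_egfr(egfr, age, sex)
        back = compute_egfr(scr, age, sex)
        np.testing.assert_allclose(back, egfr, rtol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_egfr(0.0, 40, "male")
        with pytest.raises(ValueError):
            compute_egfr(1.0, -1, "male")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EGFRParams(age_decay=1.5)


class TestBMR:
    def test_schofield_band_hand_value(self):
        # 30-y male, 70 kg: young-adult band 15.057*W + 692.2
        assert compute_bmr("male", 30, 70) == pytest.approx(
            15.057 * 70 + 692.2, abs=1e-9)

    def test_deterministic_within_band(self):
        assert compute_bmr("female", 25, 60) == compute_bmr("female", 28, 60)

    def test_monotone_in_weight(self):
        assert compute_bmr("male", 45, 90) > compute_bmr("male", 45, 70)

    def test_unknown_equation(self):
        with pytest.raises(ValueError, match="equation"):
            compute_bmr("male", 30, 70, equation="harris-benedict")


class TestMenstrualImputation:
    @pytest.mark.parametrize("status,age,expected", [
        ("missing", 51, "no"),    # imputation rule
        ("missing", 50, "yes"),   # strict > 50
        ("yes", 70, "yes"),       # pass-through
        ("no", 30, "no"),
        (np.nan, 60, "no"),
    ])
    def test_rule(self, status, age, expected):
        assert impute_menstrual_status(status, age) == expected

    def test_vectorized(self):
        out = impute_menstrual_status(
            np.array(["missing", "yes", "missing"], dtype=object),
            np.array([55.0, 20.0, 30.0]))
        assert list(out) == ["no", "yes", "yes"]


def _toy_cohort(n=10, seed=0, **kw):
    return generate_cohort(CohortConfig(n_subjects=n, seed=seed, **kw))


class TestExclusions:
    def test_report_is_partition(self, small_cohort):
        _, report = apply_exclusions(small_cohort)
        assert report.check_partition()

    def test_step1_counts_flagged(self):
        cohort = _toy_cohort(10, seed=3, disease_flag_prevalence={
            "kidney_disease": 0.0, "hypertension": 0.0, "diabetes": 0.0,
            "kidney_medication": 0.0, "hypertension_medication": 0.0,
            "diabetes_medication": 0.0},
            missing_rates={"ffq_item": 0.0, "ffq_heavy_subject": 0.0,
                           "ffq_heavy_frac": 0.0, "biomarker": 0.0,
                           "biomarker_heavy_subject": 0.0,
                           "menstrual_status": 0.0})
        cohort.covariates.loc[2, "hypertension"] = 1
        _, report = apply_exclusions(cohort)
        assert report.removed_disease_or_medication == 1
        # step 4 on the 9 survivors: brute-force percentile rule
        surv = cohort.covariates.drop(index=2)
        ratio = (surv["tei"] / surv["bmr"]).to_numpy()
        lo, hi = np.quantile(ratio, [0.005, 0.995])
        expected4 = int(((ratio < lo) | (ratio > hi)).sum())
        assert report.removed_tei_bmr_range == expected4
        assert report.remaining_n == 9 - expected4

    def test_ffq_missing_threshold_is_strict_20_percent(self):
        cohort = _toy_cohort(12, seed=4, disease_flag_prevalence={
            "kidney_disease": 0.0, "hypertension": 0.0, "diabetes": 0.0,
            "kidney_medication": 0.0, "hypertension_medication": 0.0,
            "diabetes_medication": 0.0},
            missing_rates={"ffq_item": 0.0, "ffq_heavy_subject": 0.0,
                           "ffq_heavy_frac": 0.0, "biomarker": 0.0,
                           "biomarker_heavy_subject": 0.0,
                           "menstrual_status": 0.0})
        items = [c for c in cohort.ffq.columns if c.startswith("item_")]
        # 47/229 = 20.5% missing -> excluded; 45/229 = 19.7% -> retained
        cohort.ffq.loc[0, items[:47]] = np.nan
        cohort.ffq.loc[1, items[:45]] = np.nan
        _, report = apply_exclusions(cohort)
        assert report.removed_missing_ffq == 1

    def test_percentile_filter_brute_force(self):
        cohort = _toy_cohort(1000, seed=6, disease_flag_prevalence={
            "kidney_disease": 0.0, "hypertension": 0.0, "diabetes": 0.0,
            "kidney_medication": 0.0, "hypertension_medication": 0.0,
            "diabetes_medication": 0.0},
            missing_rates={"ffq_item": 0.0, "ffq_heavy_subject": 0.0,
                           "ffq_heavy_frac": 0.0, "biomarker": 0.0,
                           "biomarker_heavy_subject": 0.0,
                           "menstrual_status": 0.0})
        ratio = (cohort.covariates["tei"] / cohort.covariates["bmr"]).to_numpy()
        lo, hi = np.quantile(ratio, [0.005, 0.995])
        expected_removed = int(((ratio < lo) | (ratio > hi)).sum())
        _, report = apply_exclusions(cohort)
        assert report.removed_tei_bmr_range == expected_removed
        assert expected_removed == pytest.approx(10, abs=2)

    def test_residual_ffq_missing_imputed_to_zero(self, small_cohort):
        tables, _ = apply_exclusions(small_cohort)
        items = [c for c in tables["ffq"].columns if c.startswith("item_")]
        assert not tables["ffq"][items].isna().any().any()

    def test_empty_sample_raises_named_step(self):
        cohort = _toy_cohort(12, seed=7)
        cohort.covariates["diabetes"] = 1
        with pytest.raises(ValueError, match="step 1"):
            apply_exclusions(cohort)


class TestHealthyPlus:
    def test_truth_table(self):
        # one violation per clause among 8 rows -> 3 excluded
        hba1c = [6.6, 5.0, 5.0, 5.0, 5.0, 6.5, 5.0, 5.0]
        egfr = [95, 50, 95, 95, 95, 60, 95, 95]
        uacr = [10, 10, 40, 10, 10, 30, 10, 10]
        mask = flag_healthy_plus(hba1c, egfr, uacr)
        assert mask.sum() == 3
        assert list(mask[:3]) == [True, True, True]

    def test_boundaries_retained(self):
        assert not flag_healthy_plus(6.5, 60.0, 30.0)

    def test_missing_uacr(self):
        with pytest.raises(ValueError, match="UACR"):
            flag_healthy_plus([5.0], [90.0], None)


def test_simple_impute_median_and_mode():
    df = pd.DataFrame({"x": [1.0, np.nan, 3.0], "c": ["a", "a", None]})
    out = simple_impute(df)
    assert out["x"].tolist() == [1.0, 2.0, 3.0]
    assert out["c"].tolist() == ["a", "a", "a"]
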