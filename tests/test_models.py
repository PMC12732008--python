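"""Logistic outcome models: closed forms, calibration, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from usvtwin.cohort import Cohort
from usvtwin.models import (
    FixedRateModel,
    brier_score,
    calibration_bins,
    fit_outcome_model,
    marginal_rates,
    predict_risk,
)
from usvtwin.source import SourceConfig, sample_cohort


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1 / (1 + np.exp(-x))


@pytest.fixture(scope="module")
def big_cohort():
    return sample_cohort(SourceConfig(n_total=4000), seed=21)


class TestFit:
    def test_treatment_only_model_is_saturated_two_group_logit(self, big_cohort):
        """Closed form: intercept = logit(VKA rate); treatment coefficient =
        logit(DOAC rate) − logit(VKA rate)."""
        model = fit_outcome_model(big_cohort, "recurrence", predictors=("treatment",))
        df = big_cohort.df
        p_vka = df.loc[df["treatment"] == "VKA", "recurrence"].mean()
        p_doac = df.loc[df["treatment"] == "DOAC", "recurrence"].mean()
        assert model.coefficients["const"] == pytest.approx(_logit(p_vka), abs=1e-8)
        assert model.coefficients["treatment_DOAC"] == pytest.approx(
            _logit(p_doac) - _logit(p_vka), abs=1e-8
        )
        assert not model.penalized

    def test_independent_endpoint_gives_null_coefficients(self):
        rng = np.random.default_rng(777)  # independent of the cohort's seed
        cohort = sample_cohort(SourceConfig(n_total=5000), seed=3)
        df = cohort.df.copy()
        df["major_bleed"] = rng.binomial(1, 0.3, len(df))  # independent of everything
        cohort = Cohort(df, list(cohort.schema))
        model = fit_outcome_model(cohort, "major_bleed", site_ridge=0.0)
        ci = model.conf_int()
        for term, (lo, hi) in ci.items():
            if term != "const":
                assert lo < 0 < hi

    def test_all_one_class_is_degenerate(self, big_cohort):
        df = big_cohort.df.copy()
        df["recurrence"] = 0
        with pytest.raises(ValueError, match="degenerate"):
            fit_outcome_model(Cohort(df, list(big_cohort.schema)), "recurrence")

    def test_recanalization_fit_uses_imaged_rows_only(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recanalization_complete", predictors=("treatment",))
        df = big_cohort.df
        imaged = df["recanalization"].notna()
        p_vka = (df.loc[imaged & (df["treatment"] == "VKA"), "recanalization"] == "complete").mean()
        assert model.coefficients["const"] == pytest.approx(_logit(p_vka), abs=1e-8)

    def test_parameter_recovery_coverage(self):
        """Simulate outcomes from known coefficients at n=5000; 95% Wald CIs
        should cover the truth in at least ~90% of replications."""
        truth = {"const": -2.0, "treatment_DOAC": 0.5, "active_cancer": 0.8}
        base = sample_cohort(SourceConfig(n_total=5000), seed=30).df
        eta = (
            truth["const"]
            + truth["treatment_DOAC"] * (base["treatment"] == "DOAC")
            + truth["active_cancer"] * base["active_cancer"]
        )
        p = _expit(eta.to_numpy())
        covered = {k: 0 for k in truth}
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            df = base.copy()
            df["recurrence"] = rng.binomial(1, p)
            model = fit_outcome_model(
                Cohort(df), "recurrence", predictors=("treatment", "active_cancer"),
            )
            ci = model.conf_int()
            for term in truth:
                lo, hi = ci[term]
                covered[term] += lo <= truth[term] <= hi
        for term, count in covered.items():
            assert count / n_rep >= 0.875, (term, count)


class TestPredict:
    def test_intercept_only_probability(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence", predictors=("treatment",))
        model.coefficients = {"const": _logit(0.36), "treatment_DOAC": 0.0}
        probs = predict_risk(model, big_cohort.df)
        np.testing.assert_allclose(probs, 0.36, atol=1e-12)

    def test_hand_computed_inverse_logit(self, big_cohort):
        model = fit_outcome_model(
            big_cohort, "recurrence", predictors=("treatment", "active_cancer")
        )
        model.coefficients = {"const": -1.0, "treatment_DOAC": 0.7, "active_cancer": -0.3}
        row = pd.DataFrame(
            {"treatment": ["DOAC"], "active_cancer": [1], "usvt_site": ["SVT"]}
        )
        assert predict_risk(model, row)[0] == pytest.approx(_expit(-1.0 + 0.7 - 0.3))

    def test_monotone_in_coefficient_sign(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence")
        beta = model.coefficients["treatment_DOAC"]
        row = big_cohort.df.head(1).copy()
        p = {}
        for arm in ("VKA", "DOAC"):
            row["treatment"] = arm
            p[arm] = predict_risk(model, row)[0]
        assert (p["DOAC"] > p["VKA"]) == (beta > 0)


class TestMarginalRates:
    def test_treatment_only_model_reproduces_raw_arm_rates(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence", predictors=("treatment",))
        rates = marginal_rates(model, big_cohort, n_boot=20, seed=0)
        df = big_cohort.df
        for arm, value in (("VKA", rates.vka), ("DOAC", rates.doac)):
            raw = 100 * df.loc[df["treatment"] == arm, "recurrence"].mean()
            assert value == pytest.approx(raw, abs=1e-8)
        assert rates.difference == pytest.approx(rates.doac - rates.vka)

    def test_ci_brackets_point_estimate(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence")
        rates = marginal_rates(model, big_cohort, n_boot=100, seed=1)
        assert rates.vka_ci[0] <= rates.vka <= rates.vka_ci[1]
        assert rates.doac_ci[0] <= rates.doac <= rates.doac_ci[1]


class TestBrier:
    def test_perfect_predictions_score_zero(self, big_cohort):
        model = FixedRateModel("recurrence", {"VKA": 0.0, "DOAC": 0.0})
        df = big_cohort.df.copy()
        df["recurrence"] = 0
        assert brier_score(model, Cohort(df)) == 0.0

    def test_constant_half_scores_quarter(self, big_cohort):
        model = FixedRateModel("recurrence", {"VKA": 0.5, "DOAC": 0.5})
        assert brier_score(model, big_cohort) == pytest.approx(0.25)

    def test_toy_hand_computation(self):
        df = pd.DataFrame(
            {"treatment": ["VKA", "VKA", "DOAC", "DOAC"], "recurrence": [1, 0, 1, 0]}
        )
        model = FixedRateModel("recurrence", {"VKA": 0.8, "DOAC": 0.3})
        expected = np.mean([(0.8 - 1) ** 2, 0.8**2, (0.3 - 1) ** 2, 0.3**2])
        assert brier_score(model, df) == pytest.approx(expected)


class TestCalibration:
    def test_single_bin_rejected(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence")
        with pytest.raises(ValueError):
            calibration_bins(model, big_cohort, n_bins=1)

    def test_fewer_rows_than_bins_warns_and_reduces(self, big_cohort):
        model = fit_outcome_model(big_cohort, "recurrence", predictors=("treatment",))
        small = big_cohort.df.head(5)
        with pytest.warns(UserWarning):
            bins = calibration_bins(model, small, n_bins=10)
        assert bins["count"].sum() == 5

    def test_well_calibrated_simulation(self):
        """On data simulated from the fitted model itself, every bin's
        observed rate sits within 3 binomial SEs of its mean prediction."""
        cohort = sample_cohort(SourceConfig(n_total=8000), seed=33)
        model = fit_outcome_model(cohort, "recurrence")
        df = cohort.df.copy()
        p = model.predict_risk(df)
        df["recurrence"] = np.random.default_rng(7).binomial(1, p)
        bins = calibration_bins(model, Cohort(df), n_bins=8)
        for _, row in bins.iterrows():
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["count"])
            assert abs(row["observed_rate"] - row["mean_predicted"]) < 3 * se + 1e-9
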