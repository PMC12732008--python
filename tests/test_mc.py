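"""Two-layer Monte Carlo engine: stratified case-mixes, Bernoulli layer,
convergence diagnostics, directionality and sensitivity checks."""

import numpy as np
import pandas as pd
import pytest

from usvtwin import mc
from usvtwin.cohort import Cohort
from usvtwin.models import ENDPOINTS, FixedRateModel
from usvtwin.source import SourceConfig, sample_cohort


@pytest.fixture(scope="module")
def twin_cohort():
    # stands in for a conditioned twin cohort: equal-ish arms, CVT present
    return sample_cohort(SourceConfig(n_total=300, p_vka=0.5), seed=55)


def _fixed_models(rates_by_endpoint):
    return {
        endpoint: FixedRateModel(endpoint, rates)
        for endpoint, rates in rates_by_endpoint.items()
    }


class TestScenarioSpec:
    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            mc.ScenarioSpec("doac99")

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            mc.ScenarioSpec("baseline", iterations=0)


class TestCasemix:
    def test_baseline_preserves_marginals_in_expectation(self, twin_cohort):
        spec = mc.ScenarioSpec("baseline", resample_size=20000)
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=0)
        target = (twin_cohort.df["treatment"] == "DOAC").mean()
        observed = (out["treatment"] == "DOAC").mean()
        se = np.sqrt(target * (1 - target) / len(out))
        assert abs(observed - target) < 4 * se

    def test_doac70_hits_treatment_marginal(self, twin_cohort):
        spec = mc.ScenarioSpec("doac70", resample_size=4000)
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=1)
        assert (out["treatment"] == "DOAC").mean() == pytest.approx(0.70, abs=0.001)

    def test_cancer_plus50_scales_prevalence(self, twin_cohort):
        spec = mc.ScenarioSpec("cancer_plus50", resample_size=4000)
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=1)
        source_prev = twin_cohort.df["active_cancer"].mean()
        assert out["active_cancer"].mean() == pytest.approx(1.5 * source_prev, abs=0.001)

    def test_cvt40_hits_site_marginal(self, twin_cohort):
        spec = mc.ScenarioSpec("cvt40", resample_size=4000)
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=1)
        assert (out["usvt_site"] == "CVT").mean() == pytest.approx(0.40, abs=0.001)

    def test_cvt40_without_cvt_rows_is_infeasible(self, twin_cohort):
        df = twin_cohort.df[twin_cohort.df["usvt_site"] != "CVT"].reset_index(drop=True)
        no_cvt = Cohort(df, list(twin_cohort.schema))
        with pytest.raises(mc.ScenarioInfeasibleError, match="CVT"):
            mc.build_scenario_casemix(no_cvt, mc.ScenarioSpec("cvt40"), seed=0)

    def test_ttr100_sets_vka_ttr_to_100(self, twin_cohort):
        out = mc.build_scenario_casemix(twin_cohort, mc.ScenarioSpec("ttr100"), seed=2)
        vka = out["treatment"] == "VKA"
        assert (out.loc[vka, "ttr"] == 100.0).all()
        assert out.loc[~vka, "ttr"].isna().all()

    def test_stratified_resampling_preserves_within_stratum_structure(self, twin_cohort):
        """Perturbing the treatment marginal must not distort covariate
        distributions within each arm (resampling, not editing)."""
        spec = mc.ScenarioSpec("doac70", resample_size=30000)
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=3)
        for arm in ("VKA", "DOAC"):
            src = twin_cohort.df[twin_cohort.df["treatment"] == arm]
            res = out[out["treatment"] == arm]
            assert res["active_cancer"].mean() == pytest.approx(
                src["active_cancer"].mean(), abs=0.02
            )
            assert res["age"].mean() == pytest.approx(src["age"].mean(), abs=1.0)


class TestIteration:
    def test_zero_probability_gives_zero_rates(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.0, "DOAC": 0.0}})
        out = mc.simulate_iteration(twin_cohort.df, models, seed=0)
        assert out["recurrence"] == {"VKA": 0.0, "DOAC": 0.0}

    def test_binomial_concentration(self, twin_cohort):
        spec = mc.ScenarioSpec("baseline", resample_size=10000)
        casemix = mc.build_scenario_casemix(twin_cohort, spec, seed=4)
        models = _fixed_models({"recurrence": {"VKA": 0.4, "DOAC": 0.4}})
        out = mc.simulate_iteration(casemix, models, seed=4)
        for arm in ("VKA", "DOAC"):
            n_arm = (casemix["treatment"] == arm).sum()
            assert abs(out["recurrence"][arm] - 0.4) < 4 * np.sqrt(0.4 * 0.6 / n_arm)

    def test_fixed_seed_reproducible(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.3, "DOAC": 0.2}})
        a = mc.simulate_iteration(twin_cohort.df, models, seed=11)
        b = mc.simulate_iteration(twin_cohort.df, models, seed=11)
        assert a == b

    def test_absent_arm_yields_nan(self, twin_cohort):
        vka_only = twin_cohort.df[twin_cohort.df["treatment"] == "VKA"]
        models = _fixed_models({"recurrence": {"VKA": 0.3, "DOAC": 0.2}})
        out = mc.simulate_iteration(vka_only, models, seed=0)
        assert np.isnan(out["recurrence"]["DOAC"])


class TestRunSimulation:
    def test_unbiased_for_fixed_probabilities(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.25, "DOAC": 0.15}})
        spec = mc.ScenarioSpec("baseline", resample_size=2000, iterations=100)
        result = mc.run_simulation(twin_cohort, models, [spec], master_seed=0)
        for arm, p in (("VKA", 25.0), ("DOAC", 15.0)):
            row = result.summary[result.summary["arm"] == arm].iloc[0]
            assert abs(row["mean"] - p) < 3 * row["mcse_abs"] + 1e-9
            assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]

    def test_single_iteration_ci_collapses(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.25, "DOAC": 0.15}})
        spec = mc.ScenarioSpec("baseline", resample_size=500, iterations=1)
        result = mc.run_simulation(twin_cohort, models, [spec], master_seed=1)
        row = result.summary.iloc[0]
        assert row["ci_lo"] == row["mean"] == row["ci_hi"]

    def test_mcse_scales_as_inverse_sqrt_iterations(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.25, "DOAC": 0.15}})
        mcse = {}
        for r in (100, 400):
            spec = mc.ScenarioSpec("baseline", resample_size=1000, iterations=r)
            res = mc.run_simulation(twin_cohort, models, [spec], master_seed=2)
            mcse[r] = res.summary[res.summary["arm"] == "VKA"]["mcse_abs"].iloc[0]
        ratio = mcse[100] / mcse[400]
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_deterministic_under_master_seed(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.25, "DOAC": 0.15}})
        spec = mc.ScenarioSpec("baseline", resample_size=300, iterations=20)
        a = mc.run_simulation(twin_cohort, models, [spec], master_seed=9)
        b = mc.run_simulation(twin_cohort, models, [spec], master_seed=9)
        pd.testing.assert_frame_equal(a.summary, b.summary)


@pytest.fixture(scope="module")
def result(twin_cohort):
    models = _fixed_models(
        {
            "recanalization_complete": {"VKA": 0.38, "DOAC": 0.43},
            "recurrence": {"VKA": 0.30, "DOAC": 0.30},
        }
    )
    spec = mc.ScenarioSpec("baseline", resample_size=3000, iterations=200)
    return mc.run_simulation(twin_cohort, models, [spec], master_seed=3)


class TestDirectionality:
    def test_clear_effect_preserved_and_complement(self, result):
        plus = mc.directionality(result, {"recanalization_complete": 1, "recurrence": 1})
        minus = mc.directionality(result, {"recanalization_complete": -1, "recurrence": -1})
        assert plus["recanalization_complete"] > 0.95
        # complement holds when no iteration ties occur
        assert plus["recanalization_complete"] + minus["recanalization_complete"] == pytest.approx(
            1.0, abs=0.02
        )

    def test_null_effect_splits_near_half(self, result):
        fractions = mc.directionality(result, {"recanalization_complete": 1, "recurrence": 1})
        assert 0.35 < fractions["recurrence"] < 0.65


class TestSensitivity:
    def test_variants_agree_within_mcse(self, twin_cohort):
        models = _fixed_models({"recurrence": {"VKA": 0.25, "DOAC": 0.15}})
        spec = mc.ScenarioSpec("baseline", resample_size=1000, iterations=100)
        table = mc.sensitivity_suite(
            twin_cohort, models, spec, r_values=(50, 100), master_seed=0
        )
        assert (table["max_deviation_in_mcse_units"] < 4.0).all()
        assert "weighted" in set(table["variant"])

    def test_weighted_scheme_hits_target_marginal(self, twin_cohort):
        spec = mc.ScenarioSpec("doac70", resample_size=30000, scheme="weighted")
        out = mc.build_scenario_casemix(twin_cohort, spec, seed=5)
        share = (out["treatment"] == "DOAC").mean()
        assert share == pytest.approx(0.70, abs=0.02)
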