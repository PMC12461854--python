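import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import spearmanr

from climsens.errors import ConfigError, UndefinedSensitivityError, VitalRateSkip
from climsens.popmodel import build_matrix, lambda_asymptotic
from climsens.sensitivity import (
    PerturbationScenario,
    SensitivityResult,
    average_across_populations,
    log_response_ratio,
    scaled_sensitivity,
    sensitivity_for_driver,
    sensitivity_per_vital_rate,
)
from climsens.study import CovariateTerm, Driver, Population, SpeciesStudy, VitalRateModel
from climsens.synthetic import SyntheticConfig, generate_species

from conftest import make_drivers, two_stage_study


class TestScaledSensitivity:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((1.1, 0.9, 2.0, 0.0, 1.0), 0.1),
            ((1.0, 1.0, 2.0, 0.0, 1.0), 0.0),
            ((1.05, 0.95, 3.0, 1.0, 2.0), 0.1),
        ],
    )
    def test_tabulated_cases_exact(self, args, expected):
        assert abs(scaled_sensitivity(*args) - expected) < 1e-12

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedSensitivityError):
            scaled_sensitivity(1.1, 0.9, 1.0, 1.0, 0.5)
        with pytest.raises(UndefinedSensitivityError):
            scaled_sensitivity(1.1, 0.9, 2.0, 0.0, 0.0)

    def test_sign_insensitive(self):
        assert scaled_sensitivity(0.9, 1.1, 2.0, 0.0, 1.0) == pytest.approx(0.1)


class TestLogResponseRatio:
    def test_equal_lambdas_give_zero(self):
        assert log_response_ratio(1.3, 1.3) == 0.0

    def test_e_fold(self):
        assert log_response_ratio(np.e, 1.0) == pytest.approx(1.0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigError):
            log_response_ratio(0.0, 1.0)

    def test_rank_correlation_with_scaled_sensitivity_positive(self):
        cfg = SyntheticConfig(coefficient_se=0.0)
        s_vals, lrr_vals = [], []
        for i in range(50):
            study, _ = generate_species(cfg, seed=500 + i)
            dh = "covary" if study.density_modeled else "not_applicable"
            res = sensitivity_for_driver(
                study, PerturbationScenario("temperature", "full", dh), 1, seed=0
            )
            s_vals.append(res.samples[0])
            lmax, lmin = res.lambda_pairs[0]
            # independent recomputation of both metrics from the lambda pair
            d = study.population().driver("temperature")
            assert res.samples[0] == pytest.approx(
                abs((lmax - lmin) / ((d.d_max - d.d_min) / d.d_sd))
            )
            lrr_vals.append(abs(np.log(lmax / lmin)))
        rho = spearmanr(s_vals, lrr_vals).statistic
        assert rho > 0


class TestSensitivityForDriver:
    def test_driver_with_no_effect_gives_zero(self, toy_study):
        res = sensitivity_for_driver(
            toy_study,
            PerturbationScenario("temperature", "full", "not_applicable"),
            n_samples=3,
            seed=0,
        )
        assert np.all(res.samples == 0.0)

    def test_closed_form_two_stage_lambda(self):
        # lambda solves l^2 = f(T) * s_j  (no adult survival), so |S| has a
        # hand-derivable closed form from the fecundity model
        slope, s_j, f0 = 0.4, 0.5, 2.0
        study = two_stage_study(s_j=s_j, fec=f0, fec_temp_slope=slope)
        d = study.population().driver("temperature")
        lam = lambda T: np.sqrt(np.exp(np.log(f0) + slope * T) * s_j)
        expected = abs(
            (lam(d.d_max) - lam(d.d_min)) / ((d.d_max - d.d_min) / d.d_sd)
        )
        res = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "full", "not_applicable"),
            n_samples=1, seed=0,
        )
        assert res.samples[0] == pytest.approx(expected, rel=1e-9)

    def test_no_uncertainty_gives_identical_samples(self):
        study = two_stage_study(fec_temp_slope=0.3)
        res = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "full", "not_applicable"),
            n_samples=7, seed=3,
        )
        assert res.n_samples == 7
        assert np.all(res.samples == res.samples[0])

    def test_deterministic_given_seed(self):
        study = two_stage_study(fec_temp_slope=0.3, se=0.1)
        scen = PerturbationScenario("temperature", "full", "not_applicable")
        a = sensitivity_for_driver(study, scen, 5, seed=2)
        b = sensitivity_for_driver(study, scen, 5, seed=2)
        assert np.array_equal(a.samples, b.samples)

    def test_unit_invariance_under_driver_rescaling(self):
        # rescaling a driver's series by a > 0 and its coefficient by 1/a
        # leaves |S| unchanged
        a = 37.5
        base = two_stage_study(fec_temp_slope=0.4, sj_rain_slope=-0.2)
        T = np.linspace(-1.5, 1.5, 10)
        scaled = two_stage_study(
            fec_temp_slope=0.4 / a, sj_rain_slope=-0.2,
            drivers=make_drivers(T=a * T),
        )
        scen = PerturbationScenario("temperature", "full", "not_applicable")
        s0 = sensitivity_for_driver(base, scen, 1, seed=0).samples[0]
        s1 = sensitivity_for_driver(scaled, scen, 1, seed=0).samples[0]
        assert abs(s0 - s1) < 1e-12

    def test_scenario_coherence_when_other_drivers_have_no_effect(self):
        # the focal driver is the only one entering any vital rate: full and
        # reduced covariation coincide
        study = two_stage_study(fec_temp_slope=0.5)
        full = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "full", "not_applicable"), 1, 0
        )
        red = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "reduced", "not_applicable"), 1, 0
        )
        assert full.samples[0] == pytest.approx(red.samples[0], rel=1e-12)

    def test_density_handling_flag_must_match_study(self, toy_study):
        with pytest.raises(ConfigError):
            sensitivity_for_driver(
                toy_study, PerturbationScenario("temperature", "full", "covary"), 1, 0
            )


class TestPerVitalRate:
    def fixture_study(self):
        # fecundity depends on temperature only; juvenile survival on rainfall only
        return two_stage_study(fec_temp_slope=0.5, sj_rain_slope=0.3)

    def test_rate_without_focal_driver_raises_skip(self):
        with pytest.raises(VitalRateSkip):
            sensitivity_per_vital_rate(
                self.fixture_study(), "juvenile_survival", "temperature", 1, 0
            )

    def test_focal_rate_equals_all_rates_under_reduced_covariation(self):
        study = self.fixture_study()
        per_rate = sensitivity_per_vital_rate(study, "recruitment", "temperature", 1, 0)
        all_reduced = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "reduced", "not_applicable"), 1, 0
        )
        assert per_rate.samples[0] == pytest.approx(all_reduced.samples[0], rel=1e-12)

    def test_zero_slope_in_focal_rate_gives_zero(self):
        study = two_stage_study(fec_temp_slope=1e-300, sj_rain_slope=0.3)
        res = sensitivity_per_vital_rate(study, "recruitment", "temperature", 1, 0)
        assert res.samples[0] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_sign_rates_partially_cancel_in_whole_model(self):
        T = np.linspace(-1.0, 1.0, 10)
        study = two_stage_study(
            fec_temp_slope=0.6, drivers=make_drivers(T=T, R=T),
        )
        # juvenile survival responds to the same driver with opposite sign via
        # rainfall series equal to temperature
        study.vital_rate_models[0].terms.append(CovariateTerm("temperature"))
        study.vital_rate_models[0].coefficients = np.append(
            study.vital_rate_models[0].coefficients, -0.6
        )
        pr_f = sensitivity_per_vital_rate(study, "recruitment", "temperature", 1, 0)
        pr_s = sensitivity_per_vital_rate(study, "juvenile_survival", "temperature", 1, 0)
        whole = sensitivity_for_driver(
            study, PerturbationScenario("temperature", "reduced", "not_applicable"), 1, 0
        )
        assert pr_f.samples[0] > 0 and pr_s.samples[0] > 0
        assert whole.samples[0] < pr_f.samples[0] + pr_s.samples[0]


class TestAveraging:
    def make_result(self, samples, species="s", driver="temperature"):
        samples = np.asarray(samples, float)
        return SensitivityResult(
            species=species, population="p", focal_driver=driver,
            scenario=PerturbationScenario(driver, "full", "not_applicable"),
            samples=samples,
            lambda_pairs=np.column_stack([1 + samples, 1 - samples]),
        )

    def test_single_population_is_identity(self):
        r = self.make_result([0.1, 0.2])
        avg = average_across_populations([r])
        assert np.array_equal(avg.samples, r.samples)

    def test_two_constant_populations(self):
        avg = average_across_populations(
            [self.make_result([0.2, 0.2]), self.make_result([0.4, 0.4])]
        )
        assert np.all(avg.samples == pytest.approx(0.3))

    def test_three_populations_match_independent_mean(self, rng):
        res = [self.make_result(rng.uniform(0, 1, 5)) for _ in range(3)]
        avg = average_across_populations(res)
        stacked = np.stack([r.samples for r in res])
        assert avg.samples == pytest.approx(stacked.sum(axis=0) / 3.0)

    def test_mismatched_sample_counts_rejected(self):
        with pytest.raises(ConfigError):
            average_across_populations(
                [self.make_result([0.1, 0.2]), self.make_result([0.1])]
            )


class TestDirectionalProperties:
    def test_covariation_amplification_on_correlated_same_sign_suite(self):
        cfg = SyntheticConfig(
            density_fraction=0.0, same_sign_effects=True, coefficient_se=0.0
        )
        wins = 0
        n = 25
        for i in range(n):
            study, _ = generate_species(cfg, seed=3000 + i)
            full, red = [], []
            for d in ("temperature", "rainfall"):
                full.append(sensitivity_for_driver(
                    study, PerturbationScenario(d, "full", "not_applicable"), 1, 0
                ).samples[0])
                red.append(sensitivity_for_driver(
                    study, PerturbationScenario(d, "reduced", "not_applicable"), 1, 0
                ).samples[0])
            wins += np.mean(full) > np.mean(red)
        assert wins / n >= 0.8

    def test_density_buffering_on_negative_feedback_suite(self):
        cfg = SyntheticConfig(
            density_fraction=1.0, same_sign_effects=True, coefficient_se=0.0
        )
        wins = 0
        n = 25
        for i in range(n):
            study, _ = generate_species(cfg, seed=4000 + i)
            cov, fix = [], []
            for d in ("temperature", "rainfall"):
                cov.append(sensitivity_for_driver(
                    study, PerturbationScenario(d, "full", "covary"), 1, 0
                ).samples[0])
                fix.append(sensitivity_for_driver(
                    study, PerturbationScenario(d, "full", "fixed"), 1, 0
                ).samples[0])
            wins += np.mean(cov) < np.mean(fix)
        assert wins / n >= 0.8
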