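import numpy as np
import pytest
from scipy.special import expit

from climsens.errors import (
    ConfigError,
    IncompleteEnvironmentError,
    UndefinedSensitivityError,
)
from climsens.study import (
    CovariateTerm,
    Driver,
    Environment,
    Population,
    SpeciesStudy,
    Uncertainty,
    VitalRateModel,
    environment_at_extreme,
    predict_vital_rate,
    resample_parameters,
)

from conftest import make_drivers, two_stage_study


def model_with(terms, coefs, family="binomial-logit", uncertainty=None):
    return VitalRateModel(
        "m", "nonreproductive_survival", family, terms, coefs,
        uncertainty=uncertainty or Uncertainty(),
    )


class TestPredict:
    def test_logit_all_zero_coefficients_gives_half(self):
        m = model_with([CovariateTerm(), CovariateTerm("temperature")], [0.0, 0.0])
        env = Environment(values={"temperature": 3.7})
        assert predict_vital_rate(m, env) == 0.5

    def test_log_link_intercept_only(self):
        m = model_with([CovariateTerm()], [np.log(2.0)], family="poisson-log")
        assert predict_vital_rate(m, Environment(values={})) == pytest.approx(2.0)

    def test_hand_evaluated_linear_predictor(self):
        # intercept -1, temperature coefficient 0.5, temperature 2 -> logit^-1(0)
        m = model_with([CovariateTerm(), CovariateTerm("temperature")], [-1.0, 0.5])
        env = Environment(values={"temperature": 2.0})
        assert predict_vital_rate(m, env) == pytest.approx(0.5)
        # cross-check at another point by direct evaluation
        env2 = Environment(values={"temperature": -1.0})
        assert predict_vital_rate(m, env2) == pytest.approx(float(expit(-1.5)))

    def test_missing_covariate_names_the_driver(self):
        m = model_with([CovariateTerm(), CovariateTerm("rainfall")], [0.0, 1.0])
        with pytest.raises(IncompleteEnvironmentError, match="rainfall"):
            predict_vital_rate(m, Environment(values={"temperature": 0.0}))

    def test_year_effect_applied_on_linear_predictor(self):
        m = VitalRateModel(
            "m", "reproduction", "poisson-log", [CovariateTerm()], [0.0],
            year_effect={2001: np.log(3.0)},
        )
        assert predict_vital_rate(m, Environment(values={})) == pytest.approx(1.0)
        assert predict_vital_rate(
            m, Environment(values={}, year=2001)
        ) == pytest.approx(3.0)

    def test_interaction_term_multiplies_factors(self):
        inter = CovariateTerm("temperature", interaction_with=(CovariateTerm("rainfall"),))
        m = model_with([CovariateTerm(), inter], [0.0, 1.0], family="poisson-log")
        env = Environment(values={"temperature": 2.0, "rainfall": 3.0})
        assert predict_vital_rate(m, env) == pytest.approx(np.exp(6.0))

    def test_monotone_in_single_coefficient_for_monotone_links(self, rng):
        for family in ("binomial-logit", "poisson-log"):
            for _ in range(20):
                coefs = rng.normal(size=3)
                m = model_with(
                    [CovariateTerm(), CovariateTerm("temperature"), CovariateTerm("rainfall")],
                    coefs, family=family,
                )
                env = Environment(
                    values={"temperature": abs(rng.normal()) + 0.1, "rainfall": abs(rng.normal()) + 0.1}
                )
                idx = rng.integers(0, 3)
                lo, hi = coefs.copy(), coefs.copy()
                hi[idx] += 0.5
                assert predict_vital_rate(m, env, coefficients=hi) >= predict_vital_rate(
                    m, env, coefficients=lo
                )

    def test_standardized_transform_uses_stored_series_stats(self):
        m = model_with(
            [CovariateTerm(), CovariateTerm("temperature", transformation="standardized")],
            [0.0, 1.0], family="poisson-log",
        )
        env = Environment(values={"temperature": 4.0}, driver_stats={"temperature": (2.0, 2.0)})
        assert predict_vital_rate(m, env) == pytest.approx(np.exp(1.0))
        with pytest.raises(IncompleteEnvironmentError):
            predict_vital_rate(m, Environment(values={"temperature": 4.0}))


class TestResample:
    def test_zero_se_returns_identical_copies(self):
        m = model_with(
            [CovariateTerm(), CovariateTerm("temperature")], [1.0, -2.0],
            uncertainty=Uncertainty("se", np.zeros(2)),
        )
        draws = resample_parameters(m, 5, seed=0)
        assert draws.shape == (5, 2)
        assert np.all(draws == m.coefficients)

    def test_se_sample_mean_within_clt_bound(self):
        m = model_with([CovariateTerm()], [2.5], uncertainty=Uncertainty("se", [1.0]))
        draws = resample_parameters(m, 10_000, seed=7)
        assert abs(draws.mean() - 2.5) < 3 / np.sqrt(10_000) * 3

    def test_single_row_posterior_resamples_that_row(self):
        post = np.array([[0.1, 0.2, 0.3]])
        m = model_with(
            [CovariateTerm(), CovariateTerm("temperature"), CovariateTerm("rainfall")],
            [0.0, 0.0, 0.0], uncertainty=Uncertainty("posterior", post),
        )
        draws = resample_parameters(m, 4, seed=1)
        assert np.all(draws == post[0])

    def test_uncertainty_none_copies_point_estimate(self):
        m = model_with([CovariateTerm()], [0.7])
        assert np.all(resample_parameters(m, 3, seed=0) == 0.7)

    def test_deterministic_given_seed(self):
        m = model_with([CovariateTerm()], [0.0], uncertainty=Uncertainty("se", [1.0]))
        a = resample_parameters(m, 10, seed=42)
        b = resample_parameters(m, 10, seed=42)
        assert np.array_equal(a, b)

    def test_non_psd_vcov_rejected(self):
        with pytest.raises(ConfigError, match="positive semidefinite"):
            model_with(
                [CovariateTerm(), CovariateTerm("temperature")], [0.0, 0.0],
                uncertainty=Uncertainty("vcov", np.array([[1.0, 2.0], [2.0, 1.0]])),
            )

    def test_vcov_empirical_covariance_converges(self):
        V = np.array([[1.0, 0.3], [0.3, 0.5]])
        m = model_with(
            [CovariateTerm(), CovariateTerm("temperature")], [0.0, 0.0],
            uncertainty=Uncertainty("vcov", V),
        )
        dists = []
        for n in (100, 10_000):
            draws = resample_parameters(m, n, seed=3)
            dists.append(np.linalg.norm(np.cov(draws.T) - V))
        assert dists[1] < dists[0]


class TestEnvironmentAtExtreme:
    def study(self, T=(0.0, 1.0, 2.0), R=(5.0, 7.0, 9.0), **kwargs):
        return two_stage_study(
            drivers=make_drivers(times=np.arange(len(T)), T=T, R=R), **kwargs
        )

    def test_full_covariation_takes_observed_values_at_extreme(self):
        env = environment_at_extreme(self.study(), "temperature", "max", "full")
        assert env.values == {"temperature": 2.0, "rainfall": 9.0}

    def test_reduced_covariation_takes_means(self):
        env = environment_at_extreme(self.study(), "temperature", "max", "reduced")
        assert env.values == {"temperature": 2.0, "rainfall": 7.0}

    def test_tied_extremes_take_earliest_year_vs_scan_oracle(self, rng):
        T = np.array([1.0, 3.0, 0.0, 3.0, 2.0])
        R = rng.normal(size=5)
        study = self.study(T=T, R=R)
        env = environment_at_extreme(study, "temperature", "max", "full")
        # brute-force scan: earliest index attaining the max
        idx = min(i for i in range(len(T)) if T[i] == T.max())
        assert env.values["rainfall"] == R[idx]

    def test_constant_focal_driver_is_undefined(self):
        study = self.study(T=(1.0, 1.0, 1.0))
        with pytest.raises(UndefinedSensitivityError):
            environment_at_extreme(study, "temperature", "max", "full")

    def test_density_fixed_pins_density_at_mean(self):
        dens = Driver("density", "intraspecific_density", np.arange(3), [10.0, 20.0, 60.0])
        study = self.study()
        study.populations[0].drivers.append(dens)
        env = environment_at_extreme(
            study, "temperature", "max", "full", density_handling="fixed"
        )
        assert env.values["density"] == pytest.approx(30.0)
        env2 = environment_at_extreme(
            study, "temperature", "max", "full", density_handling="covary"
        )
        assert env2.values["density"] == 60.0

    def test_year_set_only_when_year_effects_shared(self):
        study = self.study()
        assert environment_at_extreme(study, "temperature", "max", "full").year is None
        study.year_effects_shared = True
        assert environment_at_extreme(study, "temperature", "max", "full").year == 2

    def test_reduced_invariant_to_permuting_nonfocal_series_full_is_not(self, rng):
        T = rng.normal(size=8)
        R = rng.normal(size=8)
        study = self.study(T=T, R=R)
        perm = rng.permutation(8)
        study_perm = self.study(T=T, R=R[perm])
        red = environment_at_extreme(study, "temperature", "max", "reduced")
        red_p = environment_at_extreme(study_perm, "temperature", "max", "reduced")
        assert red.values == pytest.approx(red_p.values)
        # witness: full covariation depends on the time alignment
        full = environment_at_extreme(study, "temperature", "max", "full")
        full_p = environment_at_extreme(study_perm, "temperature", "max", "full")
        assert full.values["rainfall"] != pytest.approx(full_p.values["rainfall"])


class TestDriverAndStudyInvariants:
    def test_driver_summaries_recomputed_from_series(self):
        d = Driver("t", "temperature", np.arange(4), [1.0, 5.0, 3.0, 3.0])
        assert (d.d_min, d.d_max, d.d_mean) == (1.0, 5.0, 3.0)
        assert d.d_sd == pytest.approx(np.std([1, 5, 3, 3], ddof=1))
        assert d.perturbable

    def test_series_too_short_rejected(self):
        with pytest.raises(ConfigError, match="length"):
            Driver("t", "temperature", [0], [1.0])

    def test_study_needs_two_climatic_or_one_plus_biotic(self):
        lone = [Driver("temperature", "temperature", np.arange(5), np.arange(5.0))]
        with pytest.raises(ConfigError, match="climatic"):
            two_stage_study(drivers=lone)

    def test_density_modeled_reflects_terms(self, toy_study):
        assert not toy_study.density_modeled

    def test_misaligned_population_time_axes_rejected(self):
        with pytest.raises(ConfigError, match="time axis"):
            Population(
                "p",
                [
                    Driver("temperature", "temperature", np.arange(5), np.arange(5.0)),
                    Driver("rainfall", "rainfall", np.arange(1, 6), np.arange(5.0)),
                ],
            )
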