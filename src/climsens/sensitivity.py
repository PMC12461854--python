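"""Driver-perturbation protocol: scaled sensitivities of lambda.

The scaled sensitivity of population growth to a driver is

    |S| = | (lambda_max - lambda_min) / ((d_max - d_min) / SD_d) |

where lambda_max/lambda_min are growth rates with the focal driver at its
observed maximum/minimum and d_max, d_min, SD_d summarize the observed
driver series; the denominator expresses the driver range in SD units so
|S| is comparable across drivers and studies.  Scenarios control whether the
non-focal drivers covary (take their observed values in the extreme year)
or sit at their means, and whether intraspecific density is allowed to
covary or is pinned at its mean.  Parameter uncertainty is propagated by
resampling regression coefficients and recomputing lambda and |S| per draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedSensitivityError, VitalRateSkip
from .popmodel import lambda_for_study
from .study import (
    CLIMATIC_CATEGORIES,
    Environment,
    SpeciesStudy,
    environment_at_extreme,
    resample_parameters,
)


@dataclass
class PerturbationScenario:
    """Which driver is perturbed and how the rest of the environment behaves.

    density_handling must be 'not_applicable' exactly when the study does
    not model intraspecific density; scope='single:<rate>' restricts the
    perturbation to one vital rate (per-rate protocol).
    """

    focal_driver: str
    covariation: str = "full"  # 'full' | 'reduced'
    density_handling: str = "not_applicable"  # 'covary' | 'fixed' | 'not_applicable'
    scope: str = "all_vital_rates"

    def __post_init__(self):
        if self.covariation not in ("full", "reduced"):
            raise ConfigError("covariation must be 'full' or 'reduced'")
        if self.density_handling not in ("covary", "fixed", "not_applicable"):
            raise ConfigError("invalid density_handling")
        if not (
            self.scope == "all_vital_rates" or self.scope.startswith("single:")
        ):
            raise ConfigError("scope must be 'all_vital_rates' or 'single:<rate>'")

    def validate_for(self, study: SpeciesStudy):
        if (self.density_handling == "not_applicable") == study.density_modeled:
            raise ConfigError(
                "density_handling must be 'not_applicable' iff the study does "
                "not model intraspecific density"
            )
        if self.scope.startswith("single:"):
            rate = study.model(self.scope.split(":", 1)[1])
            refs = rate.referenced_drivers()
            cats = {d.name: d.category for d in study.population().drivers}
            has_focal = self.focal_driver in refs
            has_biotic = any(cats[r] not in CLIMATIC_CATEGORIES for r in refs)
            if not (has_focal or has_biotic):
                raise ConfigError(
                    f"single-rate scope requires the rate to contain the focal "
                    f"driver or a biotic driver; {rate.name!r} has neither"
                )


@dataclass
class SensitivityResult:
    """Resampled |S| values with their (lambda_max, lambda_min) provenance."""

    species: str
    population: str
    focal_driver: str
    scenario: PerturbationScenario
    samples: np.ndarray
    lambda_pairs: np.ndarray  # shape (n_samples, 2): lambda_max, lambda_min

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.lambda_pairs = np.asarray(self.lambda_pairs, dtype=float)
        if np.any(self.samples < 0):
            raise ConfigError("|S| samples must be nonnegative")
        if len(self.samples) != len(self.lambda_pairs):
            raise ConfigError("samples and lambda_pairs length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def log_response_ratios(self) -> np.ndarray:
        return np.array(
            [log_response_ratio(mx, mn) for mx, mn in self.lambda_pairs]
        )


def scaled_sensitivity(
    lambda_max: float, lambda_min: float, d_max: float, d_min: float, sd_d: float
) -> float:
    """|S| = |(lambda_max - lambda_min) / ((d_max - d_min) / SD_d)|."""
    if not (d_max > d_min) or not sd_d > 0:
        raise UndefinedSensitivityError(
            "undefined sensitivity: driver range or SD is zero"
        )
    return abs((lambda_max - lambda_min) / ((d_max - d_min) / sd_d))


def log_response_ratio(lambda_max: float, lambda_min: float) -> float:
    """ln(lambda_max / lambda_min), the classical meta-analysis effect size."""
    if lambda_max <= 0 or lambda_min <= 0:
        raise ConfigError("log response ratio requires positive growth rates")
    return math.log(lambda_max / lambda_min)


def _draws_for_study(study: SpeciesStudy, n_samples: int, rng) -> list[dict]:
    """One coefficient draw per vital-rate model per sample; the same draw
    is reused for the min and max evaluations within a sample (paired)."""
    per_model = {
        m.name: resample_parameters(m, n_samples, rng.integers(0, 2**31 - 1))
        for m in study.vital_rate_models
    }
    return [
        {name: mat[k] for name, mat in per_model.items()}
        for k in range(n_samples)
    ]


def sensitivity_for_driver(
    study: SpeciesStudy,
    scenario: PerturbationScenario,
    n_samples: int = 100,
    seed=None,
    population: Optional[str] = None,
    paired: bool = True,
    sim_options: Optional[dict] = None,
) -> SensitivityResult:
    """Resampled |S| for one focal driver under one scenario.

    For each parameter draw, the population model is built at the focal
    driver's minimum and maximum environments (per the scenario) and lambda
    is computed by the study's own method; the scaled-sensitivity formula is
    then applied.  With ``paired=True`` (default) the same draw is used for
    both extremes, isolating the driver effect from parameter noise.
    """
    scenario.validate_for(study)
    pop = study.population(population)
    focal = pop.driver(scenario.focal_driver)
    dh = scenario.density_handling
    dh_env = "covary" if dh == "not_applicable" else dh
    env_min = environment_at_extreme(
        study, focal.name, "min", scenario.covariation, dh_env, pop.name
    )
    env_max = environment_at_extreme(
        study, focal.name, "max", scenario.covariation, dh_env, pop.name
    )
    rng = np.random.default_rng(seed)
    draws_max = _draws_for_study(study, n_samples, rng)
    draws_min = draws_max if paired else _draws_for_study(study, n_samples, rng)
    sim = dict(sim_options or {})
    samples = np.empty(n_samples)
    pairs = np.empty((n_samples, 2))
    for k in range(n_samples):
        so = {**sim, "seed": rng.integers(0, 2**31 - 1)} if study.model_kind in ("IBM", "integrated") else sim
        try:
            lam_max = lambda_for_study(study, env_max, draws_max[k], sim_options=so).value
            lam_min = lambda_for_study(study, env_min, draws_min[k], sim_options=so).value
        except Exception as exc:
            raise type(exc)(f"sample {k}: {exc}") from exc
        samples[k] = scaled_sensitivity(
            lam_max, lam_min, focal.d_max, focal.d_min, focal.d_sd
        )
        pairs[k] = (lam_max, lam_min)
    return SensitivityResult(
        species=study.species,
        population=pop.name,
        focal_driver=focal.name,
        scenario=scenario,
        samples=samples,
        lambda_pairs=pairs,
    )


def sensitivity_per_vital_rate(
    study: SpeciesStudy,
    vital_rate: str,
    focal_driver: str,
    n_samples: int = 100,
    seed=None,
    population: Optional[str] = None,
    sim_options: Optional[dict] = None,
) -> SensitivityResult:
    """|S| from perturbing the focal driver in a single vital rate.

    The focal rate sees the extreme environment with full covariation; all
    other rates see every driver at its series mean.  Rates lacking the
    focal driver raise VitalRateSkip (the grid runner records a missing
    cell, mirroring how per-rate sensitivities are absent when a rate has no
    climatic covariate).
    """
    rate = study.model(vital_rate)
    if focal_driver not in rate.referenced_drivers():
        raise VitalRateSkip(
            f"vital rate {vital_rate!r} does not contain driver {focal_driver!r}"
        )
    pop = study.population(population)
    focal = pop.driver(focal_driver)
    mean_env = study.mean_environment(pop.name)
    env_min = environment_at_extreme(study, focal_driver, "min", "full", "covary", pop.name)
    env_max = environment_at_extreme(study, focal_driver, "max", "full", "covary", pop.name)
    others = {
        m.name: mean_env for m in study.vital_rate_models if m.name != vital_rate
    }
    rng = np.random.default_rng(seed)
    draws = _draws_for_study(study, n_samples, rng)
    samples = np.empty(n_samples)
    pairs = np.empty((n_samples, 2))
    for k in range(n_samples):
        lam_max = lambda_for_study(
            study, env_max, draws[k], env_by_rate=others, sim_options=sim_options
        ).value
        lam_min = lambda_for_study(
            study, env_min, draws[k], env_by_rate=others, sim_options=sim_options
        ).value
        samples[k] = scaled_sensitivity(
            lam_max, lam_min, focal.d_max, focal.d_min, focal.d_sd
        )
        pairs[k] = (lam_max, lam_min)
    return SensitivityResult(
        species=study.species,
        population=pop.name,
        focal_driver=focal_driver,
        scenario=PerturbationScenario(
            focal_driver=focal_driver,
            covariation="full",
            density_handling="covary" if study.density_modeled else "not_applicable",
            scope=f"single:{vital_rate}",
        ),
        samples=samples,
        lambda_pairs=pairs,
    )


def average_across_populations(results: list[SensitivityResult]) -> SensitivityResult:
    """Species-level |S|: sample-wise arithmetic mean across populations."""
    if not results:
        raise ConfigError("no per-population results to average")
    n = results[0].n_samples
    for r in results[1:]:
        if r.n_samples != n:
            raise ConfigError("mismatched n_samples across populations")
        if r.species != results[0].species or r.focal_driver != results[0].focal_driver:
            raise ConfigError("results must share species and focal driver")
    return SensitivityResult(
        species=results[0].species,
        population="average",
        focal_driver=results[0].focal_driver,
        scenario=results[0].scenario,
        samples=np.mean([r.samples for r in results], axis=0),
        lambda_pairs=np.mean([r.lambda_pairs for r in results], axis=0),
    )


def _result_rows(study: SpeciesStudy, res: SensitivityResult, vital_rate="all", rate_class="all"):
    pop = study.population(None if res.population == "average" else res.population)
    cat = pop.driver(res.focal_driver).category
    rows = []
    for k in range(res.n_samples):
        lam_max, lam_min = res.lambda_pairs[k]
        rows.append(
            {
                "species": res.species,
                "population": res.population,
                "taxon_group": study.taxon_group,
                "driver": res.focal_driver,
                "driver_category": cat,
                "covariation": res.scenario.covariation,
                "density_handling": res.scenario.density_handling,
                "density_in_model": study.density_modeled,
                "vital_rate": vital_rate,
                "rate_class": rate_class,
                "sample": k,
                "lambda_max": lam_max,
                "lambda_min": lam_min,
                "S": res.samples[k],
                "lrr": log_response_ratio(lam_max, lam_min)
                if lam_max > 0 and lam_min > 0
                else np.nan,
                "age_at_maturity": study.age_at_sexual_maturity,
                "n_vital_rates": study.n_vital_rates(),
                "mean_params_per_rate": study.mean_params_per_rate(),
            }
        )
    return rows


def scenario_grid(study: SpeciesStudy) -> list[PerturbationScenario]:
    """All covariation x density-handling scenarios for each perturbable
    climatic driver.  Density combinations are emitted only where the study
    models intraspecific density."""
    scenarios = []
    for d in study.climatic_drivers():
        if not d.perturbable:
            continue
        for cov in ("full", "reduced"):
            if study.density_modeled:
                for dh in ("covary", "fixed"):
                    scenarios.append(PerturbationScenario(d.name, cov, dh))
            else:
                scenarios.append(PerturbationScenario(d.name, cov, "not_applicable"))
    return scenarios


def run_scenario_grid(
    study: SpeciesStudy,
    n_samples: int = 100,
    seed=None,
    sim_options: Optional[dict] = None,
) -> pd.DataFrame:
    """Long-format |S| table over the full scenario grid, averaged across
    populations (sample-wise) when the study models several."""
    rows = []
    for i, scen in enumerate(scenario_grid(study)):
        per_pop = [
            sensitivity_for_driver(
                study, scen, n_samples,
                seed=np.random.SeedSequence([_entropy(seed), i, j]),
                population=p, sim_options=sim_options,
            )
            for j, p in enumerate(study.population_names)
        ]
        res = per_pop[0] if len(per_pop) == 1 else average_across_populations(per_pop)
        rows.extend(_result_rows(study, res))
    return pd.DataFrame(rows)


def run_per_rate_grid(
    study: SpeciesStudy,
    n_samples: int = 100,
    seed=None,
    sim_options: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-vital-rate |S| rows for every (climatic driver, rate) pair where
    the rate contains the driver; other pairs are skipped (missing cells)."""
    rows = []
    for i, d in enumerate(study.climatic_drivers()):
        if not d.perturbable:
            continue
        for j, m in enumerate(study.vital_rate_models):
            if m.rate_class == "trait_change":
                continue
            try:
                per_pop = [
                    sensitivity_per_vital_rate(
                        study, m.name, d.name, n_samples,
                        seed=np.random.SeedSequence([_entropy(seed), i, j, k]),
                        population=p, sim_options=sim_options,
                    )
                    for k, p in enumerate(study.population_names)
                ]
            except VitalRateSkip:
                continue
            res = per_pop[0] if len(per_pop) == 1 else average_across_populations(per_pop)
            rows.extend(_result_rows(study, res, vital_rate=m.name, rate_class=m.rate_class))
    return pd.DataFrame(rows)


def _entropy(seed) -> int:
    if seed is None:
        return 0
    if isinstance(seed, np.random.SeedSequence):
        e = seed.entropy
        return int(e[0] if isinstance(e, (list, tuple)) else e) % (2**31 - 1)
    return int(seed) % (2**31 - 1)
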