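"""Domain types for climate-driven demographic studies.

A *study* couples a species' life-cycle structure with (i) regression models
for its vital rates (survival, reproduction, trait change) whose covariates
are environmental drivers and/or individual state, and (ii) the observed
time series of those drivers.  The types here carry everything needed to
evaluate a vital rate in a given environment, to resample regression
parameters from their reported uncertainty, and to construct the extreme
environments used by driver-perturbation protocols: the focal driver at its
observed minimum or maximum while the remaining drivers either take their
observed values in the same year ("full" covariation) or sit at their means
("reduced" covariation), with intraspecific density optionally pinned at its
mean regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import (
    ConfigError,
    DomainError,
    IncompleteEnvironmentError,
    UndefinedSensitivityError,
)

DRIVER_CATEGORIES = (
    "temperature",
    "rainfall",
    "intraspecific_density",
    "interspecific_biotic",
)
CLIMATIC_CATEGORIES = ("temperature", "rainfall")

RATE_CLASSES = (
    "reproduction",
    "nonreproductive_survival",
    "reproductive_survival",
    "trait_change",
)

FAMILY_LINKS = (
    "binomial-logit",
    "poisson-log",
    "negative_binomial-log",
    "gaussian-identity",
    "gamma-log",
)

TRANSFORMATIONS = ("identity", "log", "standardized")

STATE_VARIABLES = ("size", "age", "stage")


@dataclass
class Driver:
    """An observed environmental driver series.

    ``times`` and ``values`` are aligned; the summary statistics used by
    perturbation protocols (min, max, mean, SD) are always recomputed from
    the series, so they cannot drift out of sync with it.  SD is the sample
    standard deviation (ddof=1).
    """

    name: str
    category: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.category not in DRIVER_CATEGORIES:
            raise ConfigError(
                f"driver {self.name!r}: unknown category {self.category!r}"
            )
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ConfigError(f"driver {self.name!r}: series length must be >= 2")
        if len(self.times) != len(self.values):
            raise ConfigError(f"driver {self.name!r}: times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError(f"driver {self.name!r}: non-finite values in series")

    @property
    def d_min(self) -> float:
        return float(np.min(self.values))

    @property
    def d_max(self) -> float:
        return float(np.max(self.values))

    @property
    def d_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def d_sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def perturbable(self) -> bool:
        return self.d_sd > 0 and self.d_max > self.d_min

    def value_at(self, time) -> float:
        idx = np.nonzero(self.times == time)[0]
        if len(idx) == 0:
            raise ConfigError(
                f"driver {self.name!r}: no observation at time {time!r}"
            )
        return float(self.values[idx[0]])

    def extreme_time(self, which: str):
        """Time of the series extreme; ties broken by earliest time index."""
        if which not in ("min", "max"):
            raise ValueError("which must be 'min' or 'max'")
        target = self.d_min if which == "min" else self.d_max
        idx = int(np.nonzero(self.values == target)[0][0])
        return self.times[idx]


@dataclass
class Environment:
    """Driver values (native scale) at which vital rates are evaluated.

    ``driver_stats`` carries the (mean, sd) of each driver's *observed*
    series so that 'standardized' covariate transformations always use the
    stored statistics, never statistics recomputed from perturbed values.
    """

    values: dict[str, float]
    year: Optional[object] = None
    driver_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ConfigError(f"environment value for {name!r} is not finite")


@dataclass
class CovariateTerm:
    """One term of a linear predictor.

    ``driver_or_state`` is a driver name, one of the individual-state
    variables ('size', 'age', 'stage'), or None for the intercept.
    ``interaction_with`` lists further CovariateTerms whose (transformed)
    values multiply into this term.
    """

    driver_or_state: Optional[str] = None
    is_state: bool = False
    transformation: str = "identity"
    interaction_with: tuple = ()
    coefficient_index: Optional[int] = None

    def __post_init__(self):
        if self.transformation not in TRANSFORMATIONS:
            raise ConfigError(f"unknown transformation {self.transformation!r}")
        if self.is_state and self.driver_or_state not in STATE_VARIABLES:
            raise ConfigError(
                f"unknown state variable {self.driver_or_state!r}; "
                f"expected one of {STATE_VARIABLES}"
            )
        self.interaction_with = tuple(self.interaction_with)

    @property
    def is_intercept(self) -> bool:
        return self.driver_or_state is None

    def referenced_drivers(self) -> set[str]:
        refs = set()
        if self.driver_or_state is not None and not self.is_state:
            refs.add(self.driver_or_state)
        for sub in self.interaction_with:
            refs |= sub.referenced_drivers()
        return refs

    def _factor_value(self, env: Environment, state) -> float:
        if self.is_intercept:
            return 1.0
        if self.is_state:
            if state is None:
                raise DomainError(
                    f"term references state {self.driver_or_state!r} but no "
                    "state value was supplied"
                )
            x = float(state)
        else:
            if self.driver_or_state not in env.values:
                raise IncompleteEnvironmentError(
                    f"incomplete environment: no value for driver "
                    f"{self.driver_or_state!r}"
                )
            x = env.values[self.driver_or_state]
        if self.transformation == "log":
            if x <= 0:
                raise DomainError(
                    f"log transform of non-positive value {x} for "
                    f"{self.driver_or_state!r}"
                )
            return float(np.log(x))
        if self.transformation == "standardized":
            stats = env.driver_stats.get(self.driver_or_state)
            if stats is None:
                raise IncompleteEnvironmentError(
                    f"no stored series statistics for standardized driver "
                    f"{self.driver_or_state!r}"
                )
            mean, sd = stats
            if sd <= 0:
                raise UndefinedSensitivityError(
                    f"driver {self.driver_or_state!r} has zero SD; cannot standardize"
                )
            return (x - mean) / sd
        return x

    def value(self, env: Environment, state=None) -> float:
        v = self._factor_value(env, state)
        for sub in self.interaction_with:
            v *= sub._factor_value(env, state)
        return v


@dataclass
class Uncertainty:
    """Reported parameter uncertainty of a vital-rate regression.

    kind: 'none' | 'se' (per-coefficient SEs, independent normals) |
    'vcov' (multivariate normal) | 'posterior' (rows of an MCMC sample
    matrix, resampled with replacement).
    """

    kind: str = "none"
    values: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("none", "se", "vcov", "posterior"):
            raise ConfigError(f"unknown uncertainty kind {self.kind!r}")
        if self.kind != "none":
            if self.values is None:
                raise ConfigError(f"uncertainty kind {self.kind!r} requires values")
            self.values = np.asarray(self.values, dtype=float)


@dataclass
class VitalRateModel:
    """One regression model for one demographic rate.

    ``applicable_domain`` restricts where the model applies: a sequence of
    stage labels (matrix/individual-based models) or a (lo, hi) size
    interval (integral projection models); None means unrestricted.
    ``year_effect`` maps year identifiers to deviations added on the
    linear-predictor scale.
    """

    name: str
    rate_class: str
    family_link: str
    terms: list[CovariateTerm]
    coefficients: np.ndarray
    uncertainty: Uncertainty = field(default_factory=Uncertainty)
    year_effect: Optional[dict] = None
    applicable_domain: Optional[object] = None

    def __post_init__(self):
        if self.rate_class not in RATE_CLASSES:
            raise ConfigError(
                f"model {self.name!r}: unknown rate_class {self.rate_class!r}"
            )
        if self.family_link not in FAMILY_LINKS:
            raise ConfigError(
                f"model {self.name!r}: unknown family_link {self.family_link!r}"
            )
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise ConfigError(
                f"model {self.name!r}: {len(self.coefficients)} coefficients "
                f"for {len(self.terms)} terms"
            )
        idx = [t.coefficient_index for t in self.terms if t.coefficient_index is not None]
        if len(idx) != len(set(idx)):
            raise ConfigError(f"model {self.name!r}: duplicate coefficient_index")
        u = self.uncertainty
        if u.kind == "se" and len(u.values) != len(self.coefficients):
            raise ConfigError(f"model {self.name!r}: SE vector length mismatch")
        if u.kind == "vcov":
            V = u.values
            if V.shape != (len(self.coefficients),) * 2:
                raise ConfigError(f"model {self.name!r}: vcov shape mismatch")
            if not np.allclose(V, V.T, atol=1e-10):
                raise ConfigError(f"model {self.name!r}: vcov not symmetric")
            if np.min(np.linalg.eigvalsh(0.5 * (V + V.T))) < -1e-10:
                raise ConfigError(f"model {self.name!r}: vcov not positive semidefinite")
        if u.kind == "posterior" and u.values.shape[1] != len(self.coefficients):
            raise ConfigError(f"model {self.name!r}: posterior column count mismatch")

    def referenced_drivers(self) -> set[str]:
        refs = set()
        for t in self.terms:
            refs |= t.referenced_drivers()
        return refs

    def applies_to(self, state) -> bool:
        """Domain check: numeric (lo, hi) intervals are checked against
        numeric states, stage-label collections against string states;
        mismatched kinds (e.g. a numeric stage index against a label domain)
        are the caller's responsibility and pass here."""
        dom = self.applicable_domain
        if dom is None or state is None:
            return True
        numeric_dom = (
            isinstance(dom, (list, tuple))
            and len(dom) == 2
            and all(isinstance(x, (int, float)) and not isinstance(x, bool) for x in dom)
        )
        if numeric_dom:
            if isinstance(state, (int, float)):
                lo, hi = dom
                return lo <= float(state) <= hi
            return True
        if isinstance(state, str):
            return state in dom
        return True


def linear_predictor(
    model: VitalRateModel, env: Environment, state=None, coefficients=None
) -> float:
    coefs = model.coefficients if coefficients is None else coefficients
    eta = 0.0
    for c, term in zip(coefs, model.terms):
        eta += c * term.value(env, state)
    if model.year_effect and env.year is not None:
        eta += model.year_effect.get(env.year, 0.0)
    return float(eta)


def predict_vital_rate(
    model: VitalRateModel, env: Environment, state=None, coefficients=None
) -> float:
    """Evaluate a vital-rate regression at an environment and state.

    Returns the rate on the response scale (inverse link applied); the
    year-effect deviation for ``env.year`` is added on the linear-predictor
    scale when the model declares one.
    """
    if state is not None and not model.applies_to(state):
        raise DomainError(
            f"state {state!r} outside applicable domain of model {model.name!r}"
        )
    eta = linear_predictor(model, env, state, coefficients)
    link = model.family_link.rsplit("-", 1)[1]
    if link == "logit":
        return float(expit(eta))
    if link == "log":
        return float(np.exp(eta))
    return eta


def resample_parameters(
    model: VitalRateModel, n: int, seed=None
) -> np.ndarray:
    """Draw ``n`` coefficient vectors from the model's reported uncertainty.

    SE vectors give independent normals around the point estimate, vcov a
    multivariate normal, posterior matrices uniform resampling of rows with
    replacement, and 'none' n copies of the point estimate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = model.uncertainty
    point = model.coefficients
    if u.kind == "none":
        return np.tile(point, (n, 1))
    if u.kind == "se":
        return point + rng.standard_normal((n, len(point))) * u.values
    if u.kind == "vcov":
        return rng.multivariate_normal(point, u.values, size=n, method="eigh")
    rows = rng.integers(0, u.values.shape[0], size=n)
    return u.values[rows]


@dataclass
class Population:
    """One population of a study: its identifier and driver series.

    Driver series within a population share the time axis (validated), which
    is how 'observed values of other drivers at the focal extreme' are
    aligned across drivers.
    """

    name: str
    drivers: list[Driver]

    def __post_init__(self):
        times = None
        for d in self.drivers:
            if times is None:
                times = d.times
            elif len(d.times) != len(times) or not np.all(d.times == times):
                raise ConfigError(
                    f"population {self.name!r}: driver {d.name!r} time axis "
                    "differs from the other drivers"
                )
        names = [d.name for d in self.drivers]
        if len(names) != len(set(names)):
            raise ConfigError(f"population {self.name!r}: duplicate driver names")

    def driver(self, name: str) -> Driver:
        for d in self.drivers:
            if d.name == name:
                return d
        raise ConfigError(f"population {self.name!r}: no driver named {name!r}")


@dataclass
class SpeciesStudy:
    """A species' life cycle, vital-rate models, drivers and metadata.

    ``structure`` is an ordered list of stage labels for matrix and
    individual-based models, or a dict {'L':, 'U':, 'mesh_size':} for
    integral projection models.  ``matrix_map`` (MPM/IBM) lists cells
    {'from':, 'to':, 'rates': [...], 'kind': 'survival'|'fecundity'}: the
    cell value is the product of the named rates evaluated at the source
    stage, cells repeated at a position add.  ``kernel_map`` (IPM) names the
    roles survival/growth/recruitment plus recruit-size distribution.
    """

    species: str
    taxon_group: str
    age_at_sexual_maturity: float
    model_kind: str
    structure: object
    vital_rate_models: list[VitalRateModel]
    populations: list[Population]
    matrix_map: Optional[list[dict]] = None
    kernel_map: Optional[dict] = None
    year_effects_shared: bool = False

    def __post_init__(self):
        if self.taxon_group not in ("bird", "mammal", "plant"):
            raise ConfigError(f"unknown taxon_group {self.taxon_group!r}")
        if self.model_kind not in ("MPM", "IPM", "IBM", "integrated"):
            raise ConfigError(f"unknown model_kind {self.model_kind!r}")
        if not self.age_at_sexual_maturity > 0:
            raise ConfigError("age_at_sexual_maturity must be > 0")
        if len(self.vital_rate_models) < 2:
            raise ConfigError(
                "study must declare at least two vital-rate models "
                "(selection criterion: >=2 vital rates)"
            )
        if not self.populations:
            raise ConfigError("study must declare at least one population")
        names = [m.name for m in self.vital_rate_models]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate vital-rate model names")
        # selection rule: >=2 climatic drivers, or 1 climatic + 1 biotic
        cats = [d.category for d in self.populations[0].drivers]
        n_clim = sum(c in CLIMATIC_CATEGORIES for c in cats)
        n_biotic = sum(c not in CLIMATIC_CATEGORIES for c in cats)
        if not (n_clim >= 2 or (n_clim >= 1 and n_biotic >= 1)):
            raise ConfigError(
                "driver set must contain at least two climatic drivers or "
                "one climatic and one biotic driver"
            )
        driver_names = {d.name for d in self.populations[0].drivers}
        for m in self.vital_rate_models:
            missing = m.referenced_drivers() - driver_names
            if missing:
                raise ConfigError(
                    f"model {m.name!r} references unknown drivers {sorted(missing)}"
                )
        if self.model_kind in ("MPM", "IBM", "integrated") and self.matrix_map:
            stages = set(self.stages)
            for cell in self.matrix_map:
                if cell["from"] not in stages or cell["to"] not in stages:
                    raise ConfigError(
                        f"matrix_map cell {cell} references unknown stage"
                    )
                for r in cell["rates"]:
                    if r not in names:
                        raise ConfigError(
                            f"matrix_map cell references undefined rate {r!r}"
                        )

    @property
    def stages(self) -> list[str]:
        if self.model_kind == "IPM":
            raise ConfigError("IPM studies have a size domain, not stages")
        return list(self.structure)

    @property
    def density_modeled(self) -> bool:
        dens = {
            d.name
            for d in self.populations[0].drivers
            if d.category == "intraspecific_density"
        }
        return any(m.referenced_drivers() & dens for m in self.vital_rate_models)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def population(self, name: Optional[str] = None) -> Population:
        if name is None:
            return self.populations[0]
        for p in self.populations:
            if p.name == name:
                return p
        raise ConfigError(f"no population named {name!r}")

    def model(self, name: str) -> VitalRateModel:
        for m in self.vital_rate_models:
            if m.name == name:
                return m
        raise ConfigError(f"no vital-rate model named {name!r}")

    def climatic_drivers(self, population: Optional[str] = None) -> list[Driver]:
        return [
            d
            for d in self.population(population).drivers
            if d.category in CLIMATIC_CATEGORIES
        ]

    def n_vital_rates(self) -> int:
        return len(self.vital_rate_models)

    def mean_params_per_rate(self) -> float:
        return float(
            np.mean([len(m.coefficients) for m in self.vital_rate_models])
        )

    def _stats(self, pop: Population) -> dict[str, tuple[float, float]]:
        return {d.name: (d.d_mean, d.d_sd) for d in pop.drivers}

    def mean_environment(self, population: Optional[str] = None) -> Environment:
        pop = self.population(population)
        return Environment(
            values={d.name: d.d_mean for d in pop.drivers},
            year=None,
            driver_stats=self._stats(pop),
        )

    def environment_at_time(self, time, population: Optional[str] = None) -> Environment:
        pop = self.population(population)
        return Environment(
            values={d.name: d.value_at(time) for d in pop.drivers},
            year=time if self.year_effects_shared else None,
            driver_stats=self._stats(pop),
        )


def environment_at_extreme(
    study: SpeciesStudy,
    focal: str,
    which: str,
    covariation: str = "full",
    density_handling: str = "covary",
    population: Optional[str] = None,
) -> Environment:
    """Environment with the focal driver at its observed extreme.

    covariation='full': other drivers take their observed values at the
    (earliest) time the focal extreme occurs; 'reduced': other drivers sit
    at their series means.  density_handling='fixed' pins intraspecific
    density drivers at their means regardless of covariation.  env.year is
    the extreme year iff the study models year effects shared across vital
    rates.
    """
    if covariation not in ("full", "reduced"):
        raise ValueError("covariation must be 'full' or 'reduced'")
    if density_handling not in ("covary", "fixed"):
        raise ValueError("density_handling must be 'covary' or 'fixed'")
    pop = study.population(population)
    focal_driver = pop.driver(focal)
    if not focal_driver.perturbable:
        raise UndefinedSensitivityError(
            f"driver {focal!r} is constant (zero SD); sensitivity undefined"
        )
    t_star = focal_driver.extreme_time(which)
    values = {}
    for d in pop.drivers:
        if d.name == focal:
            values[d.name] = d.d_min if which == "min" else d.d_max
        elif d.category == "intraspecific_density" and density_handling == "fixed":
            values[d.name] = d.d_mean
        elif covariation == "full":
            values[d.name] = d.value_at(t_star)
        else:
            values[d.name] = d.d_mean
    return Environment(
        values=values,
        year=t_star if study.year_effects_shared else None,
        driver_stats=study._stats(pop),
    )


def with_coefficients(model: VitalRateModel, coefficients) -> VitalRateModel:
    """A copy of the model with replaced point-estimate coefficients."""
    return replace(model, coefficients=np.asarray(coefficients, dtype=float))
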