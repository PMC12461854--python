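import numpy as np
import pytest
from scipy.special import logit

from climsens.study import (
    CovariateTerm,
    Driver,
    Population,
    SpeciesStudy,
    Uncertainty,
    VitalRateModel,
)


def make_drivers(times=None, T=None, R=None, extra=None):
    times = np.arange(10) if times is None else np.asarray(times)
    T = np.linspace(-1.5, 1.5, len(times)) if T is None else np.asarray(T, float)
    R = np.linspace(1.0, -1.0, len(times)) if R is None else np.asarray(R, float)
    drivers = [
        Driver("temperature", "temperature", times, T),
        Driver("rainfall", "rainfall", times, R),
    ]
    if extra:
        drivers.extend(extra)
    return drivers


def intercept_only(name, rate_class, family_link, value, domain=None, se=None):
    unc = Uncertainty("se", np.array([se])) if se is not None else Uncertainty()
    return VitalRateModel(
        name, rate_class, family_link, [CovariateTerm()], [value],
        uncertainty=unc, applicable_domain=domain,
    )


def two_stage_study(
    s_j=0.5,
    fec=2.0,
    s_a=0.0,
    fec_temp_slope=0.0,
    sj_rain_slope=0.0,
    drivers=None,
    model_kind="MPM",
    se=None,
):
    """Juvenile/adult life cycle: J survives into A with s_j, A reproduces
    into J with fec (optionally temperature-dependent on the log scale) and
    survives with s_a.  The default (0.5, 2, 0) has lambda = 1 exactly."""
    drivers = drivers if drivers is not None else make_drivers()
    fec_terms = [CovariateTerm()]
    fec_coefs = [np.log(fec)]
    if fec_temp_slope:
        fec_terms.append(CovariateTerm("temperature"))
        fec_coefs.append(fec_temp_slope)
    sj_terms = [CovariateTerm()]
    sj_coefs = [logit(s_j)]
    if sj_rain_slope:
        sj_terms.append(CovariateTerm("rainfall"))
        sj_coefs.append(sj_rain_slope)
    unc = (
        Uncertainty("se", np.full(len(fec_coefs), se))
        if se is not None
        else Uncertainty()
    )
    unc_sj = (
        Uncertainty("se", np.full(len(sj_coefs), se))
        if se is not None
        else Uncertainty()
    )
    models = [
        VitalRateModel(
            "juvenile_survival", "nonreproductive_survival", "binomial-logit",
            sj_terms, sj_coefs, uncertainty=unc_sj, applicable_domain=["J"],
        ),
        VitalRateModel(
            "recruitment", "reproduction", "poisson-log",
            fec_terms, fec_coefs, uncertainty=unc, applicable_domain=["A"],
        ),
    ]
    matrix_map = [
        {"from": "J", "to": "A", "rates": ["juvenile_survival"]},
        {"from": "A", "to": "J", "rates": ["recruitment"], "kind": "fecundity"},
    ]
    if s_a:
        models.append(
            intercept_only(
                "adult_survival", "reproductive_survival", "binomial-logit",
                logit(s_a), domain=["A"],
            )
        )
        matrix_map.append({"from": "A", "to": "A", "rates": ["adult_survival"]})
    return SpeciesStudy(
        species="toy",
        taxon_group="bird",
        age_at_sexual_maturity=1.0,
        model_kind=model_kind,
        structure=["J", "A"],
        vital_rate_models=models,
        populations=[Population("pop1", drivers)],
        matrix_map=matrix_map,
    )


@pytest.fixture
def toy_study():
    return two_stage_study()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
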