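"""Scaled sensitivity of lambda to a climatic driver under four scenarios.

Generates one synthetic species whose vital rates respond to correlated
temperature and rainfall drivers and to its own (negative) density feedback,
then perturbs temperature between its observed extremes while (i) letting
the other drivers covary vs. holding them at their means, and (ii) letting
observed density covary vs. pinning it at its mean.  Covariation of
same-sign climate effects amplifies |S|; density covariation buffers it.
"""

from climsens import PerturbationScenario, sensitivity_for_driver
from climsens.synthetic import SyntheticConfig, generate_species

config = SyntheticConfig(
    density_fraction=1.0, same_sign_effects=True, coefficient_se=0.0
)
study, truth = generate_species(config, seed=7)
print(
    f"species {study.species}: {study.taxon_group}, age at maturity "
    f"{study.age_at_sexual_maturity:.1f} y, lambda at mean environment "
    f"{truth.lambda_mean_env:.3f}"
)

for covariation, density in [
    ("full", "covary"), ("full", "fixed"),
    ("reduced", "covary"), ("reduced", "fixed"),
]:
    scen = PerturbationScenario("temperature", covariation, density)
    res = sensitivity_for_driver(study, scen, n_samples=1, seed=0)
    print(
        f"covariation={covariation:7s} density={density:6s} -> "
        f"|S| = {res.samples[0]:.4f}  "
        f"(lambda_max={res.lambda_pairs[0][0]:.4f}, "
        f"lambda_min={res.lambda_pairs[0][1]:.4f})"
    )
print(
    "full covariation raises |S| relative to the reduced scenario, while\n"
    "letting density covary lowers it relative to holding density fixed"
)
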