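# climsens

Comparative sensitivity analysis of structured populations to climatic
drivers, for population ecologists and comparative demographers who work
with vital-rate regression models.

Natural populations respond to climate through its effects on stage-, age-
or size-specific survival and reproduction, and those effects are filtered
by correlations among drivers (hot years are often dry years) and by density
feedbacks (a bad year for survival is also a year with less competition).
`climsens` rebuilds structured population models — matrix population models
(MPM), integral projection models (IPM) and individual-based models (IBM) —
from published vital-rate regressions and observed driver series, and asks:
how much does the population growth rate λ move when one climatic driver
swings over its observed range, depending on what the rest of the
environment is doing?

The core statistic is the scaled sensitivity

    |S| = | (λ_max − λ_min) / ((d_max − d_min) / SD_d) |

where λ_max, λ_min are growth rates with the focal driver at its observed
maximum and minimum and the denominator is the driver range in SD units,
making |S| comparable across drivers and species. Scenarios control whether
the other drivers covary with the focal extreme (take their observed values
in that year) or sit at their means, and whether intraspecific density
covaries or is held fixed. Parameter uncertainty is propagated by resampling
regression coefficients (SEs, vcov, or posterior draws) and recomputing λ
and |S| per draw. Across species, the resampled |S| values are meta-regressed
with a Gamma log-link mixed model (Laplace maximum likelihood, nested random
intercepts by taxonomic group and species, random covariation slopes,
Nakagawa-style marginal/conditional R²) against driver covariation, density
feedback, life-history speed (log age at sexual maturity) and
model-complexity controls.

A synthetic meta-dataset generator with a known ground-truth ledger emulates
the structure of a real comparative archive (three taxa, ages at maturity
1–20 y, correlated climate drivers, endogenous density series), so the whole
pipeline is testable end to end without any download.

## Worked example

`examples/02_perturbation_scenarios.py` generates one synthetic plant with a
density feedback and perturbs temperature under the four scenarios:

```
species sp684179: plant, age at maturity 10.2 y, lambda at mean environment 0.982
covariation=full    density=covary -> |S| = 0.0945  (lambda_max=1.2795, lambda_min=0.9098)
covariation=full    density=fixed  -> |S| = 0.1059  (lambda_max=1.3239, lambda_min=0.9094)
covariation=reduced density=covary -> |S| = 0.0793  (lambda_max=1.2272, lambda_min=0.9168)
covariation=reduced density=fixed  -> |S| = 0.0793  (lambda_max=1.2272, lambda_min=0.9168)
```

Reading the numbers: with full covariation the rainfall driver (correlated
with temperature, same-sign effect) swings together with the focal extreme,
so λ_max is higher and |S| larger than under reduced covariation (0.094 vs.
0.079) — measuring one driver in isolation underestimates the joint climate
response. Letting observed density covary with the extreme buffers the
response relative to pinning density at its mean (0.094 vs. 0.106): a good
climate year is also a crowded year, and the feedback claws part of the gain
back. Under reduced covariation every non-focal driver is at its mean, so
the density handling makes no difference.

The other examples build a toy two-stage model and verify the eigenvalue
against a stochastic simulation (`01_growth_rates.py`), and run the
meta-regression on a 12-species synthetic suite (`03_meta_analysis.py`).

The full pipeline is one call (or the `climsens all` CLI wrapper):

```python
from climsens import run_pipeline
from climsens.synthetic import SyntheticConfig

run_pipeline(SyntheticConfig(n_species=41, seed=1), seed=1,
             out_dir="run", n_samples=100)
```

which writes the study configs (`studies/*.yaml` + driver CSVs), the long
sensitivity tables (`sensitivities.csv`, `per_rate_sensitivities.csv`), the
fitted meta-regression tables (`table1.*`, `table2.*`) and a reproducibility
manifest. The same pipeline ingests a directory of hand-written study
configs (`ingest="path/"`) in place of the generator.

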