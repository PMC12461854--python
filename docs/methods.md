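# Methods

## The quantity being computed

For a structured population whose vital rates (survival, recruitment, trait
change) are regression functions of environmental drivers, the scaled
sensitivity of the annual population growth rate λ to a focal driver d is

    |S| = | (λ_max − λ_min) / ((d_max − d_min) / SD_d) |

where λ_max and λ_min are the growth rates with the focal driver set to its
observed maximum and minimum, and the denominator expresses the observed
driver range in standard-deviation units so that |S| is comparable across
drivers, species and study designs. SD_d is the sample standard deviation
(ddof = 1) of the observed series; the convention is not fixed by the
definition, and with ≥ 7 annual observations the choice moves |S| by < 8%.
The log response ratio ln(λ_max/λ_min) is provided as an alternative effect
size for robustness checks.

## Perturbation scenarios

Setting the focal driver to an extreme leaves a choice for every other
driver:

- **full covariation** — each non-focal driver takes its observed value in
  the year the focal extreme occurred (ties broken by the earliest year, so
  re-runs are deterministic and order-independent);
- **reduced covariation** — non-focal drivers sit at their series means;
- **density handling** — where intraspecific density is itself a model
  covariate, it either covaries like any other driver or is pinned at its
  mean ("fixed"), isolating how much density feedback moderates the climate
  response. Density drivers are identified by their category, never by name.

Drivers measured in the same population share a time axis (validated at
load), which is the alignment used for "observed value at the focal
extreme". When a study models year effects shared across vital rates, the
year of the focal extreme selects the year-effect level; studies without
shared year effects evaluate at zero year deviation.

In the per-vital-rate protocol the focal rate sees the extreme environment
with full covariation while every other rate sees all drivers at their
means; rates that do not contain the focal driver are skipped (a missing
cell, not a zero).

## Population models and λ

Matrix models evaluate each life-cycle cell as a declared product of vital
rates and take λ as the dominant eigenvalue. The eigenvalue is computed by
power iteration with an adaptive shift at the current Rayleigh estimate:
a positive shift makes the Perron root strictly dominant for cyclic life
cycles, and tying it to the current estimate (rather than to the largest
entry) preserves the spectral gap when fecundities are orders of magnitude
larger than survival probabilities. Convergence is a relative residual of
1e-10 with a stability-window fallback for clustered spectra (near-identity
kernels), where the Rayleigh quotient settles long before the eigenvector.

Integral projection models are discretized on a midpoint mesh; the growth
and recruit-size densities are renormalized within the size domain so no
probability mass is evicted at the boundaries (the simplest defensible
eviction correction; boundary bins are the alternative not taken).

Individual-based and integrated studies compute λ as the mean of simulated
annual growth ratios: replicated runs record N(t+1)/N(t) after a 10-year
burn-in that removes transient stage-structure effects, with the initial
population at the stable stage distribution of the mean-environment matrix
(both choices minimize transients; the protocol only fixes "at least 50
years from at least 100 simulations", which are the defaults). The default
estimator is the geometric mean (exp of mean log growth), the consistent
estimator of long-run stochastic growth; the arithmetic alternative is
available behind a flag for sensitivity-to-convention checks. Replicates
that go extinct contribute records up to extinction rather than being
dropped, which would bias λ upward. Demographic stochasticity is binomial /
multinomial for survival-transitions and Poisson for reproduction; a
deterministic expected-count reproduction mode exists for exact-arithmetic
tests. Simulation-based λ inside sensitivity loops uses n_reps = 100 and
n_years = 50 by default with a per-call override.

## Parameter uncertainty

Reported regression uncertainty is propagated by resampling coefficient
vectors — independent normals for SE vectors, a multivariate normal for a
variance–covariance matrix, uniform resampling with replacement for
posterior sample matrices (with replacement because the requested draw count
may exceed the stored posterior size) — and recomputing λ and |S| per draw
(100 draws by default). The same draw is used for the λ_max and λ_min
evaluations of one sample (paired perturbation), which isolates the driver
effect from parameter noise; unpaired draws are available via a flag.
Species with several populations are averaged sample-wise across
populations.

## The synthetic meta-dataset

The generator emulates the statistical structure of a comparative archive of
climate–demography studies; its defaults are fixed once and shared by tests
and the acceptance script:

- 41 species: 15 birds, 8 mammals, 18 plants (largest-remainder allocation);
- age at sexual maturity log-uniform on [1, 20] years; the life cycle is
  age-classified with round(age) juvenile classes and one adult class, adult
  survival rising with age at maturity (1 − 0.5/age, capped at 0.97) and
  recruitment solved so λ = 1 at the mean environment;
- 30 years of driver observations; a temperature-like and a rainfall-like
  standardized driver with cross-correlation ρ = 0.6 (the compound hot–dry
  motif) and interannual autocorrelation 0.4 (typical of annual climate
  anomalies);
- climate effect sizes N(0.3, 0.15) per SD of driver on the linear-predictor
  scale; each driver enters each rate with probability 0.85 (every driver is
  forced into at least one rate so the selection rule holds); reproduction
  effects scale with (age/4.5)^−0.5, implementing the faster-life-histories
  rely-more-on-reproduction coupling the meta-regression is designed to
  detect;
- 40% of species with ≥ 2 juvenile classes split juvenile survival into
  first-year and older-juvenile models, so the number of vital rates and
  parameters per rate vary across species and the model-complexity
  covariates are estimable;
- 13/41 of species carry a density feedback: a coefficient −|N(0.5, 0.15)|
  on log abundance in juvenile survival and recruitment (Ricker form; one
  canonical form keeps the ground truth tractable while preserving the
  buffering mechanism). The observed density series is produced by forward
  simulation of the generated model under the generated climate with
  within-interval (implicit) regulation: the rates over interval t respond
  to the density the population reaches during that interval, which is also
  the abundance recorded at the census alongside that year's climate. This
  makes observed density covary contemporaneously with climate — the pattern
  in field data where the census follows the season the drivers describe —
  and is solved per year as a damped fixed point (the negative feedback
  makes it a contraction).
- reported coefficients carry declared SEs of 0.05 for resampling; additive
  reporting noise on the coefficients themselves is available but off by
  default, separating estimator properties from generator properties.

Species whose λ at the mean environment falls outside [0.5, 1.5] are
regenerated (at most 100 attempts). Every species carries a truth-ledger
entry — true coefficients, λ at the mean environment, per-driver |S| under
full covariation — computed by brute force directly on the generating model
(logistic/exponential evaluation plus a dense eigensolver), independent of
the study-model machinery, and the engine is required to agree with it to
1e-8 on noiseless studies.

What the generator does not emulate: multi-population structure with
distinct driver series (supported by the pipeline, exercised by toy
fixtures), year random effects, posterior-matrix uncertainty, interspecific
biotic drivers (category supported, generator stub), trait-change rates, and
any real species' parameter values. Passing tests therefore demonstrate that
the machinery is correct and that the designed mechanisms (covariation
amplification, density buffering, life-history scaling) propagate through
the full pipeline — not that any particular field system behaves this way.

## The Gamma log-link mixed model

|S| samples are strictly positive and right-skewed, so the meta-regression
assumes a Gamma response with log link: log E[S] = Xβ + Zb, with independent
Gaussian random effects grouped as nested intercepts (taxonomic group,
species) and — in the global model — the same nesting on the slope of the
covariation indicator. Random slopes are independent of the intercepts by
default (the correlated parameterization is a flag), and one variance is
estimated per term.

Estimation is maximum likelihood with a Laplace approximation of the
random-effect integral (REML is not well defined for non-Gaussian mixed
models; Laplace-ML is the standard choice and a documented source of small
discrepancies from other fitting machinery). The implementation proceeds in
two stages: (1) penalized IRLS profiles (β, b) jointly inside a bounded
quasi-Newton search over the variance components (parameterized as SDs, so
boundary variances are exactly reachable) and the Gamma shape; (2) a final
search over (β, SDs, log shape) jointly, with only the random-effect modes
solved inside, because the profiled stage ignores the determinant's
dependence on β, which shifts weakly identified fixed effects (typically the
intercept) by O(1e-3). Observed information (weights ν·y/μ, strictly
positive) is used throughout, including in the Laplace determinant. The
treatment coding sets covariation = yes and density = no as reference
levels, so "covariation_no" is the effect of reducing environmental
complexity. Wald z inference on the log-link scale; fixed-effect SEs come
from the β block of the inverse joint observed information. Fixed effects
that are constant or collinear in a given dataset (synthetic suites can hold
complexity covariates constant) are dropped with a warning before fitting.

Numerical safeguards: linear predictors are capped at |η| ≤ 500 (beyond
which exp over/underflows) with step halving; the inner Newton solver stops
on the gradient norm or when two consecutive steps gain less than the
float64 resolution of the objective (a stall means nothing further is
representable, even if the gradient test is unmet); variance SDs are floored
at e⁻⁸ and flagged as boundary below 1e-3.

Two independent oracles check the estimator: an adaptive Gauss–Hermite
quadrature fit (25 nodes, mode-centered and curvature-scaled) for the
single-random-intercept case, and R's glmmTMB on a fixture in the test
suite; agreement is required to 1e-3 on coefficients (observed agreement is
~1e-6).

Marginal and conditional R² are variance partitions on the latent log scale:
fixed-effect variance is var(Xβ̂) over the data; each random term contributes
σ̂²·mean(z²) (σ̂² for intercepts); the observation-level variance of the Gamma
log link is trigamma(shape) by default, with the lognormal approximation
ln(1 + 1/shape) behind a flag.

## Analysis layouts

The global analysis uses whole-model perturbations under default density
handling (density covarying where modeled): fixed effects covariation_no,
density_yes, log age at maturity, log number of vital rates, log mean
parameters per vital rate, and covariation_no × density_yes; nested random
intercepts and covariation slopes. The per-vital-rate analysis groups rates
into reproduction (reference), nonreproductive survival and reproductive
survival, excludes trait change, drops the covariation and density terms
(neither varies in that protocol), and adds age × class interactions. The
driver-type analysis adds a temperature-vs-rainfall indicator to the global
model, dropped with a warning when only one category is present. Rows with
|S| ≤ 0 (a driver with no effect in a noiseless fixture) fall outside the
Gamma support and are dropped with a count warning.

## Problem sizes and determinism

The default pipeline (41 species × 100 resamples × scenario grid) produces
≈ 16,400 global rows and ≈ 23,600 per-rate rows and runs in a few minutes on
one core; the test suite uses 10–60 species and 1–25 resamples per check,
sizes at which every assertion is already stable. All randomness flows from
one seed through counter-based per-(species, scenario) streams, so results
are reproducible independently of iteration order; rerunning the pipeline
with the same configuration and seed is byte-identical.

## Known limitations

- Laplace-ML slightly biases variance components downward on few groups
  (3 taxonomic groups is few); the quadrature oracle bounds the effect for
  intercept models.
- The eigenvalue accuracy guarantee (1e-9 against a dense solver) is for
  well-separated spectra; clustered spectra fall back to the
  stability-window rule with accuracy nearer 1e-6.
- Per-rate perturbation is not implemented for simulation-based λ
  (individual-based and integrated studies), mirroring the practice of
  computing per-rate sensitivities only where model structure permits.
- Categorical environments (good/bad, wet/dry) are out of scope by the
  selection rules; config validation rejects what it cannot represent
  rather than approximating it.
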