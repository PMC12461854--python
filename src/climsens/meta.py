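"""Meta-regression of scaled sensitivities across species.

Pools resampled |S| values from all species into Gamma log-link mixed
models.  The global analysis models |S| as a function of driver covariation
(reference level: covariation accounted for), whether intraspecific density
is in the vital-rate models (reference: no), log age at sexual maturity,
model-complexity controls (log number of vital rates, log mean parameters
per vital rate) and the covariation x density interaction, with nested
random intercepts by taxonomic group and species and the same nesting on
the covariation slope.  The per-vital-rate analysis replaces the
covariation/density terms with vital-rate class (reference: reproduction)
and its interaction with log age.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError
from .glmm import GLMMFit, RandomTerm, fit_gamma_glmm

RATE_CLASS_DUMMIES = {
    "nonreproductive_survival": "vr_nonreproductive_survival",
    "reproductive_survival": "vr_reproductive_survival",
}


def _drop_nonpositive(df: pd.DataFrame) -> pd.DataFrame:
    bad = int((df["S"] <= 0).sum())
    if bad:
        warnings.warn(
            f"dropping {bad} rows with |S| <= 0 (outside Gamma support)",
            stacklevel=3,
        )
    return df[df["S"] > 0].copy()


def prepare_table1_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Meta-rows for the global analysis from the long sensitivity table.

    Keeps whole-model perturbations under the default density handling
    (density covarying where modeled) and codes covariation_no = 1 for the
    reduced-complexity scenario, density_yes = 1 for species whose models
    include intraspecific density.
    """
    rows = df[
        (df["vital_rate"] == "all")
        & (df["density_handling"].isin(["covary", "not_applicable"]))
    ].copy()
    if rows.empty:
        raise ConfigError("no whole-model sensitivity rows found")
    rows = _drop_nonpositive(rows)
    rows["covariation_no"] = (rows["covariation"] == "reduced").astype(float)
    rows["density_yes"] = rows["density_in_model"].astype(float)
    rows["log_age"] = np.log(rows["age_at_maturity"].astype(float))
    rows["log_n_vital_rates"] = np.log(rows["n_vital_rates"].astype(float))
    rows["log_params_per_rate"] = np.log(rows["mean_params_per_rate"].astype(float))
    rows["covariation_no_x_density_yes"] = rows["covariation_no"] * rows["density_yes"]
    return rows


def _estimable(rows: pd.DataFrame, fixed: list[str]) -> list[str]:
    """Drop fixed-effect columns that are constant or linearly dependent on
    the intercept and the columns kept so far (with a warning); synthetic
    suites can hold complexity covariates constant across species."""
    kept: list[str] = []
    cols = [np.ones(len(rows))]
    for c in fixed:
        x = rows[c].to_numpy(float)
        trial = np.column_stack(cols + [x])
        if np.linalg.matrix_rank(trial) > len(cols):
            kept.append(c)
            cols.append(x)
        else:
            warnings.warn(
                f"dropping inestimable fixed effect {c!r} (constant or "
                "collinear in these data)",
                stacklevel=3,
            )
    return kept


TABLE1_FIXED = [
    "covariation_no",
    "density_yes",
    "log_age",
    "log_n_vital_rates",
    "log_params_per_rate",
    "covariation_no_x_density_yes",
]


def table1_analysis(df: pd.DataFrame, **glmm_kwargs) -> tuple[GLMMFit, str]:
    """Global GLMM of |S|: covariation, density, life-history speed and
    complexity controls, nested random intercepts and covariation slopes."""
    rows = prepare_table1_rows(df)
    random = [
        RandomTerm("taxon_group"),
        RandomTerm("species"),
        RandomTerm("taxon_group", "covariation_no"),
        RandomTerm("species", "covariation_no"),
    ]
    fit = fit_gamma_glmm(rows, "S", _estimable(rows, TABLE1_FIXED), random, **glmm_kwargs)
    return fit, format_glmm_table(
        fit, rows, title="Scaled sensitivities |S|: covariation, density and life history"
    )


def prepare_table2_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Meta-rows for the per-vital-rate analysis (trait change excluded,
    reproduction is the reference class)."""
    rows = df[df["rate_class"].isin(
        ["reproduction", "nonreproductive_survival", "reproductive_survival"]
    )].copy()
    if rows.empty:
        raise ConfigError("no per-vital-rate sensitivity rows found")
    rows = _drop_nonpositive(rows)
    rows["log_age"] = np.log(rows["age_at_maturity"].astype(float))
    rows["log_n_vital_rates"] = np.log(rows["n_vital_rates"].astype(float))
    rows["log_params_per_rate"] = np.log(rows["mean_params_per_rate"].astype(float))
    for cls, col in RATE_CLASS_DUMMIES.items():
        rows[col] = (rows["rate_class"] == cls).astype(float)
        rows[f"log_age_x_{col}"] = rows["log_age"] * rows[col]
    return rows


TABLE2_FIXED = [
    "vr_nonreproductive_survival",
    "vr_reproductive_survival",
    "log_age",
    "log_n_vital_rates",
    "log_params_per_rate",
    "log_age_x_vr_nonreproductive_survival",
    "log_age_x_vr_reproductive_survival",
]


def table2_analysis(df: pd.DataFrame, **glmm_kwargs) -> tuple[GLMMFit, str]:
    """Per-vital-rate GLMM of |S|: vital-rate class, life-history speed and
    their interaction, nested random intercepts (covariation is not varied
    in the per-rate protocol and density terms are excluded)."""
    rows = prepare_table2_rows(df)
    random = [RandomTerm("taxon_group"), RandomTerm("species")]
    fit = fit_gamma_glmm(rows, "S", _estimable(rows, TABLE2_FIXED), random, **glmm_kwargs)
    return fit, format_glmm_table(
        fit, rows, title="Per-vital-rate |S|: vital-rate class and life history"
    )


def driver_type_analysis(df: pd.DataFrame, **glmm_kwargs) -> tuple[GLMMFit, str]:
    """Global model plus a temperature-vs-rainfall driver-type effect.

    If the data contain a single driver category the term is inestimable and
    dropped with a warning (the fit reduces to the global model)."""
    rows = prepare_table1_rows(df)
    fixed = list(TABLE1_FIXED)
    cats = rows["driver_category"].unique()
    if len(cats) > 1:
        rows["driver_temperature"] = (rows["driver_category"] == "temperature").astype(float)
        fixed.append("driver_temperature")
    else:
        warnings.warn(
            f"single driver category {cats[0]!r}: temperature-vs-rainfall "
            "term dropped as inestimable",
            stacklevel=2,
        )
    random = [
        RandomTerm("taxon_group"),
        RandomTerm("species"),
        RandomTerm("taxon_group", "covariation_no"),
        RandomTerm("species", "covariation_no"),
    ]
    fit = fit_gamma_glmm(rows, "S", _estimable(rows, fixed), random, **glmm_kwargs)
    return fit, format_glmm_table(fit, rows, title="Driver-type analysis")


def format_glmm_table(fit: GLMMFit, rows: pd.DataFrame, title: str = "") -> str:
    """Plain-text report: coefficient, SE, p per fixed effect, variance per
    random term, R-squared footer, sample-size line."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    lines.append(f"{'Fixed effects':38s}{'Coefficient':>12s}{'SE':>10s}{'P-value':>10s}")
    for name, b, se, p in zip(fit.fixed_names, fit.beta, fit.se, fit.p_values):
        ptxt = "<0.001" if p < 0.001 else f"{p:.3f}"
        lines.append(f"{name:38s}{b:12.3f}{se:10.3f}{ptxt:>10s}")
    lines.append("")
    lines.append(f"{'Random effects':38s}{'Variance':>12s}{'SD':>10s}")
    for label, v in zip(fit.random_terms, fit.variances):
        lines.append(f"{label:38s}{v:12.4f}{math_sqrt(v):10.4f}")
    lines.append("")
    lines.append(f"Gamma shape: {fit.shape:.3f}   log-likelihood: {fit.loglik:.2f}")
    lines.append(
        f"Marginal R2: {fit.r2_marginal:.3f}   Conditional R2: {fit.r2_conditional:.3f}"
    )
    n_species = rows["species"].nunique() if "species" in rows else float("nan")
    n_groups = rows["taxon_group"].nunique() if "taxon_group" in rows else float("nan")
    lines.append(
        f"n_samples = {fit.n_obs}, n_species = {n_species}, n_groups = {n_groups}"
    )
    if fit.boundary:
        lines.append(f"boundary (near-zero) variances: {', '.join(fit.boundary)}")
    return "\n".join(lines)


def math_sqrt(v: float) -> float:
    return float(np.sqrt(v))


def coef_csv(fit: GLMMFit) -> pd.DataFrame:
    out = fit.coef_table().reset_index().rename(columns={"index": "term"})
    out["r2_marginal"] = fit.r2_marginal
    out["r2_conditional"] = fit.r2_conditional
    return out
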