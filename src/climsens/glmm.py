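"""Gamma log-link mixed models by Laplace-approximated maximum likelihood.

The response y > 0 is Gamma with shape nu and mean mu, log mu = X beta + Z b,
with independent Gaussian random effects b grouped into terms (random
intercepts and/or random slopes per grouping factor), one variance per term.
Estimation profiles (beta, b) by penalized iteratively reweighted least
squares (Newton on the joint penalized log-likelihood) inside an outer
derivative-free search over the variance components and the Gamma shape,
with the marginal likelihood approximated by a Laplace integral over b.

An independent, slower adaptive Gauss-Hermite quadrature fit is provided
for the single-random-intercept case as a cross-check oracle, and
variance-partition (marginal/conditional) R-squared uses the trigamma
observation-level variance for the Gamma log link (a lognormal
approximation, ln(1 + 1/shape), is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma
from scipy.stats import norm

from .errors import ConfigError, NonConvergenceError

_LOG_SD_MIN, _LOG_SD_MAX = -8.0, 4.0
_BOUNDARY_SD = 1e-3


@dataclass
class RandomTerm:
    """One random-effect term: an intercept (slope=None) or a random slope
    on a numeric column, grouped by the levels of ``group``."""

    group: str
    slope: Optional[str] = None

    @property
    def label(self) -> str:
        return self.group if self.slope is None else f"{self.group}:{self.slope}"


@dataclass
class GLMMFit:
    """Fitted Gamma log-link mixed model."""

    fixed_names: list
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    random_terms: list          # RandomTerm labels, fit order
    variances: np.ndarray       # one variance component per term
    shape: float                # Gamma shape (1 / dispersion)
    loglik: float
    n_obs: int
    group_counts: dict
    converged: bool
    boundary: list              # labels of components pinned near zero
    gradient_norm: float
    random_effects: dict = field(default_factory=dict, repr=False)
    fitted: Optional[np.ndarray] = field(default=None, repr=False)
    var_fixed: float = 0.0
    random_contribs: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)
    r2_marginal: Optional[float] = None
    r2_conditional: Optional[float] = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.beta,
                "se": self.se,
                "p_value": self.p_values,
            },
            index=self.fixed_names,
        )


def _gamma_loglik(y, mu, nu):
    if not np.all(mu > 0) or not np.all(np.isfinite(mu)):
        return -np.inf
    return float(
        np.sum(nu * np.log(nu * y / mu) - nu * y / mu - np.log(y))
        - len(y) * gammaln(nu)
    )


def fit_gamma_glm(y, X, tol=1e-10, max_iter=200):
    """Fixed-effects Gamma log-link GLM by IRLS; returns (beta, shape, ll).

    Shape is estimated from Pearson residuals; used for starting values and
    as the degenerate (zero random variance) reference fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(float(np.mean(y)), 1e-300))
    eta = X @ beta
    for _ in range(max_iter):
        mu = np.exp(eta)
        # log link: working response z = eta + (y - mu)/mu, weights mu^2/V(mu)=1
        z = eta + (y - mu) / mu
        beta_new, *_ = np.linalg.lstsq(X, z, rcond=None)
        eta_new = X @ beta_new
        if np.max(np.abs(eta_new - eta)) < tol * (1 + np.max(np.abs(eta))):
            beta, eta = beta_new, eta_new
            break
        beta, eta = beta_new, eta_new
    mu = np.exp(eta)
    dof = max(len(y) - X.shape[1], 1)
    dispersion = float(np.sum(((y - mu) / mu) ** 2) / dof)
    nu = 1.0 / max(dispersion, 1e-8)
    return beta, nu, _gamma_loglik(y, mu, nu)


class _REDesign:
    """Random-effects design exploiting the one-nonzero-per-term structure:
    each observation belongs to exactly one level of each grouping factor, so
    Z b, Z'r and Z'WZ reduce to grouped sums (bincount), avoiding any
    explicit sparse or dense Z."""

    def __init__(self, df: pd.DataFrame, terms: list[RandomTerm]):
        self.codes, self.values, self.sizes, self.slices, self.labels = [], [], [], [], []
        col0 = 0
        n = len(df)
        for term in terms:
            levels = pd.unique(df[term.group])
            level_index = {lv: i for i, lv in enumerate(levels)}
            self.codes.append(df[term.group].map(level_index).to_numpy(np.int64))
            self.values.append(
                np.ones(n)
                if term.slope is None
                else df[term.slope].to_numpy(dtype=float)
            )
            self.sizes.append(len(levels))
            self.slices.append(slice(col0, col0 + len(levels)))
            self.labels.append([f"{term.label}[{lv}]" for lv in levels])
            col0 += len(levels)
        self.q = col0
        self.n = n

    def zb(self, b):
        eta = np.zeros(self.n)
        for codes, vals, sl in zip(self.codes, self.values, self.slices):
            eta += vals * b[sl][codes]
        return eta

    def ztr(self, r):
        out = np.empty(self.q)
        for codes, vals, L, sl in zip(self.codes, self.values, self.sizes, self.slices):
            out[sl] = np.bincount(codes, weights=r * vals, minlength=L)
        return out

    def ztwz(self, w):
        H = np.zeros((self.q, self.q))
        k = len(self.codes)
        for i in range(k):
            ci, vi, Li, si = self.codes[i], self.values[i], self.sizes[i], self.slices[i]
            for j in range(i, k):
                cj, vj, Lj, sj = self.codes[j], self.values[j], self.sizes[j], self.slices[j]
                block = np.bincount(
                    ci * Lj + cj, weights=w * vi * vj, minlength=Li * Lj
                ).reshape(Li, Lj)
                H[si, sj] = block
                if j != i:
                    H[sj, si] = block.T
        return H

    def xtwz(self, X, w):
        p = X.shape[1]
        out = np.empty((p, self.q))
        for codes, vals, L, sl in zip(self.codes, self.values, self.sizes, self.slices):
            wv = w * vals
            for j in range(p):
                out[j, sl] = np.bincount(codes, weights=wv * X[:, j], minlength=L)
        return out


def _pirls(y, X, design, d_inv_diag, nu, beta0, b0, tol=1e-9, max_iter=100, offset=0.0):
    """Joint Newton (penalized IRLS) for (beta, b) at fixed variances/shape.

    Returns beta, b, mu, gradient norm at the optimum.  With an empty X
    this reduces to the random-effects-only solve at a fixed offset.
    """
    p, q = X.shape[1], design.q
    beta, b = beta0.copy(), b0.copy()
    eta = offset + X @ beta + design.zb(b)
    log_y_sum = float(np.sum(np.log(y)))
    n = len(y)

    def pen_ll(eta_, b_):
        if np.max(np.abs(eta_)) > 500:
            return -np.inf
        # Gamma log-likelihood written in eta to avoid per-call log(mu)
        return (
            n * (nu * math.log(nu) - float(gammaln(nu)))
            + (nu - 1.0) * log_y_sum
            - nu * float(np.sum(eta_))
            - nu * float(np.sum(y * np.exp(-eta_)))
            - 0.5 * float(b_ @ (d_inv_diag * b_))
        )

    current = pen_ll(eta, b)
    if not np.isfinite(current):
        # warm start landed in an overflow region; restart from a safe point
        beta = np.zeros(p)
        if p:
            beta[0] = math.log(max(float(np.mean(y)), 1e-300))
        b = np.zeros(q)
        eta = offset + X @ beta + design.zb(b)
        current = pen_ll(eta, b)
    gnorm = np.inf
    stalls = 0
    for _ in range(max_iter):
        mu = np.exp(eta)
        r = nu * (y / mu - 1.0)
        g_beta = X.T @ r
        g_b = design.ztr(r) - d_inv_diag * b
        gnorm = float(np.linalg.norm(np.concatenate([g_beta, g_b])))
        if gnorm < tol * (1 + abs(current)):
            break
        w = nu * y / mu  # observed information weights, positive for y > 0
        H11 = X.T @ (X * w[:, None])
        H12 = design.xtwz(X, w) if q else np.zeros((p, 0))
        H22 = design.ztwz(w) + np.diag(d_inv_diag) if q else np.zeros((0, 0))
        H = np.block([[H11, H12], [H12.T, H22]])
        g = np.concatenate([g_beta, g_b])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p + q), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _half in range(30):
            beta_n = beta + t * step[:p]
            b_n = b + t * step[p:]
            eta_n = offset + X @ beta_n + design.zb(b_n)
            new = pen_ll(eta_n, b_n)
            if np.isfinite(new) and new >= current - 1e-12:
                break
            t *= 0.5
        else:
            break  # no admissible step; stop at the current point
        beta, b, eta = beta_n, b_n, eta_n
        # stall detection: near the mode each Newton step gains less than
        # the float64 resolution of the objective; iterating further cannot
        # improve the result, even if the gradient-norm test is not yet met
        if new - current <= 1e-12 * (1 + abs(current)):
            stalls += 1
            if stalls >= 2:
                current = new
                break
        else:
            stalls = 0
        current = new
    mu = np.exp(eta)
    return beta, b, mu, gnorm


def _laplace_loglik(y, X, design, sds, nu, state, beta_fixed=None):
    """Laplace-approximate marginal log-likelihood at given SDs and shape;
    warm-starts the inner PIRLS from ``state`` and updates it in place.

    With ``beta_fixed`` the fixed effects are held at the given values and
    only the random-effect modes are solved (the exact Laplace objective for
    an outer optimizer over beta); otherwise beta is profiled jointly with b.
    """
    q = design.q
    d_inv = np.empty(q)
    log_det_D = 0.0
    for sl, sd in zip(design.slices, sds):
        v = max(sd, math.exp(_LOG_SD_MIN)) ** 2
        d_inv[sl] = 1.0 / v
        log_det_D += (sl.stop - sl.start) * math.log(v)
    if beta_fixed is None:
        beta, b, mu, gnorm = _pirls(
            y, X, design, d_inv, nu, state["beta"], state["b"]
        )
    else:
        beta = np.asarray(beta_fixed, float)
        _, b, mu, gnorm = _pirls(
            y, np.zeros((len(y), 0)), design, d_inv, nu,
            np.zeros(0), state["b"], offset=X @ beta,
        )
    state["beta"], state["b"], state["gnorm"] = beta, b, gnorm
    w = nu * y / mu
    H22 = design.ztwz(w) + np.diag(d_inv)
    sign, logdet_H = np.linalg.slogdet(H22)
    if sign <= 0:
        return -np.inf
    ll = (
        _gamma_loglik(y, mu, nu)
        - 0.5 * float(b @ (d_inv * b))
        - 0.5 * (log_det_D + logdet_H)
    )
    return ll


def fit_gamma_glmm(
    df: pd.DataFrame,
    response: str,
    fixed: list[str],
    random: list[RandomTerm],
    add_intercept: bool = True,
    maxiter: int = 2000,
    xatol: float = 1e-6,
    fatol: float = 1e-8,
) -> GLMMFit:
    """Fit the Gamma log-link mixed model by Laplace ML.

    ``fixed`` names numeric columns of ``df`` (categorical predictors are
    supplied as treatment-coded dummy columns by the caller); an intercept
    is prepended by default.  Starting values come from the fixed-effects
    Gamma GLM.  Deterministic given the data.
    """
    y = df[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ConfigError("Gamma response must be strictly positive")
    X = df[fixed].to_numpy(dtype=float)
    names = list(fixed)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["Intercept"] + names
    design = _REDesign(df, random)

    beta0, nu0, _ = fit_gamma_glm(y, X)
    state = {"beta": beta0, "b": np.zeros(design.q), "gnorm": np.inf}

    # outer search over raw SDs (bounded at 0, so boundary variances are
    # exactly reachable) and log shape
    x0 = np.concatenate([np.full(len(random), 0.3), [math.log(nu0)]])
    bounds = [(0.0, 50.0)] * len(random) + [(-10.0, 12.0)]

    def objective(x):
        sds = np.maximum(x[:-1], math.exp(_LOG_SD_MIN))
        nu_ = math.exp(float(np.clip(x[-1], -10, 12)))
        ll = _laplace_loglik(y, X, design, sds, nu_, state)
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": fatol, "gtol": 1e-9},
    )
    res_nm = minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol, "adaptive": True},
    )
    if res_nm.fun < res.fun:
        res = res_nm
    objective(res.x)  # sync `state` with the profiled optimum

    # second stage: exact Laplace ML over (beta, sds, log shape) jointly --
    # the profiled stage ignores the determinant's dependence on beta, which
    # shifts weakly identified fixed effects (typically the intercept) by
    # O(1e-3); here beta is an outer parameter and only b is solved inside
    p = X.shape[1]
    x0_full = np.concatenate([state["beta"], res.x])
    bounds_full = [(None, None)] * p + bounds

    def objective_full(x):
        sds_ = np.maximum(x[p:-1], math.exp(_LOG_SD_MIN))
        nu_ = math.exp(float(np.clip(x[-1], -10, 12)))
        ll = _laplace_loglik(y, X, design, sds_, nu_, state, beta_fixed=x[:p])
        return -ll if np.isfinite(ll) else 1e12

    res_full = minimize(
        objective_full,
        x0_full,
        method="L-BFGS-B",
        bounds=bounds_full,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    final_nll = objective_full(res_full.x)
    if not np.isfinite(final_nll):
        raise NonConvergenceError(
            "Laplace objective non-finite at optimum",
            diagnostics={"x": res_full.x.tolist()},
        )
    res = res_full
    state["beta"] = res_full.x[:p]
    sds = np.maximum(np.abs(res.x[p:-1]), math.exp(_LOG_SD_MIN))
    nu = math.exp(float(np.clip(res.x[-1], -10, 12)))
    beta, b = state["beta"], state["b"]
    q = design.q
    d_inv = np.empty(q)
    for sl, sd in zip(design.slices, sds):
        d_inv[sl] = 1.0 / max(sd, math.exp(_LOG_SD_MIN)) ** 2
    mu = np.exp(X @ beta + design.zb(b))
    w = nu * y / mu
    p = X.shape[1]
    H11 = X.T @ (X * w[:, None])
    H12 = design.xtwz(X, w) if q else np.zeros((p, 0))
    H22 = design.ztwz(w) + np.diag(d_inv)
    H = np.block([[H11, H12], [H12.T, H22]])
    cov = np.linalg.inv(H + 1e-12 * np.eye(p + q))
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    zscores = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * norm.sf(np.abs(zscores))

    variances = sds**2
    boundary = [t.label for t, sd in zip(random, sds) if sd < _BOUNDARY_SD]
    ranef = {}
    for term, sl, labs in zip(random, design.slices, design.labels):
        ranef[term.label] = dict(zip(labs, b[sl]))

    var_fixed = float(np.var(X @ beta))
    contribs = np.empty(len(random))
    for i, (term, v) in enumerate(zip(random, variances)):
        if term.slope is None:
            contribs[i] = v
        else:
            contribs[i] = v * float(np.mean(df[term.slope].to_numpy(float) ** 2))

    fit = GLMMFit(
        fixed_names=names,
        beta=beta,
        se=se,
        p_values=pvals,
        random_terms=[t.label for t in random],
        variances=variances,
        shape=nu,
        loglik=-final_nll,
        n_obs=len(y),
        group_counts={t.label: int(df[t.group].nunique()) for t in random},
        converged=bool(res.success) and state["gnorm"] < 1e-4,
        boundary=boundary,
        gradient_norm=float(state["gnorm"]),
        random_effects=ranef,
        fitted=mu,
        var_fixed=var_fixed,
        random_contribs=contribs,
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def r2_nakagawa(fit: GLMMFit, method: str = "trigamma") -> tuple[float, float]:
    """Variance-partition R-squared for the Gamma log-link mixed model.

    Marginal: variance of the fixed-effect linear predictor over the total
    (fixed + random + observation-level); conditional adds the random-effect
    variance to the numerator.  The observation-level variance on the log
    scale is trigamma(shape) by default, ln(1 + 1/shape) with
    method='lognormal'.
    """
    if method == "trigamma":
        var_obs = float(polygamma(1, fit.shape))
    elif method == "lognormal":
        var_obs = math.log(1.0 + 1.0 / fit.shape)
    else:
        raise ConfigError("method must be 'trigamma' or 'lognormal'")
    var_rand = float(np.sum(fit.random_contribs))
    total = fit.var_fixed + var_rand + var_obs
    if total <= 0:
        raise ConfigError("zero total variance; R2 undefined")
    return fit.var_fixed / total, (fit.var_fixed + var_rand) / total


def fit_gamma_glmm_agq(
    df: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    n_points: int = 25,
    add_intercept: bool = True,
    maxiter: int = 4000,
) -> GLMMFit:
    """Adaptive Gauss-Hermite ML fit for a single random intercept.

    This is the slow, independent cross-check for the Laplace fit: the
    random-effect integral is evaluated per group by quadrature centered at
    the conditional mode with curvature scaling, and all parameters are
    optimized directly.  Only one grouping factor, intercept-only.
    """
    y = df[response].to_numpy(dtype=float)
    X = df[fixed].to_numpy(dtype=float)
    names = list(fixed)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["Intercept"] + names
    groups = df[group].to_numpy()
    levels = pd.unique(groups)
    rows_per = [np.nonzero(groups == lv)[0] for lv in levels]
    nodes, weights = np.polynomial.hermite.hermgauss(n_points)

    def group_ll(eta0, yg, sigma, nu):
        # mode of g(u) = ll(eta0 + u) - u^2 / (2 sigma^2) by Newton
        u = 0.0
        for _ in range(50):
            mu = np.exp(eta0 + u)
            g1 = nu * float(np.sum(yg / mu - 1.0)) - u / sigma**2
            g2 = -nu * float(np.sum(yg / mu)) - 1.0 / sigma**2
            step = g1 / g2
            u_new = u - step
            if abs(u_new - u) < 1e-12:
                u = u_new
                break
            u = u_new
        mu = np.exp(eta0 + u)
        h = nu * float(np.sum(yg / mu)) + 1.0 / sigma**2
        s = 1.0 / math.sqrt(h)
        t = u + math.sqrt(2.0) * s * nodes
        vals = np.empty(n_points)
        for k, tk in enumerate(t):
            mu_k = np.exp(eta0 + tk)
            vals[k] = (
                _gamma_loglik(yg, mu_k, nu)
                - 0.5 * tk**2 / sigma**2
                - 0.5 * math.log(2 * math.pi * sigma**2)
                + nodes[k] ** 2
                + math.log(weights[k])
            )
        m = float(np.max(vals))
        return m + math.log(float(np.sum(np.exp(vals - m)))) + math.log(
            math.sqrt(2.0) * s
        )

    beta0, nu0, _ = fit_gamma_glm(y, X)
    x0 = np.concatenate([beta0, [math.log(0.3), math.log(nu0)]])

    def objective(x):
        beta = x[: X.shape[1]]
        sigma = math.exp(float(np.clip(x[-2], _LOG_SD_MIN, _LOG_SD_MAX)))
        nu = math.exp(float(np.clip(x[-1], -10, 12)))
        eta = X @ beta
        if np.max(eta) > 500:
            return np.inf
        total = 0.0
        for idx in rows_per:
            total += group_ll(eta[idx], y[idx], sigma, nu)
        return -total

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-9, "adaptive": True},
    )
    beta = res.x[: X.shape[1]]
    sigma = math.exp(float(np.clip(res.x[-2], _LOG_SD_MIN, _LOG_SD_MAX)))
    nu = math.exp(float(np.clip(res.x[-1], -10, 12)))
    var_fixed = float(np.var(X @ beta))
    fit = GLMMFit(
        fixed_names=names,
        beta=beta,
        se=np.full(X.shape[1], np.nan),
        p_values=np.full(X.shape[1], np.nan),
        random_terms=[group],
        variances=np.array([sigma**2]),
        shape=nu,
        loglik=-float(res.fun),
        n_obs=len(y),
        group_counts={group: len(levels)},
        converged=bool(res.success),
        boundary=[group] if sigma < _BOUNDARY_SD else [],
        gradient_norm=np.nan,
        var_fixed=var_fixed,
        random_contribs=np.array([sigma**2]),
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit
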