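"""Drivers of dietary overlap: correlations, mixed models, AICc ranking.

The response (total or aquatic-only dietary overlap, one value per site) is
modeled as a linear mixed-effect model with a site random intercept,

    y = X beta + Z b + e,   b ~ N(0, sigma2_site I),  e ~ N(0, sigma2 I).

The fit profiles the variance ratio lambda = sigma2_site / sigma2 out of
the (restricted) likelihood and maximizes over lambda >= 0, so with one
observation per site the random variance hits the zero boundary and the
fixed-effect estimates, standard errors, t and p exactly reproduce ordinary
least squares.  The REML log-likelihood keeps every constant,

    logLik = -1/2 [ (n-p) ln 2pi + ln|V| + ln|X' V^-1 X| + y' P y ],

matching the convention of nlme-style fits; AICc counts both variance
components in k even at the boundary.  Stepwise forward selection compares
maximum-likelihood fits (fixed effects differ between candidates); final
reported fits use REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_tables import ValidationError

#: the seventeen candidate explanatory variables screened against overlap
CANDIDATE_VARIABLES = [
    "prey_diversity",
    "prey_abundance",
    "density_salmon",
    "density_bullhead",
    "density_trout",
    "density_charr",
    "density_total",
    "surface_salmon",
    "surface_bullhead",
    "levins_salmon",
    "levins_bullhead",
    "one_minus_is_salmon_mean",
    "one_minus_is_bullhead_mean",
    "fullness_salmon",
    "fullness_bullhead",
    "length_salmon",
    "length_bullhead",
]


@dataclass
class ModelSpec:
    """A model formula: response, ordered fixed effects, site random intercept."""

    response: str
    fixed: list[str]
    random_site_intercept: bool = True

    def __post_init__(self) -> None:
        if len(set(self.fixed)) != len(self.fixed):
            dupes = sorted({v for v in self.fixed if self.fixed.count(v) > 1})
            raise ValidationError(f"duplicate fixed effects: {dupes}")


@dataclass
class ModelFit:
    """Fitted mixed model: coefficients, variance components, information criteria."""

    spec: ModelSpec
    coefficients: dict[str, dict[str, float]]
    sigma2_residual: float
    sigma2_site: float
    logLik_REML: float
    logLik_ML: float
    AIC: float
    AICc: float
    k_params: int
    n_obs: int
    method: str
    sites: list[str] = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return np.array([c["estimate"] for c in self.coefficients.values()])


@dataclass
class CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""

    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r and two-sided p (t with n-2 df) between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson needs two equal-length vectors of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def aicc(logLik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); requires n > k+1."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [c for c in (*spec.fixed, spec.response) if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks columns {missing}")
    sub = data[[spec.response, *spec.fixed]].astype(float)
    if sub.isna().any().any():
        raise ValidationError("incomplete cases in model variables")
    y = sub[spec.response].to_numpy()
    X = np.column_stack([np.ones(len(sub))] + [sub[v].to_numpy() for v in spec.fixed])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify which added columns break full rank
        names = ["intercept", *spec.fixed]
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValidationError(f"singular design; collinear terms: {bad}")
    groups = data["site"].to_numpy() if "site" in data.columns else np.arange(len(sub))
    return y, X, np.asarray(groups)


def _profiled_loglik(
    lam: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray, restricted: bool
) -> tuple[float, np.ndarray, float]:
    """Profiled (RE)ML log-likelihood at variance ratio lam, with GLS beta, sigma2."""
    n, p = X.shape
    Sigma = np.eye(n) + lam * (Z @ Z.T)
    Sinv = np.linalg.inv(Sigma)
    XtSX = X.T @ Sinv @ X
    beta = np.linalg.solve(XtSX, X.T @ Sinv @ y)
    r = y - X @ beta
    quad = float(r @ Sinv @ r)
    if quad <= 1e-12 * max(1.0, float(y @ y)):
        quad = 0.0  # numerically exact fit; variance at the zero boundary
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
    if restricted:
        df = n - p
        sigma2 = quad / df if quad > 0 else 0.0
        if sigma2 == 0:
            return math.inf, beta, 0.0  # degenerate perfect fit; caller handles
        _, logdet_XtSX = np.linalg.slogdet(XtSX)
        ll = -0.5 * (
            df * (math.log(2 * math.pi) + math.log(sigma2) + 1)
            + logdet_Sigma
            + logdet_XtSX
        )
    else:
        sigma2 = quad / n if quad > 0 else 0.0
        if sigma2 == 0:
            return math.inf, beta, 0.0
        ll = -0.5 * (n * (math.log(2 * math.pi) + math.log(sigma2) + 1) + logdet_Sigma)
    return ll, beta, sigma2


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, method: str = "reml") -> ModelFit:
    """Fit a site-random-intercept linear mixed model by REML or ML.

    ``data`` holds one row per observation with a ``site`` column for the
    grouping; with one observation per site the site variance is estimated
    at the zero boundary and the fixed part equals OLS.  Coefficient
    p-values are two-sided t with residual df = n - p.
    """
    if method not in ("reml", "ml"):
        raise ValidationError(f"unknown method {method!r}")
    y, X, groups = _design(data, spec)
    n, p = X.shape
    if n < p + 3:
        raise ValidationError(f"too few observations (n={n}) for {p} fixed effects")
    site_labels = sorted(set(map(str, groups)))
    Z = (np.array([str(g) for g in groups])[:, None] == np.array(site_labels)[None, :]).astype(float)
    if not spec.random_site_intercept:
        Z = np.zeros((n, 1))

    restricted = method == "reml"

    def neg(log_lam: float) -> float:
        ll, _, _ = _profiled_loglik(math.exp(log_lam), y, X, Z, restricted)
        return -ll if math.isfinite(ll) else 1e12

    ll0, beta0, s2_0 = _profiled_loglik(0.0, y, X, Z, restricted)
    best_lam, best_ll = 0.0, ll0
    if spec.random_site_intercept:
        res = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
        if math.isfinite(res.fun) and -res.fun > best_ll + 1e-10:
            best_lam, best_ll = math.exp(res.x), -res.fun

    ll, beta, sigma2 = _profiled_loglik(best_lam, y, X, Z, restricted)
    if not math.isfinite(ll):  # zero-residual boundary (e.g. constant response)
        ll, sigma2 = -math.inf, 0.0
    Sigma = np.eye(n) + best_lam * (Z @ Z.T)
    Sinv = np.linalg.inv(Sigma)
    cov_beta = sigma2 * np.linalg.inv(X.T @ Sinv @ X) if sigma2 > 0 else np.zeros((p, p))
    se = np.sqrt(np.diag(cov_beta))
    df_resid = n - p
    names = ["intercept", *spec.fixed]
    coefficients = {}
    for j, name in enumerate(names):
        if se[j] > 0:
            t_val = beta[j] / se[j]
        elif abs(beta[j]) < 1e-10:
            t_val = 0.0
        else:
            t_val = math.copysign(math.inf, beta[j])
        p_val = float(2 * stats.t.sf(abs(t_val), df_resid)) if math.isfinite(t_val) else 0.0
        coefficients[name] = {
            "estimate": float(beta[j]),
            "se": float(se[j]),
            "t": float(t_val),
            "p": p_val,
        }

    k = p + 2  # intercept+slopes plus both variance components, boundary or not
    # likelihood under the other criterion, at its own optimum, for reporting
    other = "ml" if restricted else "reml"
    ll_other = _fit_loglik_only(y, X, Z, spec.random_site_intercept, other == "reml")
    aic = -2.0 * ll + 2.0 * k
    return ModelFit(
        spec=spec,
        coefficients=coefficients,
        sigma2_residual=float(sigma2),
        sigma2_site=float(best_lam * sigma2),
        logLik_REML=float(ll if restricted else ll_other),
        logLik_ML=float(ll_other if restricted else ll),
        AIC=float(aic),
        AICc=float(aicc(ll, k, n)) if n > k + 1 else float("nan"),
        k_params=k,
        n_obs=n,
        method=method,
        sites=site_labels,
    )


def _fit_loglik_only(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, random_ok: bool, restricted: bool
) -> float:
    def neg(log_lam: float) -> float:
        ll, _, _ = _profiled_loglik(math.exp(log_lam), y, X, Z, restricted)
        return -ll if math.isfinite(ll) else 1e12

    ll0, _, _ = _profiled_loglik(0.0, y, X, Z, restricted)
    best = ll0
    if random_ok:
        res = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
        if math.isfinite(res.fun):
            best = max(best, -res.fun)
    return best


def forward_stepwise(
    data: pd.DataFrame,
    candidates: Sequence[str],
    response: str,
    min_improvement: float = 1e-9,
) -> list[str]:
    """Forward selection by ML-based AIC from an intercept-only start.

    At each step the candidate giving the largest AIC decrease is added;
    selection stops when no candidate lowers AIC.  Returns variables in
    selection order.
    """
    if len(candidates) < 2:
        raise ValidationError("forward selection needs >= 2 candidates")
    selected: list[str] = []
    current_aic = fit_lmm(ModelSpec(response, []), data, method="ml").AIC
    remaining = list(candidates)
    while remaining:
        trials = []
        for var in remaining:
            try:
                fit = fit_lmm(ModelSpec(response, [*selected, var]), data, method="ml")
            except ValidationError:
                continue
            trials.append((fit.AIC, var))
        if not trials:
            break
        best_aic, best_var = min(trials)
        if best_aic < current_aic - min_improvement:
            selected.append(best_var)
            remaining.remove(best_var)
            current_aic = best_aic
        else:
            break
    return selected


def rank_models(
    data: pd.DataFrame,
    variables: Sequence[str],
    response: str,
    max_terms: int = 1,
) -> pd.DataFrame:
    """REML-fit all 1..max_terms-variable models and rank ascending by AICc.

    The default candidate set is the single-variable models; multi-variable
    combinations are opt-in via ``max_terms`` because REML likelihoods of
    models with different fixed effects are only loosely comparable and the
    single-variable set is the conventional screen.  Ties (AICc within
    1e-9) are broken in favor of fewer parameters.  Returns a table with
    model formula, k, logLik, AIC, AICc and delta-AICc.
    """
    from itertools import combinations

    if not variables:
        raise ValidationError("no variables to rank")
    rows = []
    for size in range(1, max_terms + 1):
        for combo in combinations(variables, size):
            try:
                fit = fit_lmm(ModelSpec(response, list(combo)), data, method="reml")
            except ValidationError:
                continue
            rows.append(
                {
                    "model": " + ".join(combo),
                    "n_fixed": size,
                    "k": fit.k_params,
                    "logLik": fit.logLik_REML,
                    "AIC": fit.AIC,
                    "AICc": fit.AICc,
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(["AICc", "k"], kind="mergesort").reset_index(drop=True)
    table["delta_AICc"] = table["AICc"] - table["AICc"].iloc[0]
    return table


@dataclass
class BootstrapSummary:
    """Parametric-bootstrap distributions for the best model's slope."""

    n_boot: int
    slopes: np.ndarray
    slope_mean: float
    slope_sd: float
    slope_ci: tuple[float, float]
    sign_consistency: float
    r_values: np.ndarray
    r_mean: float
    seed: int


def parametric_bootstrap(
    fit: ModelFit,
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Simulate responses from the fitted model and refit each replicate.

    Each replicate draws site random intercepts and residuals from the
    fitted variance components, refits the same model by REML, and records
    the first fixed-effect slope and the Pearson r between the simulated
    response and the first predictor.  Replicate RNG streams are spawned
    from ``seed`` so results are reproducible and order-independent.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not (math.isfinite(fit.sigma2_residual) and math.isfinite(fit.sigma2_site)):
        raise ValidationError("non-finite variance estimates; cannot simulate")
    if not fit.spec.fixed:
        raise ValidationError("bootstrap needs at least one fixed effect")
    y, X, groups = _design(data, fit.spec)
    site_labels = sorted(set(map(str, groups)))
    Z = (np.array([str(g) for g in groups])[:, None] == np.array(site_labels)[None, :]).astype(float)
    mu = X @ fit.beta
    slope_name = fit.spec.fixed[0]
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    slopes = np.empty(n_boot)
    r_values = np.empty(n_boot)
    sim_data = data.copy()
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        b = rng.normal(0.0, math.sqrt(fit.sigma2_site), Z.shape[1])
        e = rng.normal(0.0, math.sqrt(fit.sigma2_residual), len(mu))
        y_star = mu + Z @ b + e
        sim_data[fit.spec.response] = y_star
        refit = fit_lmm(fit.spec, sim_data, method="reml")
        slopes[i] = refit.coefficients[slope_name]["estimate"]
        if np.ptp(y_star) > 0:
            r_values[i] = pearson(sim_data[slope_name], y_star).r
        else:
            r_values[i] = 0.0
    estimate_sign = math.copysign(1.0, fit.coefficients[slope_name]["estimate"])
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return BootstrapSummary(
        n_boot=n_boot,
        slopes=slopes,
        slope_mean=float(slopes.mean()),
        slope_sd=float(slopes.std(ddof=1)) if n_boot > 1 else 0.0,
        slope_ci=(float(lo), float(hi)),
        sign_consistency=float(np.mean(np.sign(slopes) == estimate_sign)),
        r_values=r_values,
        r_mean=float(r_values.mean()),
        seed=seed,
    )
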