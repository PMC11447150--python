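"""Multilevel models linking interval hypoglycaemia status to functioning scores.

The outcome model for one (cohort, phase, domain) cell is a linear
random-intercept regression

    score_ij = intercept + exposure dummies + covariates + u_i + e_ij,

with participant random intercepts ``u_i`` and residuals carrying an AR(1)
working correlation within participant (intervals ordered by start time).
Estimation proceeds in stages:

1. variance components by profiled maximum likelihood (the likelihood of a
   random-intercept model concentrates to a one-dimensional search over the
   variance ratio);
2. the AR(1) coefficient from the lag-1 correlation of level-1 residuals,
   followed by one refit under the updated working covariance;
3. optional robust estimation: iteratively reweighted least squares with
   Huber weights (tuning constant 1.345) on the whitened residuals, the
   standard response to heavy-tailed / heteroscedastic score residuals.

Standard errors are cluster-robust (sandwich over participants); 95% CIs
are Wald. Effects are additionally presented as percent change from the
model intercept, the usual display for 0-10 diary scales; CI bounds are
transformed by the same division (the intercept treated as fixed).

Multiplicity: the primary category family is tested against a
Bonferroni-corrected threshold alpha_family / n_tests, where n_tests
counts domains x cohorts x model iterations; exploratory subtype families
are flagged at the unadjusted alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .classify import CATEGORIES, SDH_SUBTYPE_LEVELS
from .ema import DEFAULT_CATALOGUE, DomainCatalogue
from .errors import ConfigurationError, EstimationError, UndefinedStatisticError

DEFAULT_HUBER_C = 1.345
Z_95 = float(stats.norm.ppf(0.975))

#: Default adjustment set (all present in the baseline covariate table).
DEFAULT_COVARIATES = (
    "age",
    "gender",
    "diabetes_duration",
    "impaired_awareness",
    "monitoring_modality",
    "hfs_total",
    "depressive_symptoms",
    "completion_rate",
)

PRH_COMBINED_LEVELS = (
    "none",
    "symptomatic-treated",
    "symptomatic-prevented",
    "symptomatic-other",
    "asymptomatic-treated",
    "asymptomatic-prevented",
    "asymptomatic-other",
)

#: family -> (exposure column, reference level, full level order, extra adjusters)
EXPOSURE_FAMILIES = {
    "category": ("category", "A", CATEGORIES, ()),
    "prh": ("prh_combined", "none", PRH_COMBINED_LEVELS, ("sdh_present",)),
    "sdh": ("sdh_subtype", "none", SDH_SUBTYPE_LEVELS, ("prh_present",)),
}

PRIMARY_FAMILY = "category"


# --------------------------------------------------------------------------
# multiplicity arithmetic


def count_tests(
    n_morning_domains: int = 10,
    n_evening_domains: int = 9,
    n_cohorts: int = 2,
    n_model_iterations: int = 7,
) -> int:
    """Size of the test family: (morning + evening domains) x cohorts x iterations."""
    n_domains = n_morning_domains + n_evening_domains
    if n_domains < 1 or n_cohorts < 1 or n_model_iterations < 1:
        raise ValueError("test family must contain at least one test")
    return n_domains * n_cohorts * n_model_iterations


def bonferroni_threshold(alpha_family: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance threshold alpha_family / n_tests."""
    if not 0.0 < alpha_family <= 1.0:
        raise ValueError("alpha_family must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha_family / n_tests


def percent_change(coefficient: float, intercept: float) -> float:
    """Coefficient expressed as % change from the model intercept."""
    if intercept == 0:
        raise UndefinedStatisticError("percent change undefined for zero intercept")
    return 100.0 * coefficient / intercept


@dataclass(frozen=True)
class MultiplicityPlan:
    alpha_family: float = 0.05
    n_tests: int = 1

    def __post_init__(self):
        if not 0.0 < self.alpha_family <= 1.0:
            raise ValueError("alpha_family must lie in (0, 1]")
        if self.n_tests < 1:
            raise ValueError("n_tests must be a positive integer")

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_family / self.n_tests


# --------------------------------------------------------------------------
# core estimator


@dataclass
class RandomInterceptFit:
    """Raw fit of the random-intercept working-covariance model."""

    names: list
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma_u: float
    sigma_e: float
    rho: float
    n_obs: int
    n_groups: int
    converged: bool
    n_iter: int = 0


def _profiled_ml(y, X, codes, n_groups):
    """ML variance ratio and GLS coefficients for V_i = sigma2 (I + lam J)."""
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    SX = np.zeros((n_groups, p))
    np.add.at(SX, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    ng = np.bincount(codes, minlength=n_groups).astype(float)

    def beta_quad(lam):
        c = lam / (1.0 + lam * ng)
        A = XtX - SX.T @ (SX * c[:, None])
        b = Xty - SX.T @ (c * Sy)
        beta = linalg.solve(A, b, assume_a="pos")
        quad = yty - float(np.dot(c * Sy, Sy)) - float(beta @ b)
        return beta, quad

    def nll(loglam):
        _, quad = beta_quad(np.exp(loglam))
        if quad <= 0:
            return np.inf
        return n * np.log(quad / n) + float(np.sum(np.log1p(np.exp(loglam) * ng)))

    res = optimize.minimize_scalar(
        nll, bounds=(-16.0, 9.0), method="bounded", options={"xatol": 1e-11}
    )
    lam = float(np.exp(res.x))
    # check the boundary lam -> 0 (no between-participant variance)
    _, quad0 = beta_quad(0.0)
    if quad0 > 0 and n * np.log(quad0 / n) <= res.fun:
        lam = 0.0
    beta, quad = beta_quad(lam)
    return lam, quad / n, beta, bool(res.success)


def _estimate_rho(resid, codes, lam, n_groups, min_pairs=10):
    """Lag-1 autocorrelation of level-1 residuals (marginal residual minus
    the shrunken participant-mean residual), over within-participant
    consecutive observations."""
    ng = np.bincount(codes, minlength=n_groups).astype(float)
    ebar = np.bincount(codes, weights=resid, minlength=n_groups) / np.maximum(ng, 1)
    f = lam * ng / (1.0 + lam * ng)
    e1 = resid - (f * ebar)[codes]
    adjacent = codes[1:] == codes[:-1]
    a, b = e1[:-1][adjacent], e1[1:][adjacent]
    if len(a) < min_pairs or a.std() == 0 or b.std() == 0:
        return 0.0
    rho = float(np.corrcoef(a, b)[0, 1])
    if not np.isfinite(rho):
        return 0.0
    return float(np.clip(rho, -0.9, 0.9))


def _whiten(X, y, codes, lam, rho):
    """Left-multiply each participant block by L^-1, chol(L L') = lam J + R(rho)."""
    n = len(y)
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    bounds = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [n]))
    chol_cache: dict[int, np.ndarray] = {}
    for s0, s1 in zip(starts, stops):
        m = s1 - s0
        L = chol_cache.get(m)
        if L is None:
            C = lam + linalg.toeplitz(rho ** np.arange(m))
            L = np.linalg.cholesky(C)
            chol_cache[m] = L
        Xw[s0:s1] = linalg.solve_triangular(L, X[s0:s1], lower=True)
        yw[s0:s1] = linalg.solve_triangular(L, y[s0:s1], lower=True)
    return Xw, yw


def _wls(X, y, w):
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ y
    return linalg.solve(A, b, assume_a="pos"), A


def _mad_scale(r):
    s = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    if s <= 0:
        s = float(r.std()) or 1.0
    return s


def fit_random_intercept(
    y,
    X,
    groups,
    order=None,
    *,
    robust: bool = True,
    ar1: bool = True,
    huber_c: float = DEFAULT_HUBER_C,
    max_iter: int = 50,
    tol: float = 1e-8,
    names=None,
) -> RandomInterceptFit:
    """Fit the working-covariance random-intercept model (see module docstring).

    ``X`` must contain an intercept column. Rows are re-sorted internally by
    (group, order); with ``robust=False`` and ``ar1=False`` the coefficients
    are exactly the maximum-likelihood random-intercept estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if order is None:
        order = np.arange(len(y))
    order = np.asarray(order)
    codes, uniques = pd.factorize(groups, sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise EstimationError("estimation requires at least two participants")
    if len(y) <= X.shape[1] + 1:
        raise EstimationError("too few observations for the requested design")

    idx = np.lexsort((order, codes))
    y, X, codes = y[idx], X[idx], codes[idx]

    lam, sigma2, beta_ml, ml_ok = _profiled_ml(y, X, codes, n_groups)

    rho = 0.0
    if ar1:
        rho = _estimate_rho(y - X @ beta_ml, codes, lam, n_groups)

    Xw, yw = _whiten(X, y, codes, lam, rho)

    w = np.ones(len(yw))
    beta, A = _wls(Xw, yw, w)
    n_iter, irls_ok = 0, True
    if robust:
        irls_ok = False
        for n_iter in range(1, max_iter + 1):
            r = yw - Xw @ beta
            scale = _mad_scale(r)
            u = np.abs(r) / scale
            w = np.where(u <= huber_c, 1.0, huber_c / np.maximum(u, 1e-12))
            beta_new, A = _wls(Xw, yw, w)
            if np.max(np.abs(beta_new - beta)) <= tol * (1.0 + np.max(np.abs(beta_new))):
                beta = beta_new
                irls_ok = True
                break
            beta = beta_new

    # cluster-robust sandwich over participants; for the Huber M-estimator the
    # bread uses psi'(u) (an indicator), not the IRLS working weights c/|u|
    r = yw - Xw @ beta
    score = Xw * (w * r)[:, None]
    Gm = np.zeros((n_groups, X.shape[1]))
    np.add.at(Gm, codes, score)
    if robust:
        u = np.abs(r) / _mad_scale(r)
        psi_prime = (u <= huber_c).astype(float)
        B = (Xw * psi_prime[:, None]).T @ Xw
    else:
        B = A
    bread = linalg.inv(B)
    meat = Gm.T @ Gm
    cov = bread @ meat @ bread * n_groups / max(n_groups - 1, 1)
    se = np.sqrt(np.diag(cov))

    return RandomInterceptFit(
        names=list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])],
        params=beta,
        se=se,
        cov=cov,
        sigma_u=float(np.sqrt(sigma2 * lam)),
        sigma_e=float(np.sqrt(sigma2)),
        rho=rho,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(ml_ok and irls_ok and np.all(np.isfinite(beta))),
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# domain-level interface


@dataclass(frozen=True)
class ModelSpec:
    """One domain x cohort x phase x exposure-family model."""

    cohort: str
    phase: str  # "night" (-> morning functioning) or "day" (-> evening)
    outcome_domain: str
    exposure_family: str = "category"
    covariates: tuple = ()

    def __post_init__(self):
        if self.exposure_family not in EXPOSURE_FAMILIES:
            raise ConfigurationError(
                f"unknown exposure family {self.exposure_family!r}"
            )

    @property
    def exposure_col(self) -> str:
        return EXPOSURE_FAMILIES[self.exposure_family][0]

    @property
    def reference(self) -> str:
        return EXPOSURE_FAMILIES[self.exposure_family][1]

    @property
    def levels(self) -> tuple:
        return EXPOSURE_FAMILIES[self.exposure_family][2]

    @property
    def adjusters(self) -> tuple:
        return EXPOSURE_FAMILIES[self.exposure_family][3]


@dataclass
class LevelEstimate:
    level: str
    coef: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    percent_change: float
    percent_ci_low: float
    percent_ci_high: float
    significant: bool | None = None


@dataclass
class ModelResult:
    spec: ModelSpec
    intercept: float
    intercept_se: float
    levels: list
    n_obs: int
    n_participants: int
    n_dropped_missing: int
    converged: bool
    rho: float
    sigma_u: float
    sigma_e: float
    multiplicity: str = "unadjusted"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cohort": self.spec.cohort,
                "phase": self.spec.phase,
                "domain": self.spec.outcome_domain,
                "family": self.spec.exposure_family,
                "level": lv.level,
                "coef": lv.coef,
                "se": lv.se,
                "ci_low": lv.ci_low,
                "ci_high": lv.ci_high,
                "percent_change": lv.percent_change,
                "percent_ci_low": lv.percent_ci_low,
                "percent_ci_high": lv.percent_ci_high,
                "p_value": lv.p_value,
                "significant": lv.significant,
                "multiplicity": self.multiplicity,
                "intercept": self.intercept,
                "n_obs": self.n_obs,
                "n_participants": self.n_participants,
                "converged": self.converged,
                "rho": self.rho,
            }
            for lv in self.levels
        ]
        return pd.DataFrame(rows)


def _design(sub: pd.DataFrame, spec: ModelSpec):
    """Intercept + exposure dummies (reference first) + centred covariates."""
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    observed = set(sub[spec.exposure_col].unique())
    ordered = [lv for lv in spec.levels if lv in observed]
    ordered += sorted(observed - set(spec.levels))
    for lv in spec.levels:
        if lv not in observed:
            warnings.warn(
                f"exposure level {lv!r} unobserved for "
                f"{spec.cohort}/{spec.phase}/{spec.outcome_domain}; omitted",
                stacklevel=3,
            )
    for lv in ordered:
        if lv == spec.reference:
            continue
        cols.append((sub[spec.exposure_col] == lv).to_numpy(float))
        names.append(lv)
    exposure_names = names[1:]

    def add_if_independent(col, name, dropped):
        # keep the design full rank: small cohorts easily alias covariates
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, col, rcond=None)
        resid = col - X @ beta
        if float(resid @ resid) > 1e-8 * max(float(col @ col), 1.0):
            cols.append(col)
            names.append(name)
        else:
            dropped.append(name)

    dropped: list = []
    for cov in spec.covariates:
        v = sub[cov]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            add_if_independent((v - v.mean()).to_numpy(float), cov, dropped)
        elif pd.api.types.is_numeric_dtype(v):
            add_if_independent(v.to_numpy(float), cov, dropped)
        else:
            for cat in sorted(v.astype(str).unique())[1:]:
                add_if_independent(
                    (v.astype(str) == cat).to_numpy(float), f"{cov}[{cat}]", dropped
                )
    if dropped:
        warnings.warn(
            f"dropped collinear covariate column(s) {dropped} for "
            f"{spec.cohort}/{spec.phase}/{spec.outcome_domain}",
            stacklevel=3,
        )
    return np.column_stack(cols), names, exposure_names


def fit_domain_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    robust: bool = True,
    ar1: bool = True,
    huber_c: float = DEFAULT_HUBER_C,
) -> ModelResult:
    """Fit one domain model on interval-outcome rows.

    ``data`` needs columns ``participant_id``, ``order``, the outcome
    (named after the domain, or a ``score`` column), the exposure column
    and every covariate in the spec. Rows with a missing value in any used
    column are dropped (pairwise deletion) and counted.
    """
    outcome = spec.outcome_domain if spec.outcome_domain in data.columns else "score"
    used = ["participant_id", "order", outcome, spec.exposure_col, *spec.covariates]
    for c in used:
        if c not in data.columns:
            raise ConfigurationError(f"model data lacks required column {c!r}")
    sub = data[used].dropna()
    n_dropped = len(data) - len(sub)
    if sub["participant_id"].nunique() < 2:
        raise EstimationError(
            "domain model requires observations from at least two participants"
        )
    if sub[spec.exposure_col].nunique() < 2:
        raise EstimationError(
            f"exposure {spec.exposure_col!r} has fewer than two observed levels"
        )

    X, names, exposure_names = _design(sub, spec)
    fit = fit_random_intercept(
        sub[outcome].to_numpy(float),
        X,
        sub["participant_id"].to_numpy(),
        sub["order"].to_numpy(),
        robust=robust,
        ar1=ar1,
        huber_c=huber_c,
        names=names,
    )

    intercept = float(fit.params[0])
    levels = []
    for name in exposure_names:
        i = names.index(name)
        coef, se = float(fit.params[i]), float(fit.se[i])
        lo, hi = coef - Z_95 * se, coef + Z_95 * se
        z = coef / se if se > 0 else np.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        if intercept != 0:
            pct = percent_change(coef, intercept)
            pct_lo = percent_change(lo, intercept)
            pct_hi = percent_change(hi, intercept)
            if pct_lo > pct_hi:  # negative intercept flips the bounds
                pct_lo, pct_hi = pct_hi, pct_lo
        else:
            pct = pct_lo = pct_hi = np.nan
        levels.append(
            LevelEstimate(name, coef, se, lo, hi, p, pct, pct_lo, pct_hi)
        )
    return ModelResult(
        spec=spec,
        intercept=intercept,
        intercept_se=float(fit.se[0]),
        levels=levels,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        n_dropped_missing=n_dropped,
        converged=fit.converged,
        rho=fit.rho,
        sigma_u=fit.sigma_u,
        sigma_e=fit.sigma_e,
    )


def run_model_family(
    table: pd.DataFrame,
    *,
    catalogue: DomainCatalogue = DEFAULT_CATALOGUE,
    covariates=None,
    exposures=("category", "prh", "sdh"),
    alpha_family: float = 0.05,
    n_model_iterations: int = 7,
    robust: bool = True,
    ar1: bool = True,
) -> tuple[list, MultiplicityPlan]:
    """Fit every cohort x phase x domain model for the requested families.

    ``table`` is the tidy interval-outcome table (one row per interval x
    domain) produced by :func:`hypodiary.pipeline.assemble_model_table`.
    The primary category family is flagged against the Bonferroni
    threshold; subtype families against the unadjusted alpha. Models whose
    exposure collapses to a single observed level are skipped with a
    warning.
    """
    cohorts = sorted(table["cohort"].unique())
    plan = MultiplicityPlan(
        alpha_family=alpha_family,
        n_tests=count_tests(
            len(catalogue.morning), len(catalogue.evening), len(cohorts), n_model_iterations
        ),
    )
    if covariates is None:
        covariates = tuple(c for c in DEFAULT_COVARIATES if c in table.columns)

    results: list[ModelResult] = []
    for family in exposures:
        threshold = plan.alpha_per_test if family == PRIMARY_FAMILY else alpha_family
        label = "bonferroni" if family == PRIMARY_FAMILY else "unadjusted"
        for cohort in cohorts:
            for phase in ("night", "day"):
                for domain in catalogue.for_phase(phase):
                    sub = table[
                        (table["cohort"] == cohort)
                        & (table["phase"] == phase)
                        & (table["domain"] == domain)
                    ]
                    if sub.empty:
                        continue
                    spec = ModelSpec(
                        cohort=cohort,
                        phase=phase,
                        outcome_domain=domain,
                        exposure_family=family,
                        covariates=tuple(covariates),
                    )
                    try:
                        res = fit_domain_model(sub, spec, robust=robust, ar1=ar1)
                    except EstimationError as exc:
                        warnings.warn(
                            f"skipping {cohort}/{phase}/{domain}/{family}: {exc}",
                            stacklevel=2,
                        )
                        continue
                    res.multiplicity = label
                    for lv in res.levels:
                        lv.significant = bool(lv.p_value < threshold)
                    results.append(res)
    return results, plan


def results_frame(results) -> pd.DataFrame:
    """Concatenate model results into one tidy table."""
    if not results:
        return pd.DataFrame()
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
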