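"""Linear mixed-model fitting contract shared by all analysis stages.

Models are declared as :class:`ModelSpec` (numeric/binary fixed terms,
product interactions, independent random intercepts — possibly on composite
grouping labels, the standard encoding of nested factors).  Variance
parameters are estimated by maximizing the profiled REML log-likelihood
directly (Woodbury identity, so each evaluation costs O(nq + q³) with q the
total number of random levels); this one code path handles single, multiple
and crossed random intercepts uniformly, and is cross-validated against
lme4/lmerTest in the test suite.  Fixed effects come from GLS at the
estimated variances; models without random terms fall back to OLS.

Inference on fixed effects uses a Satterthwaite approximation to the
denominator degrees of freedom, computed here from first principles: the
GLS covariance of the fixed effects is evaluated as a function of the
variance parameters (via the Woodbury identity, so only q x q solves are
needed), the covariance of the variance-parameter estimates comes from a
numerical Hessian of the profiled REML log-likelihood, and the two are
combined by the delta method.  ``df_method`` can instead select plain
residual-df t tests or normal-approximation Wald tests.

Marginal and conditional R² follow the variance-components definition:
sigma_f² is the variance of the fixed-effect linear predictor across
observations, and

    R²_m = sigma_f² / (sigma_f² + sigma_r² + sigma_e²)
    R²_c = (sigma_f² + sigma_r²) / (sigma_f² + sigma_r² + sigma_e²)

with sigma_r² summed over all random intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SingleLevelFactorError,
)

RandomFactor = Union[str, tuple[str, ...]]

_DF_METHODS = ("satterthwaite", "residual", "normal")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a linear mixed model."""

    response: str
    fixed_terms: tuple[str, ...]
    interactions: tuple[tuple[str, ...], ...] = ()
    random_intercepts: tuple[RandomFactor, ...] = ()
    reml: bool = True
    df_method: str = "satterthwaite"

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(
            self, "interactions", tuple(tuple(t) for t in self.interactions)
        )
        object.__setattr__(
            self,
            "random_intercepts",
            tuple(t if isinstance(t, str) else tuple(t) for t in self.random_intercepts),
        )
        if self.df_method not in _DF_METHODS:
            raise ValueError(f"df_method must be one of {_DF_METHODS}")
        for terms in self.interactions:
            if len(terms) < 2:
                raise ValueError(f"interaction {terms} needs at least two terms")
            missing = set(terms) - set(self.fixed_terms)
            if missing:
                raise ValueError(
                    f"interaction {terms} uses terms absent from fixed_terms: {sorted(missing)}"
                )

    @property
    def term_names(self) -> tuple[str, ...]:
        return (
            ("Intercept",)
            + self.fixed_terms
            + tuple(":".join(t) for t in self.interactions)
        )


def factor_name(factor: RandomFactor) -> str:
    return factor if isinstance(factor, str) else ":".join(factor)


@dataclass
class ModelFit:
    """Fitted mixed model: coefficients, inference and variance components."""

    spec: ModelSpec
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    dof: dict[str, float]
    var_fixed: float
    var_random: dict[str, float]
    var_residual: float
    n_obs: int
    n_groups: dict[str, int]
    converged: bool
    degenerate: bool
    log_likelihood: float
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _machinery: "_VarianceMachinery" = field(repr=False, default=None)

    @property
    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": [self.coefficients[t] for t in self.terms],
                "se": [self.standard_errors[t] for t in self.terms],
                "df": [self.dof[t] for t in self.terms],
                "p": [self.p_values[t] for t in self.terms],
            }
        )


@dataclass(frozen=True)
class R2Result:
    """Marginal and conditional R² from variance components."""

    r2_marginal: float
    r2_conditional: float


@dataclass(frozen=True)
class InsufficientData:
    """Explicit non-crash result for analyses the data cannot support."""

    reason: str


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    col = np.asarray(table[name], dtype=float)
    if np.isnan(col).any():
        raise ValueError(f"column {name!r} contains missing values")
    return col


def build_design_matrix(table: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design matrix (intercept, main terms, product interactions).

    Raises :class:`RankDeficiencyError` naming the aliased columns when the
    matrix is rank deficient.
    """
    missing = [t for t in spec.fixed_terms + (spec.response,) if t not in table.columns]
    if missing:
        raise KeyError(f"table lacks required columns: {missing}")
    n = len(table)
    cols = [np.ones(n)]
    for t in spec.fixed_terms:
        cols.append(_column(table, t))
    for terms in spec.interactions:
        prod = np.ones(n)
        for t in terms:
            prod = prod * _column(table, t)
        cols.append(prod)
    X = np.column_stack(cols)
    names = spec.term_names

    # pivoted QR exposes which columns are linearly dependent
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = scipy.linalg.qr(X / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in sorted(piv[rank:])]
        raise RankDeficiencyError(aliased)
    return X, names


def _random_codes(table: pd.DataFrame, spec: ModelSpec):
    """Integer codes and level counts for each random factor."""
    out = []
    for factor in spec.random_intercepts:
        name = factor_name(factor)
        cols = (factor,) if isinstance(factor, str) else factor
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"random factor {name!r}: table lacks columns {missing}")
        labels = table[list(cols)].astype(str).agg(":".join, axis=1)
        codes, levels = pd.factorize(labels, sort=True)
        if len(levels) < 2:
            raise SingleLevelFactorError(
                f"random factor {name!r} has a single level ({levels[0]!r})"
            )
        out.append((name, codes, len(levels)))
    return out


class _VarianceMachinery:
    """Woodbury-based GLS quantities as functions of the variance parameters.

    theta = (sigma²_1, ..., sigma²_K, sigma²_e) with one variance per random
    factor.  All operations cost O(nq + q³) with q the total number of random
    levels.
    """

    def __init__(self, X, y, factors):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        self.factor_names = [name for name, _, _ in factors]
        blocks = []
        col_factor = []
        for k, (_, codes, n_levels) in enumerate(factors):
            Z = np.zeros((self.n, n_levels))
            Z[np.arange(self.n), codes] = 1.0
            blocks.append(Z)
            col_factor.extend([k] * n_levels)
        self.Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self.col_factor = np.asarray(col_factor, dtype=int)
        self.q = self.Z.shape[1]
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ X
        self.Zty = self.Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _active(self, theta):
        sig_e = theta[-1]
        comp = np.asarray(theta[:-1], dtype=float)
        d = comp[self.col_factor]
        active = d > 1e-12 * max(sig_e, 1e-300)
        return sig_e, d, active

    def _solve_W(self, theta):
        """W = (sigma_e² D⁻¹ + Z'Z)⁻¹ on the active random columns."""
        sig_e, d, active = self._active(theta)
        if not active.any():
            return sig_e, active, None
        M = self.ZtZ[np.ix_(active, active)].copy()
        M[np.diag_indices_from(M)] += sig_e / d[active]
        return sig_e, active, np.linalg.inv(M)

    def xtvinvx(self, theta):
        sig_e, active, W = self._solve_W(theta)
        if W is None:
            return self.XtX / sig_e
        ZtXa = self.ZtX[active]
        return (self.XtX - ZtXa.T @ W @ ZtXa) / sig_e

    def cov_beta(self, theta):
        return np.linalg.inv(self.xtvinvx(theta))

    def gls_beta(self, theta):
        sig_e, active, W = self._solve_W(theta)
        if W is None:
            A, b = self.XtX / sig_e, self.Xty / sig_e
        else:
            ZtXa, Ztya = self.ZtX[active], self.Zty[active]
            A = (self.XtX - ZtXa.T @ W @ ZtXa) / sig_e
            b = (self.Xty - ZtXa.T @ W @ Ztya) / sig_e
        return np.linalg.solve(A, b)

    def reml_loglike(self, theta, reml=True):
        """Profiled (over beta) REML (or ML) log-likelihood, up to an
        additive constant."""
        sig_e, d, active = self._active(theta)
        if sig_e <= 0 or np.any(np.asarray(theta[:-1]) < 0):
            return -np.inf
        if active.any():
            M = self.ZtZ[np.ix_(active, active)].copy()
            M[np.diag_indices_from(M)] += sig_e / d[active]
            sign, logdet_M = np.linalg.slogdet(M)
            if sign <= 0:
                return -np.inf
            qa = int(active.sum())
            logdet_V = (self.n - qa) * np.log(sig_e) + np.log(d[active]).sum() + logdet_M
            W = np.linalg.inv(M)
            ZtXa, Ztya = self.ZtX[active], self.Zty[active]
            XtVinvX = (self.XtX - ZtXa.T @ W @ ZtXa) / sig_e
            XtVinvy = (self.Xty - ZtXa.T @ W @ Ztya) / sig_e
            ytViy = (self.yty - Ztya @ W @ Ztya) / sig_e
        else:
            logdet_V = self.n * np.log(sig_e)
            XtVinvX = self.XtX / sig_e
            XtVinvy = self.Xty / sig_e
            ytViy = self.yty / sig_e
        sign, logdet_XVX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        quad = ytViy - XtVinvy @ beta
        if not reml:
            return -0.5 * (logdet_V + quad)
        return -0.5 * (logdet_V + logdet_XVX + quad)

    # ---- Satterthwaite ----------------------------------------------------

    def _interior(self, theta):
        """Indices of variance parameters away from the zero boundary.

        Components estimated (numerically) at zero are held fixed: the REML
        surface is one-sided there, and a boundary component's sampling
        variability cannot enter the Satterthwaite denominator.
        """
        sig_e = theta[-1]
        keep = [k for k in range(len(theta) - 1) if theta[k] > 1e-6 * sig_e]
        return keep + [len(theta) - 1]

    def _theta_cov(self, theta, interior, rel=1e-4):
        """Covariance of the interior variance-parameter estimates from the
        numerical Hessian of the REML log-likelihood. None when unusable."""
        d = len(interior)
        sub = theta[interior]
        steps = np.minimum(np.maximum(np.abs(sub) * rel, 1e-10), np.abs(sub) / 2)

        def f(delta):
            th = theta.copy()
            th[interior] = sub + delta
            return self.reml_loglike(th)

        H = np.zeros((d, d))
        f0 = f(np.zeros(d))
        if not np.isfinite(f0):
            return None
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = steps[i]
            for j in range(i, d):
                ej = np.zeros(d)
                ej[j] = steps[j]
                if i == j:
                    H[i, i] = (f(ei) - 2 * f0 + f(-ei)) / steps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
                    ) / (4 * steps[i] * steps[j])
        if not np.all(np.isfinite(H)):
            return None
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(A)):
            return None
        return A

    def blup(self, theta, beta):
        """Random-effect predictions (Henderson equations) on active columns."""
        sig_e, active, W = self._solve_W(theta)
        u = np.zeros(self.q)
        if W is not None:
            r = self.y - self.X @ beta
            u[active] = W @ (self.Z[:, active].T @ r)
        return u

    def optimize_reml(self, theta0=None, maxiter=2000, reml=True):
        """Maximize the profiled REML (or ML) log-likelihood over the
        variance parameters directly (Nelder-Mead on the log-variance scale,
        one restart if the first pass stalls).

        The Woodbury formulation makes each evaluation O(nq + q³) and
        handles any number of crossed random intercepts uniformly.
        """
        from scipy.optimize import minimize

        beta_ols, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        s2 = float(np.mean((self.y - self.X @ beta_ols) ** 2))
        s2 = max(s2, 1e-12)
        K = len(self.factor_names)
        if theta0 is None:
            theta0 = np.array([s2 / (K + 1)] * K + [s2 / 2])
        eta0 = np.log(np.maximum(theta0, 1e-10 * s2))

        def neg(eta):
            ll = self.reml_loglike(np.exp(eta), reml=reml)
            return -ll if np.isfinite(ll) else 1e12

        res = minimize(neg, eta0, method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=1e-7, fatol=1e-9))
        if not res.success:  # one restart from the current best point
            res = minimize(neg, res.x, method="Nelder-Mead",
                           options=dict(maxiter=maxiter, xatol=1e-7, fatol=1e-9))
        theta = np.exp(res.x)
        # variances driven to the numerical floor are boundary zeros
        theta[:-1][theta[:-1] < 1e-8 * theta[-1]] = 0.0
        return theta, bool(res.success)

    def satterthwaite_df(self, theta):
        """Per-coefficient Satterthwaite denominator degrees of freedom."""
        theta = np.asarray(theta, dtype=float)
        C0 = self.cov_beta(theta)
        interior = self._interior(theta)
        A = self._theta_cov(theta, interior)
        dfs = np.full(self.p, np.inf)
        if A is None:
            return dfs, C0
        d = len(interior)
        grads = np.zeros((self.p, d))
        for k, idx in enumerate(interior):
            h = min(max(theta[idx] * 1e-4, 1e-10), theta[idx] / 2)
            tp = theta.copy()
            tp[idx] += h
            tm = theta.copy()
            tm[idx] -= h
            grads[:, k] = (
                np.diag(self.cov_beta(tp)) - np.diag(self.cov_beta(tm))
            ) / (2 * h)
        for i in range(self.p):
            denom = grads[i] @ A @ grads[i]
            if denom > 0 and np.isfinite(denom):
                dfs[i] = max(2 * C0[i, i] ** 2 / denom, 1.0)
        return dfs, C0


def _pvalues_from_df(beta, se, dfs):
    p = np.empty_like(beta)
    for i, (b, s, d) in enumerate(zip(beta, se, dfs)):
        if s <= 0:
            p[i] = np.nan
        elif np.isinf(d):
            p[i] = 2 * stats.norm.sf(abs(b / s))
        else:
            p[i] = 2 * stats.t.sf(abs(b / s), d)
    return p


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a linear mixed model per ``spec`` on a model-ready table.

    Noise-free data (zero residual after ordinary least squares) are handled
    by an exact least-squares path flagged ``degenerate``, since REML cannot
    estimate zero variances; coefficients are then exact, standard errors 0
    and p-values undefined.
    """
    y = _column(table, spec.response)
    X, names = build_design_matrix(table, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed parameters ({p})")
    factors = _random_codes(table, spec)
    n_groups = {name: k for name, _, k in factors}

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_ols = y - X @ beta_ols
    ref = max(float(np.mean(y**2)), 1.0)
    if float(np.mean(resid_ols**2)) <= 1e-14 * ref:
        fitted = X @ beta_ols
        return ModelFit(
            spec=spec, terms=names,
            coefficients=dict(zip(names, beta_ols)),
            standard_errors={t: 0.0 for t in names},
            p_values={t: float("nan") for t in names},
            dof={t: float("nan") for t in names},
            var_fixed=float(np.var(fitted, ddof=1)) if n > 1 else 0.0,
            var_random={name: 0.0 for name in n_groups},
            var_residual=0.0, n_obs=n, n_groups=n_groups,
            converged=True, degenerate=True, log_likelihood=float("nan"),
            fitted=fitted, residuals=y - fitted, _X=X, _y=y,
        )

    if not factors:
        return _fit_ols(table, spec, X, y, names)

    mach = _VarianceMachinery(X, y, factors)
    theta, converged = mach.optimize_reml(reml=spec.reml)
    beta = mach.gls_beta(theta)
    sigma_e = float(theta[-1])
    var_random = {name: float(theta[k]) for k, (name, _, _) in enumerate(factors)}
    if spec.df_method == "satterthwaite" and converged:
        dfs, C = mach.satterthwaite_df(theta)
        se = np.sqrt(np.diag(C))
    else:
        C = mach.cov_beta(theta)
        se = np.sqrt(np.diag(C))
        if spec.df_method == "residual":
            dfs = np.full(p, float(n - p))
        else:
            dfs = np.full(p, np.inf)
    pvals = _pvalues_from_df(beta, se, dfs)

    u = mach.blup(theta, beta)
    fitted = X @ beta + mach.Z @ u
    llf = float(mach.reml_loglike(theta, reml=spec.reml)
                - 0.5 * (n - p if spec.reml else n) * np.log(2 * np.pi))
    return ModelFit(
        spec=spec, terms=names,
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        p_values=dict(zip(names, pvals)),
        dof=dict(zip(names, dfs)),
        var_fixed=float(np.var(X @ beta, ddof=1)),
        var_random=var_random,
        var_residual=sigma_e,
        n_obs=n, n_groups=n_groups,
        converged=converged, degenerate=False,
        log_likelihood=llf,
        fitted=fitted, residuals=y - fitted, _X=X, _y=y, _machinery=mach,
    )


def _fit_ols(table, spec, X, y, names):
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    n, p = X.shape
    if spec.df_method == "normal":
        dfs = np.full(p, np.inf)
    else:
        dfs = np.full(p, float(n - p))
    se = np.asarray(res.bse)
    pvals = _pvalues_from_df(np.asarray(res.params), se, dfs)
    fitted = np.asarray(res.fittedvalues)
    return ModelFit(
        spec=spec, terms=names,
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, se)),
        p_values=dict(zip(names, pvals)),
        dof=dict(zip(names, dfs)),
        var_fixed=float(np.var(fitted, ddof=1)),
        var_random={},
        var_residual=float(res.ssr / (n - p)),
        n_obs=n, n_groups={},
        converged=True, degenerate=False,
        log_likelihood=float(res.llf),
        fitted=fitted, residuals=y - fitted, _X=X, _y=y,
    )


def compute_r2(fit: ModelFit) -> R2Result:
    """Marginal and conditional R² from the fit's variance components."""
    if not fit.converged:
        raise ConvergenceError("cannot compute R² from a non-converged fit")
    return compute_r2_from_components(
        fit.var_fixed, sum(fit.var_random.values()), fit.var_residual
    )


def compute_r2_from_components(
    var_fixed: float, var_random: float, var_residual: float
) -> R2Result:
    if min(var_fixed, var_random, var_residual) < 0:
        raise ValueError("variance components must be >= 0")
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise ValueError("total variance is zero; R² undefined")
    return R2Result(
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_random) / total,
    )


@dataclass(frozen=True)
class Diagnostics:
    """Residual diagnostics for a fitted model."""

    fitted: np.ndarray
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    influence: np.ndarray


def diagnostics(fit: ModelFit, table: Optional[pd.DataFrame] = None) -> Diagnostics:
    """Residual-vs-fitted values, normal q-q pairs, and per-observation
    influence (leave-one-out displacement of the fixed coefficients, scaled
    by their covariance — a Cook's-distance analogue for the GLS fit).
    """
    if not fit.converged:
        raise ConvergenceError("diagnostics require a converged fit")
    resid = np.asarray(fit.residuals, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    n = len(resid)
    (osm, osr), _ = stats.probplot(resid, dist="norm")

    X, y = fit._X, fit._y
    p = X.shape[1]
    if fit.degenerate:
        return Diagnostics(fitted, resid, osm, osr, np.zeros(n))

    sigma_e = max(fit.var_residual, 1e-300)
    if fit._machinery is not None:
        mach = fit._machinery
        d = np.array([max(fit.var_random[name], 0.0) for name in mach.factor_names])
        dcol = d[mach.col_factor]
        active = dcol > 1e-12 * sigma_e
        Za = mach.Z[:, active]
        # Henderson augmented least squares: deleting a data row of the
        # augmented system is exactly the leave-one-out GLS refit at fixed theta
        M_top = np.hstack([X, Za]) / np.sqrt(sigma_e)
        M_bot = np.hstack([np.zeros((int(active.sum()), p)),
                           np.diag(1.0 / np.sqrt(dcol[active]))])
        M = np.vstack([M_top, M_bot])
        y_aug = np.concatenate([y / np.sqrt(sigma_e), np.zeros(int(active.sum()))])
        cov_beta = fit._machinery.cov_beta(
            np.concatenate([d, [sigma_e]])
        )
    else:
        M = X / np.sqrt(sigma_e)
        y_aug = y / np.sqrt(sigma_e)
        cov_beta = np.linalg.inv(X.T @ X) * sigma_e

    A_inv = np.linalg.inv(M.T @ M)
    coef = A_inv @ (M.T @ y_aug)
    e_aug = y_aug - M @ coef
    cov_beta_inv = np.linalg.inv(cov_beta)
    infl = np.zeros(n)
    Mtop = M[:n]
    h = np.einsum("ij,jk,ik->i", Mtop, A_inv, Mtop)
    for i in range(n):
        denom = 1.0 - h[i]
        if denom <= 1e-12:
            infl[i] = np.inf
            continue
        dcoef = A_inv @ Mtop[i] * (e_aug[i] / denom)
        dbeta = dcoef[:p]
        infl[i] = float(dbeta @ cov_beta_inv @ dbeta) / p
    return Diagnostics(fitted, resid, osm, osr, infl)


def significance_code(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
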