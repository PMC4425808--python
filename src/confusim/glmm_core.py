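"""Binomial GLMM with a logit link and one Gaussian random intercept.

The marginal likelihood integrates the per-group intercept out of the
Bernoulli likelihood,

    L_i(beta, tau) = integral prod_j Bernoulli(y_ij | logit^-1(x_ij' beta + u))
                     phi(u; 0, tau^2) du,

one one-dimensional integral per group.  The integral is evaluated by the
Laplace approximation (the default, and the common software default for
binary mixed models) or by adaptive Gauss-Hermite quadrature of any odd
order; AGQ with order 1 *is* the Laplace approximation, so a single code
path serves both.  The inner mode u_i* is found by a damped Newton
iteration — the integrand is log-concave in u, so this converges fast and
is solved to near machine precision, which keeps the outer objective
smooth enough for finite-difference derivatives.

Fitting maximises the marginal log-likelihood over (beta, log tau) with
bounded L-BFGS-B (log tau bounded below at -10, i.e. tau ~= 4.5e-5, which
is numerically indistinguishable from a pure logistic regression and is
how a zero variance component manifests).  On non-convergence the
optimiser is restarted once from the incumbent, then once from the
logistic-regression start with Nelder-Mead; a fit that still fails is
returned with ``converged=False`` and a warning, never silently.

BIC is -2*loglik + k*log(n) with n the number of Bernoulli observations
and k counting all fixed effects plus the variance component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2

from .formula import ModelSpec, build_matrices, parse_formula

__all__ = [
    "GLMMFit",
    "ModelComparison",
    "BootstrapResult",
    "ConvergenceError",
    "NotNestedError",
    "SeparationError",
    "marginal_loglik",
    "fit",
    "lrt",
    "bic",
    "parametric_bootstrap",
]

_LOGTAU_MIN = -10.0
_LOGTAU_MAX = 3.0


class ConvergenceError(RuntimeError):
    pass


class NotNestedError(ValueError):
    pass


class SeparationError(RuntimeError):
    pass


@dataclass
class GLMMFit:
    """A fitted binomial random-intercept GLMM."""

    spec: ModelSpec
    coef: pd.Series
    tau: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    quad_order: int
    n_groups: int
    message: str = ""
    separation: bool = False
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _group_codes: np.ndarray = field(default=None, repr=False)
    _group_levels: np.ndarray = field(default=None, repr=False)
    _starts: np.ndarray = field(default=None, repr=False)
    _se: pd.Series = field(default=None, repr=False)

    @property
    def beta(self) -> np.ndarray:
        return self.coef.to_numpy()

    def std_errors(self) -> pd.Series:
        """Wald standard errors of (beta, log tau) from the numeric Hessian."""
        if self._se is None:
            psi = np.append(self.beta, np.log(max(self.tau, np.exp(_LOGTAU_MIN))))
            hess = _numeric_hessian(
                lambda p: -_loglik_psi(self._X, self._y, self._starts, p, self.quad_order),
                psi,
            )
            cov = np.linalg.pinv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            self._se = pd.Series(se, index=list(self.coef.index) + ["log_tau"])
        return self._se

    def fitted_linear_predictor(self) -> np.ndarray:
        return self._X @ self.beta

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula,
            "coefficients": dict(self.coef),
            "tau": self.tau,
            "loglik": self.loglik,
            "bic": bic(self) if self.converged else None,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "quad_order": self.quad_order,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test between two nested fits, with BICs."""

    chi_sq: float
    df: int
    p_value: float
    bic_full: float
    bic_reduced: float


@dataclass
class BootstrapResult:
    """Percentile parametric-bootstrap interval for one statistic."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    samples: np.ndarray
    n_failed: int


def _group_starts(group_codes: np.ndarray) -> np.ndarray:
    """reduceat boundaries of the (sorted) group-code vector."""
    return np.flatnonzero(np.r_[True, np.diff(group_codes) != 0])


def _bernoulli_loglik_rows(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable
    return y * eta - np.logaddexp(0.0, eta)


def _inner_mode(eta: np.ndarray, y: np.ndarray, starts: np.ndarray, tau2: float, u0=None):
    """Per-group posterior mode of u and curvature H = -d2h/du2 at the mode.

    h_i(u) = sum_j [y eta - log(1+e^eta)] - u^2/(2 tau2); log-concave, so
    damped Newton from u0 (warm start) converges in a handful of steps.
    """
    n_groups = len(starts)
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    codes = np.repeat(np.arange(n_groups), np.diff(np.r_[starts, len(y)]))

    def h_of(u_vec):
        e = eta + u_vec[codes]
        ll = np.add.reduceat(_bernoulli_loglik_rows(y, e), starts)
        return ll - u_vec**2 / (2.0 * tau2)

    h = h_of(u)
    for _ in range(100):
        e = eta + u[codes]
        mu = expit(e)
        grad = np.add.reduceat(y - mu, starts) - u / tau2
        w = np.add.reduceat(mu * (1.0 - mu), starts)
        H = w + 1.0 / tau2
        if np.max(np.abs(grad)) < 1e-11:
            break
        step = grad / H
        # backtrack any group whose h decreased (rare; h is concave)
        for _ in range(30):
            h_new = h_of(u + step)
            bad = h_new < h - 1e-12
            if not np.any(bad):
                break
            step[bad] *= 0.5
        u = u + step
        h = h_of(u)
    e = eta + u[codes]
    mu = expit(e)
    H = np.add.reduceat(mu * (1.0 - mu), starts) + 1.0 / tau2
    return u, H, h


_hermgauss_cache: dict[int, tuple] = {}


def _hermgauss(order: int):
    if order not in _hermgauss_cache:
        _hermgauss_cache[order] = hermgauss(order)
    return _hermgauss_cache[order]


def _marginal_loglik_arrays(
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    beta: np.ndarray,
    tau: float,
    quad_order: int = 1,
    u0=None,
):
    """Marginal log-likelihood and the inner modes (for warm starting)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    eta = X @ beta
    if tau <= np.exp(_LOGTAU_MIN):
        # degenerate random effect: ordinary logistic log-likelihood
        ll = np.sum(_bernoulli_loglik_rows(y, eta))
        return float(ll), np.zeros(len(starts))
    tau2 = tau**2
    u, H, h = _inner_mode(eta, y, starts, tau2, u0)

    if quad_order <= 1:
        # Laplace: h(u*) - 0.5*log(tau^2 * H); tau2*H = tau2*sum(w) + 1
        ll = h - 0.5 * np.log(tau2 * H)
        return float(np.sum(ll)), u

    nodes, weights = _hermgauss(quad_order)
    sigma = 1.0 / np.sqrt(H)  # (n_groups,)
    codes = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, len(y)]))
    # log integrand at shifted/scaled nodes, per group x node
    a = np.empty((quad_order, len(starts)))
    for k in range(quad_order):
        u_k = u + np.sqrt(2.0) * sigma * nodes[k]
        e = eta + u_k[codes]
        ll_rows = _bernoulli_loglik_rows(y, e)
        h_k = np.add.reduceat(ll_rows, starts) - u_k**2 / (2.0 * tau2)
        a[k] = h_k + nodes[k] ** 2 + np.log(weights[k])
    amax = a.max(axis=0)
    lse = amax + np.log(np.sum(np.exp(a - amax), axis=0))
    ll = np.log(np.sqrt(2.0) * sigma) - 0.5 * np.log(2.0 * np.pi * tau2) + lse
    return float(np.sum(ll)), u


def marginal_loglik(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    coefs,
    tau: float,
    quad_order: int = 1,
) -> float:
    """Marginal log-likelihood of given coefficients on a data table.

    ``coefs`` is a vector in design-matrix column order (intercept first).
    ``quad_order=1`` is the Laplace approximation; odd orders > 1 use
    adaptive Gauss-Hermite quadrature.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    X, names, y, group_codes, _, _ = build_matrices(spec, data)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (X.shape[1],):
        raise ValueError(f"expected {X.shape[1]} coefficients, got {coefs.shape}")
    starts = _group_starts(group_codes)
    ll, _ = _marginal_loglik_arrays(X, y, starts, coefs, tau, quad_order)
    return ll


def _loglik_psi(X, y, starts, psi, quad_order, warm=None):
    beta, logtau = psi[:-1], psi[-1]
    ll, u = _marginal_loglik_arrays(
        X, y, starts, beta, np.exp(logtau), quad_order, None if warm is None else warm.get("u")
    )
    if warm is not None:
        warm["u"] = u
    return ll


def _irls_logistic(X: np.ndarray, y: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Plain logistic regression by IRLS (starting values for the GLMM)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(X.T @ wx, wx.T @ z, rcond=None)[0]
        new = np.clip(new, -30, 30)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    return beta


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return hess


def fit(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    quad_order: int = 1,
    start: np.ndarray | None = None,
    tau_start: float = 0.5,
    fix_tau: float | None = None,
) -> GLMMFit:
    """Maximum-likelihood fit of a binomial random-intercept GLMM.

    ``start`` may give (beta..., log tau) to warm-start (used heavily by
    the parametric bootstrap).  ``fix_tau`` pins the random-intercept SD
    instead of estimating it (fix_tau=0 is ordinary logistic regression).
    Deterministic given data and start.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    X, names, y, group_codes, group_levels, _ = build_matrices(spec, data)
    if len(group_levels) < 2:
        raise ValueError("need at least two groups to estimate a random intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    starts = _group_starts(group_codes)
    return _fit_arrays(spec, X, names, y, group_codes, group_levels, starts,
                       quad_order, start, tau_start, fix_tau)


def _fit_arrays(
    spec, X, names, y, group_codes, group_levels, starts, quad_order,
    start=None, tau_start=0.5, fix_tau=None,
) -> GLMMFit:
    warm: dict = {}
    logtau_fixed = None
    if fix_tau is not None:
        if fix_tau < 0:
            raise ValueError("fix_tau must be non-negative")
        logtau_fixed = np.log(max(fix_tau, np.exp(_LOGTAU_MIN)))

    def objective(psi):
        if logtau_fixed is not None:
            psi = np.append(psi, logtau_fixed)
        return -_loglik_psi(X, y, starts, psi, quad_order, warm)

    if start is not None:
        psi0 = np.asarray(start, dtype=float)
    else:
        beta0 = _irls_logistic(X, y)
        psi0 = np.append(beta0, np.log(tau_start))
    psi0[-1] = np.clip(psi0[-1], _LOGTAU_MIN, _LOGTAU_MAX)

    if logtau_fixed is not None:
        psi0 = psi0[:-1]
        bounds = [(None, None)] * X.shape[1]
    else:
        bounds = [(None, None)] * X.shape[1] + [(_LOGTAU_MIN, _LOGTAU_MAX)]
    res = optimize.minimize(
        objective, psi0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500, "maxfun": 100000},
    )
    if not res.success:  # restart from the incumbent
        res2 = optimize.minimize(
            objective, res.x, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500, "maxfun": 100000},
        )
        if res2.fun <= res.fun:
            res = res2
    if not res.success and X.shape[1] <= 12:
        res3 = optimize.minimize(
            objective, psi0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000},
        )
        if logtau_fixed is None:
            res3.x[-1] = np.clip(res3.x[-1], _LOGTAU_MIN, _LOGTAU_MAX)
        if res3.fun <= res.fun:
            res = res3

    psi = res.x
    if logtau_fixed is not None:
        beta = psi
        tau = float(fix_tau)
    else:
        beta = psi[:-1]
        tau = float(np.exp(np.clip(psi[-1], _LOGTAU_MIN, _LOGTAU_MAX)))
    loglik = -float(res.fun)
    converged = bool(res.success) or res.status == 0
    # scale-invariant heuristic: an extreme linear predictor or constant
    # response signals (quasi-)separation
    separation = bool(np.max(np.abs(X @ beta)) > 30.0 or len(np.unique(y)) < 2)
    if not converged:
        warnings.warn(f"GLMM fit did not converge: {res.message}", RuntimeWarning)
    if separation:
        warnings.warn("possible (quasi-)separation: extreme coefficients", RuntimeWarning)

    return GLMMFit(
        spec=spec,
        coef=pd.Series(beta, index=names),
        tau=tau,
        loglik=loglik,
        n_obs=len(y),
        n_params=X.shape[1] + (0 if logtau_fixed is not None else 1),
        converged=converged,
        quad_order=quad_order,
        n_groups=len(group_levels),
        message=str(res.message),
        separation=separation,
        _X=X,
        _y=y,
        _group_codes=group_codes,
        _group_levels=group_levels,
        _starts=starts,
    )


def _is_nested(full: GLMMFit, reduced: GLMMFit, tol: float = 1e-8) -> bool:
    """Column space of the reduced design contained in the full design."""
    coef, res, *_ = np.linalg.lstsq(full._X, reduced._X, rcond=None)
    proj = full._X @ coef
    resid = np.linalg.norm(reduced._X - proj)
    return resid <= tol * max(1.0, np.linalg.norm(reduced._X))


def lrt(full: GLMMFit, reduced: GLMMFit) -> ModelComparison:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if full.n_obs != reduced.n_obs:
        raise NotNestedError("models fitted on different numbers of rows")
    if not np.array_equal(np.sort(full._y), np.sort(reduced._y)):
        raise NotNestedError("models fitted on different responses")
    df = full.n_params - reduced.n_params
    if df < 0 or (df == 0 and full.spec.formula != reduced.spec.formula):
        raise NotNestedError("reduced model has at least as many parameters as the full model")
    if not _is_nested(full, reduced):
        raise NotNestedError("reduced design is not in the span of the full design")
    chi_sq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(chi2.sf(chi_sq, df)) if df > 0 else 1.0
    if df == 0:
        chi_sq = 0.0
    return ModelComparison(
        chi_sq=chi_sq,
        df=df,
        p_value=p,
        bic_full=bic(full),
        bic_reduced=bic(reduced),
    )


def bic(fit_: GLMMFit) -> float:
    """Bayesian information criterion, n = number of Bernoulli observations."""
    if not fit_.converged:
        raise ConvergenceError("refusing to compute BIC for an unconverged fit")
    if fit_.n_params < 1:
        raise ValueError("fit has no parameters")
    return -2.0 * fit_.loglik + fit_.n_params * np.log(fit_.n_obs)


def parametric_bootstrap(
    fit_: GLMMFit,
    data: pd.DataFrame = None,
    statistic="all",
    n_boot: int = 1000,
    seed=None,
    level: float = 0.95,
):
    """Percentile parametric-bootstrap confidence intervals.

    Each replicate draws fresh group intercepts from Normal(0, tau_hat^2)
    and fresh Bernoulli responses from the fitted probabilities, refits
    the model (warm-started at the fitted optimum), and records the
    statistic.  ``statistic`` is a coefficient name, "tau", a callable
    ``GLMMFit -> float``, or "all" (every coefficient plus tau, returned
    as a dict).  Replicates that fail to converge are dropped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if not fit_.converged:
        raise ConvergenceError("cannot bootstrap an unconverged fit")
    if len(np.unique(fit_._y)) < 2:
        raise SeparationError("degenerate responses (all identical): no interval")
    if fit_.separation:
        raise SeparationError("fit flagged as separated: no interval")

    rng = np.random.default_rng(seed)
    X, y, starts = fit_._X, fit_._y, fit_._starts
    codes = fit_._group_codes
    eta_fixed = X @ fit_.beta
    psi_hat = np.append(fit_.beta, np.log(max(fit_.tau, np.exp(_LOGTAU_MIN))))

    stats = _statistic_extractors(fit_, statistic)
    samples = {name: [] for name in stats}
    n_failed = 0
    for _ in range(n_boot):
        u = rng.normal(0.0, fit_.tau, size=fit_.n_groups)
        p = expit(eta_fixed + u[codes])
        y_b = (rng.uniform(size=len(y)) < p).astype(float)
        if len(np.unique(y_b)) < 2:
            n_failed += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boot = _fit_arrays(
                fit_.spec, X, fit_.coef.index.tolist(), y_b, codes,
                fit_._group_levels, starts, fit_.quad_order, start=psi_hat,
            )
        if not boot.converged:
            n_failed += 1
            continue
        for name, f in stats.items():
            samples[name].append(f(boot))

    alpha = (1.0 - level) / 2.0
    out = {}
    for name, f in stats.items():
        arr = np.asarray(samples[name])
        if arr.size == 0:
            raise ConvergenceError("no bootstrap replicate converged")
        lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
        out[name] = BootstrapResult(
            statistic=name,
            estimate=f(fit_),
            ci_low=float(lo),
            ci_high=float(hi),
            level=level,
            samples=arr,
            n_failed=n_failed,
        )
    if isinstance(statistic, str) and statistic != "all":
        return out[statistic]
    if callable(statistic):
        return out["statistic"]
    return out


def _statistic_extractors(fit_: GLMMFit, statistic) -> dict:
    if callable(statistic):
        return {"statistic": statistic}
    if statistic == "all":
        ext = {name: (lambda f, n=name: float(f.coef[n])) for name in fit_.coef.index}
        ext["tau"] = lambda f: float(f.tau)
        return ext
    if statistic == "tau":
        return {"tau": lambda f: float(f.tau)}
    if statistic in fit_.coef.index:
        return {statistic: (lambda f, n=statistic: float(f.coef[n]))}
    raise KeyError(f"unknown statistic {statistic!r}")
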