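"""Logistic distributional regression of weekly p-scores.

Both the location ``mu_t`` and the (log-linked) scale ``sigma_t`` of a
logistic response distribution are linear in covariates:

    mu_t    = mu_0 + sum_j mu_j X_{t,j}
    sigma_t = exp(sigma_0 + sum_j sigma_j X_{t,j})

Estimation is by maximum likelihood with analytic gradients; covariate
rosters for the two parameters are chosen by stepwise search on the
Hannan-Quinn Information Criterion (HQC).  Model adequacy is checked with
normalized quantile residuals, and uncertainty for downstream indicators by
i.i.d. resampling of weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "LogisticDistFit",
    "BootstrapResult",
    "loglik",
    "hqc",
    "fit_mle",
    "stepwise_select",
    "quantile_residuals",
    "bootstrap_cis",
]

INTERCEPT = "(Intercept)"


def hqc(loglik_value: float, k: int, n: int) -> float:
    """Hannan-Quinn Information Criterion: -2 logL + 2 k ln(ln n)."""
    return -2.0 * loglik_value + 2.0 * k * np.log(np.log(n))


def loglik(
    params: np.ndarray,
    Xmu: np.ndarray,
    Xsig: np.ndarray,
    y: np.ndarray,
    grad: bool = False,
):
    """Log-likelihood of the logistic location-scale regression.

    ``params`` concatenates the mu coefficients (length ``Xmu.shape[1]``)
    and the log-scale coefficients.  Each observation contributes
    ``-z - log(sigma) - 2 log(1 + exp(-z))`` with ``z = (y - mu) / sigma``.
    With ``grad=True`` returns ``(loglik, gradient)``.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    pm = Xmu.shape[1]
    bmu, bsig = params[:pm], params[pm:]
    mu = Xmu @ bmu
    eta = Xsig @ bsig
    sig = np.exp(eta)
    z = (y - mu) / sig
    # -z - eta - 2*log(1+exp(-z)), stable via log_expit(z) = -log(1+exp(-z))
    ll = float(np.sum(-z - eta + 2.0 * log_expit(z)))
    if not grad:
        return ll
    w = 2.0 * expit(z) - 1.0  # d loglik / dz * (-1)
    gmu = Xmu.T @ (w / sig)
    gsig = Xsig.T @ (z * w - 1.0)
    return ll, np.concatenate([gmu, gsig])


@dataclass
class LogisticDistFit:
    """Fitted (or externally specified) logistic distributional model."""

    mu_terms: tuple[str, ...]
    sigma_terms: tuple[str, ...]
    mu_coeffs: dict[str, float]
    sigma_coeffs: dict[str, float]
    n: int = 0
    loglik: float = np.nan
    hqc: float = np.nan
    cov: np.ndarray | None = None
    converged: bool = True

    @classmethod
    def from_coeffs(
        cls,
        mu_coeffs: dict[str, float],
        sigma_coeffs: dict[str, float],
    ) -> "LogisticDistFit":
        """Build a fit object directly from known coefficients (e.g. a
        published table); intercepts are keyed ``"(Intercept)"``."""
        mu = dict(mu_coeffs)
        sg = dict(sigma_coeffs)
        mu.setdefault(INTERCEPT, 0.0)
        sg.setdefault(INTERCEPT, 0.0)
        return cls(
            mu_terms=tuple(k for k in mu if k != INTERCEPT),
            sigma_terms=tuple(k for k in sg if k != INTERCEPT),
            mu_coeffs=mu,
            sigma_coeffs=sg,
        )

    @property
    def param_names(self) -> list[str]:
        return [f"mu.{INTERCEPT}"] + [f"mu.{t}" for t in self.mu_terms] + [
            f"sigma.{INTERCEPT}"
        ] + [f"sigma.{t}" for t in self.sigma_terms]

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.mu_coeffs[INTERCEPT]]
            + [self.mu_coeffs[t] for t in self.mu_terms]
            + [self.sigma_coeffs[INTERCEPT]]
            + [self.sigma_coeffs[t] for t in self.sigma_terms]
        )

    @property
    def k(self) -> int:
        return 2 + len(self.mu_terms) + len(self.sigma_terms)

    def predict_mu(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.mu_coeffs[INTERCEPT], dtype=float)
        for t in self.mu_terms:
            out += self.mu_coeffs[t] * table[t].to_numpy(dtype=float)
        return out

    def predict_sigma(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.sigma_coeffs[INTERCEPT], dtype=float)
        for t in self.sigma_terms:
            eta += self.sigma_coeffs[t] * table[t].to_numpy(dtype=float)
        return np.exp(eta)

    def se(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("no covariance available (fit not estimated)")
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, Wald 95% CI, p-value."""
        est = self.params
        se = self.se()
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "p_value": p,
            }
        )


def _design(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for t in terms:
        cols.append(table[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _clean(table: pd.DataFrame, terms: set[str], response: str) -> pd.DataFrame:
    cols = [response] + sorted(terms)
    return table.dropna(subset=[c for c in cols if c in table.columns])


def fit_mle(
    table: pd.DataFrame,
    mu_covariates: tuple[str, ...] | list[str] = (),
    sigma_covariates: tuple[str, ...] | list[str] = (),
    response: str = "pscore",
    max_restarts: int = 5,
    compute_cov: bool = True,
    start: np.ndarray | None = None,
) -> LogisticDistFit:
    """Maximum-likelihood fit of the logistic distributional regression.

    Rows with missing response or covariates (e.g. the first week's lag)
    are dropped.  Optimization is quasi-Newton (BFGS) with the analytic
    gradient, restarted with a jittered scale intercept on non-convergence
    (up to ``max_restarts`` attempts).  The coefficient covariance is the
    inverse observed information (finite differences of the gradient).
    """
    mu_terms = tuple(mu_covariates)
    sig_terms = tuple(sigma_covariates)
    data = _clean(table, set(mu_terms) | set(sig_terms), response)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    k = 2 + len(mu_terms) + len(sig_terms)
    if n < 10 * k:
        raise ValueError(f"need >= 10x more weeks ({n}) than coefficients ({k})")
    Xmu = _design(data, mu_terms)
    Xsig = _design(data, sig_terms)

    if start is not None:
        x0 = np.asarray(start, dtype=float).copy()
    else:
        x0 = np.zeros(k)
        x0[0] = np.median(y)
        sd = max(np.std(y), 1e-6)
        x0[len(mu_terms) + 1] = np.log(sd * np.sqrt(3.0) / np.pi)

    def neg(p):
        ll, g = loglik(p, Xmu, Xsig, y, grad=True)
        return -ll, -g

    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(max_restarts):
        xs = x0.copy()
        if attempt > 0:
            xs[len(mu_terms) + 1] += rng.normal(0.0, 0.5)
        res = minimize(neg, xs, jac=True, method="BFGS",
                       options={"gtol": 1e-7, "maxiter": 1000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
        if res.success or (np.linalg.norm(res.jac, np.inf) < 1e-4 * max(1.0, abs(res.fun))):
            best = res if best is None or res.fun <= best.fun else best
            break
    else:
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("MLE did not converge after restarts")
    params = best.x
    ll = -best.fun

    cov = None
    if compute_cov:
        H = _fd_hessian(lambda p: loglik(p, Xmu, Xsig, y, grad=True)[1], params)
        try:
            cov = np.linalg.inv(-(H + H.T) / 2.0)
        except np.linalg.LinAlgError:
            cov = None

    pm = len(mu_terms) + 1
    mu_coeffs = {INTERCEPT: params[0], **{t: params[1 + i] for i, t in enumerate(mu_terms)}}
    sig_coeffs = {INTERCEPT: params[pm], **{t: params[pm + 1 + i] for i, t in enumerate(sig_terms)}}
    return LogisticDistFit(
        mu_terms=mu_terms,
        sigma_terms=sig_terms,
        mu_coeffs=mu_coeffs,
        sigma_coeffs=sig_coeffs,
        n=n,
        loglik=ll,
        hqc=hqc(ll, k, n),
        cov=cov,
        converged=bool(best.success),
    )


def _fd_hessian(grad_fn, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic gradient."""
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        step = h * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * step)
    return H


def stepwise_select(
    table: pd.DataFrame,
    candidates: tuple[str, ...] | list[str],
    response: str = "pscore",
    max_restarts: int = 2,
) -> LogisticDistFit:
    """Three-phase stepwise covariate selection on HQC.

    1. forward-backward on the mu terms with an intercept-only sigma;
    2. forward-backward on the sigma terms given the chosen mu roster;
    3. backward re-check of the mu terms given the chosen sigma roster.

    Candidates are scanned alphabetically and the first strictly
    HQC-decreasing move is taken, so the procedure is deterministic.  All
    models are fitted on the common complete-case rows of the full
    candidate set, keeping HQC values comparable.
    """
    cands = tuple(sorted(candidates))
    data = _clean(table, set(cands), response)
    cache: dict[tuple, LogisticDistFit] = {}

    def fit_for(mu_set: tuple[str, ...], sig_set: tuple[str, ...]) -> LogisticDistFit:
        key = (mu_set, sig_set)
        if key not in cache:
            cache[key] = fit_mle(
                data, mu_set, sig_set, response=response,
                max_restarts=max_restarts, compute_cov=False,
            )
        return cache[key]

    def forward_backward(mu_set, sig_set, vary: str):
        current = fit_for(mu_set, sig_set)
        improved = True
        while improved:
            improved = False
            active = mu_set if vary == "mu" else sig_set
            moves = [("add", c) for c in cands if c not in active]
            moves += [("drop", c) for c in active]
            for kind, c in moves:
                new = tuple(sorted(set(active) | {c})) if kind == "add" else tuple(
                    sorted(set(active) - {c})
                )
                trial_mu = new if vary == "mu" else mu_set
                trial_sig = new if vary == "sigma" else sig_set
                trial = fit_for(trial_mu, trial_sig)
                if trial.hqc < current.hqc - 1e-9:
                    current, mu_set, sig_set = trial, trial_mu, trial_sig
                    improved = True
                    break
        return mu_set, sig_set

    mu_set, sig_set = forward_backward((), (), "mu")
    mu_set, sig_set = forward_backward(mu_set, sig_set, "sigma")

    # phase 3: backward on mu only
    current = fit_for(mu_set, sig_set)
    improved = True
    while improved:
        improved = False
        for c in mu_set:
            trial_mu = tuple(sorted(set(mu_set) - {c}))
            trial = fit_for(trial_mu, sig_set)
            if trial.hqc < current.hqc - 1e-9:
                current, mu_set = trial, trial_mu
                improved = True
                break

    return fit_mle(data, mu_set, sig_set, response=response, max_restarts=5)


@dataclass
class QuantileResiduals:
    residuals: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    worm_x: np.ndarray  # theoretical normal quantiles (sorted)
    worm_y: np.ndarray  # detrended QQ deviations


def quantile_residuals(
    fit: LogisticDistFit, table: pd.DataFrame, response: str = "pscore"
) -> QuantileResiduals:
    """Normalized quantile residuals and KS test against N(0, 1).

    r_t = Phi^-1(F(y_t; mu_t, sigma_t)) with the logistic CDF F; the worm
    ordinates are sorted residuals minus the corresponding standard-normal
    quantiles (detrended QQ plot).
    """
    data = _clean(table, set(fit.mu_terms) | set(fit.sigma_terms), response)
    y = data[response].to_numpy(dtype=float)
    mu = fit.predict_mu(data)
    sig = fit.predict_sigma(data)
    u = expit((y - mu) / sig)
    eps = 1e-12
    if ((u <= 0) | (u >= 1)).any():
        warnings.warn("CDF values clamped to (eps, 1-eps)", stacklevel=2)
    u = np.clip(u, eps, 1.0 - eps)
    r = stats.norm.ppf(u)
    ks = stats.kstest(r, "norm")
    order = np.argsort(r)
    n = len(r)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return QuantileResiduals(
        residuals=r,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        worm_x=theo,
        worm_y=r[order] - theo,
    )


@dataclass
class BootstrapResult:
    param_names: list[str]
    params: np.ndarray  # (n_ok, k)
    indicator_names: list[str] = field(default_factory=list)
    indicators: np.ndarray | None = None
    n_failed: int = 0

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        a = 100.0 * (1.0 - level) / 2.0
        lo = np.percentile(self.params, a, axis=0)
        hi = np.percentile(self.params, 100.0 - a, axis=0)
        return pd.DataFrame(
            {"parameter": self.param_names, "ci_low": lo, "ci_high": hi}
        )

    def indicator_ci(self, level: float = 0.95) -> pd.DataFrame:
        if self.indicators is None:
            raise ValueError("no indicators were computed")
        a = 100.0 * (1.0 - level) / 2.0
        lo = np.nanpercentile(self.indicators, a, axis=0)
        hi = np.nanpercentile(self.indicators, 100.0 - a, axis=0)
        return pd.DataFrame(
            {"indicator": self.indicator_names, "ci_low": lo, "ci_high": hi}
        )


def bootstrap_cis(
    table: pd.DataFrame,
    mu_covariates: tuple[str, ...] | list[str],
    sigma_covariates: tuple[str, ...] | list[str],
    B: int = 1000,
    seed: int = 0,
    response: str = "pscore",
    indicator_fn=None,
    max_fail_frac: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap over i.i.d. resampling of week rows.

    Each replicate refits the logistic model; ``indicator_fn(fit, sample)``
    may compute downstream indicators (dict of name -> value) that get their
    own percentile intervals.  More than ``max_fail_frac`` failed replicate
    fits raises.  Deterministic given ``seed``.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    mu_terms = tuple(mu_covariates)
    sig_terms = tuple(sigma_covariates)
    data = _clean(table, set(mu_terms) | set(sig_terms), response).reset_index(drop=True)
    n = len(data)
    base = fit_mle(data, mu_terms, sig_terms, response=response, compute_cov=False)
    start = base.params

    rng = np.random.default_rng(seed)
    rows, ind_rows, ind_names = [], [], None
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            fit = fit_mle(
                sample, mu_terms, sig_terms, response=response,
                compute_cov=False, start=start, max_restarts=3,
            )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        rows.append(fit.params)
        if indicator_fn is not None:
            ind = indicator_fn(fit, sample)
            if ind_names is None:
                ind_names = list(ind)
            ind_rows.append([ind[k] for k in ind_names])
    if n_failed > max_fail_frac * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap fits failed")
    return BootstrapResult(
        param_names=base.param_names,
        params=np.asarray(rows),
        indicator_names=ind_names or [],
        indicators=np.asarray(ind_rows) if ind_rows else None,
        n_failed=n_failed,
    )
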