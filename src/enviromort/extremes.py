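"""Occurrence and intensity of extreme excess-mortality events.

An extreme event is a week whose p-score exceeds the empirical 90th
percentile ``u90``.  The fitted logistic distributional model yields
conditional exceedance probabilities and a closed-form per-unit odds
ratio; temporal clustering is summarized by the Ferro-Segers intervals
estimator of the extremal index, and intensity by return levels / return
periods derived from the covariate-averaged weekly distribution adjusted
with ``lambda * theta`` observations per year.  An exponential tail fitted
to threshold excesses provides a comparison curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .distreg import INTERCEPT, LogisticDistFit, hqc

__all__ = [
    "WEEKS_PER_YEAR",
    "empirical_threshold",
    "exceedance_probability",
    "odds_ratio",
    "fit_binomial_occurrence",
    "extremal_index",
    "mean_cluster_duration",
    "return_level",
    "return_period",
    "ExponentialTail",
    "exponential_tail",
]

#: Average number of weekly observations per year.
WEEKS_PER_YEAR = 365.25 / 7.0


def empirical_threshold(pscores: np.ndarray | pd.Series, q: float = 0.90) -> float:
    """Empirical quantile of the p-scores (linear interpolation between
    order statistics, quantile type 7)."""
    y = np.asarray(pd.Series(pscores).dropna(), dtype=float)
    if len(y) < 50:
        raise ValueError(f"need >= 50 weeks, got {len(y)}")
    return float(np.quantile(y, q, method="linear"))


def _conditional_params(
    fit: LogisticDistFit, covariate: str, x: float
) -> tuple[float, float]:
    """(mu, sigma) with covariate j at x and all other covariates at zero."""
    mu = fit.mu_coeffs[INTERCEPT] + fit.mu_coeffs.get(covariate, 0.0) * x
    eta = fit.sigma_coeffs[INTERCEPT] + fit.sigma_coeffs.get(covariate, 0.0) * x
    return mu, float(np.exp(eta))


def exceedance_probability(
    fit: LogisticDistFit, covariate: str, x: float, u: float
) -> float:
    """P(Y > u | X_j = x, all other covariates zero) under the fitted
    logistic distribution: 1 - F(u; mu0 + mu_j x, exp(sigma0 + sigma_j x))."""
    mu, sig = _conditional_params(fit, covariate, x)
    return float(expit((mu - u) / sig))


def odds_ratio(fit: LogisticDistFit, covariate: str, u: float | None = None) -> float:
    """Per-unit odds ratio for an extreme event from the fitted model.

    When the scale predictor does not involve the covariate, the closed
    form ``exp(mu_j / exp(sigma_0))`` applies and is independent of the
    threshold.  Otherwise the closed form is refused and a
    threshold-specific numeric OR at ``u`` is returned with a warning.
    """
    mu_j = fit.mu_coeffs.get(covariate)
    if mu_j is None:
        raise ValueError(f"covariate {covariate!r} not in mu roster")
    if covariate in fit.sigma_terms:
        if u is None:
            raise ValueError(
                f"scale depends on {covariate!r}: closed form invalid; pass a "
                "threshold u for a numeric OR"
            )
        warnings.warn(
            f"scale depends on {covariate!r}; returning threshold-specific OR",
            stacklevel=2,
        )
        p1 = exceedance_probability(fit, covariate, 1.0, u)
        p0 = exceedance_probability(fit, covariate, 0.0, u)
        return float((p1 / (1 - p1)) / (p0 / (1 - p0)))
    return float(np.exp(mu_j / np.exp(fit.sigma_coeffs[INTERCEPT])))


def fit_binomial_occurrence(
    weekly: pd.DataFrame,
    u: float,
    candidates: list[str] | tuple[str, ...],
    response: str = "pscore",
    backward: bool = True,
) -> tuple[pd.Series, object]:
    """Binomial logistic regression for the event indicator 1{Y > u}.

    Covariates are pruned by backward elimination minimizing HQC (disable
    with ``backward=False`` to keep the full candidate roster).  Returns
    (odds ratios per retained covariate incl. intercept, fitted GLM).
    Complete separation raises with the offending covariate named.
    """
    data = weekly.dropna(subset=[response, *candidates]).copy()
    data["_event"] = (data[response] > u).astype(float)
    terms = sorted(candidates)

    def _fit(active):
        X = sm.add_constant(data[list(active)], has_constant="add") if active else (
            pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
        )
        model = sm.GLM(data["_event"], X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
            bad = [c for c, s in res.bse.items() if not np.isfinite(s) or s > 1e4]
            raise RuntimeError(f"possible complete separation for {bad}")
        return res

    current = _fit(terms)
    current_hqc = hqc(current.llf, len(current.params), len(data))
    improved = backward
    while improved and terms:
        improved = False
        for c in list(terms):
            trial_terms = [t for t in terms if t != c]
            trial = _fit(trial_terms)
            trial_hqc = hqc(trial.llf, len(trial.params), len(data))
            if trial_hqc < current_hqc - 1e-9:
                current, current_hqc, terms = trial, trial_hqc, trial_terms
                improved = True
                break
    ors = np.exp(current.params).rename("odds_ratio")
    return ors, current


def extremal_index(pscores: np.ndarray | pd.Series, u: float) -> float:
    """Ferro-Segers intervals estimator of the extremal index.

    With exceedance times ``s_1 < ... < s_N`` and interexceedance times
    ``T_i = s_{i+1} - s_i``: if max T_i > 2, use the shifted variant
    ``min(1, 2 (sum (T_i - 1))^2 / (N_int sum (T_i - 1)(T_i - 2)))``,
    otherwise ``min(1, 2 (sum T_i)^2 / (N_int sum T_i^2))``.
    """
    y = np.asarray(pd.Series(pscores), dtype=float)
    times = np.flatnonzero(y > u) + 1  # 1-based observation times
    if len(times) < 2:
        raise ValueError("need at least 2 exceedances")
    T = np.diff(times).astype(float)
    n_int = len(T)
    if T.max() > 2:
        num = 2.0 * np.sum(T - 1.0) ** 2
        den = n_int * np.sum((T - 1.0) * (T - 2.0))
    else:
        num = 2.0 * np.sum(T) ** 2
        den = n_int * np.sum(T**2)
    return float(min(1.0, num / den))


def mean_cluster_duration(theta: float) -> float:
    """Average cluster length implied by the extremal index: 1 / theta."""
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    return 1.0 / theta


def _averaged_params(fit: LogisticDistFit, weekly: pd.DataFrame) -> tuple[float, float]:
    """Covariate-averaged (mu, sigma).

    Averaging conditional logistic quantiles over observed weeks is, by
    linearity of the location-scale quantile function, a logistic quantile
    function with the averaged parameters; the same pair therefore defines
    the averaged distribution used for return periods.
    """
    cols = sorted(set(fit.mu_terms) | set(fit.sigma_terms))
    data = weekly.dropna(subset=[c for c in cols if c in weekly.columns])
    return float(np.mean(fit.predict_mu(data))), float(np.mean(fit.predict_sigma(data)))


def return_level(
    fit: LogisticDistFit,
    weekly: pd.DataFrame,
    T: float,
    theta: float,
    lam: float = WEEKS_PER_YEAR,
) -> float:
    """T-year return level of weekly p-scores.

    p = (1 - 1/T)^(1/(lambda theta)); the conditional quantile
    ``mu_t + sigma_t log(p / (1-p))`` is averaged across all observed
    covariate weeks.
    """
    if T <= 1:
        raise ValueError("return period T must exceed 1 year")
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    p = (1.0 - 1.0 / T) ** (1.0 / (lam * theta))
    mu_bar, sig_bar = _averaged_params(fit, weekly)
    return float(mu_bar + sig_bar * np.log(p / (1.0 - p)))


def return_period(
    fit: LogisticDistFit,
    weekly: pd.DataFrame,
    y_event: float,
    theta: float,
    lam: float = WEEKS_PER_YEAR,
) -> float:
    """Return period of a given p-score level: T = 1 / (1 - F^(lambda theta))
    with F the covariate-averaged weekly distribution (exact inverse of
    :func:`return_level`)."""
    if not np.isfinite(y_event):
        raise ValueError("y_event must be finite")
    mu_bar, sig_bar = _averaged_params(fit, weekly)
    F = expit((y_event - mu_bar) / sig_bar)
    return float(1.0 / (1.0 - F ** (lam * theta)))


@dataclass
class ExponentialTail:
    """Exponential excess model above a threshold u.

    Tail CDF for y >= u: ``F(y) = 1 - zeta_u * exp(-(y - u) / beta)`` with
    ``zeta_u`` the empirical exceedance fraction and ``beta`` the MLE (mean
    excess).  Return levels/periods use the same annual-maximum
    approximation ``F^(lambda theta)`` as the logistic model.
    """

    u: float
    beta: float
    zeta: float
    theta: float
    lam: float = WEEKS_PER_YEAR
    n_exceed: int = 0

    def cdf(self, y: float) -> float:
        if y < self.u:
            raise ValueError("tail CDF defined only above the threshold")
        return float(1.0 - self.zeta * np.exp(-(y - self.u) / self.beta))

    def return_level(self, T: float) -> float:
        if T <= 1:
            raise ValueError("return period T must exceed 1 year")
        p = (1.0 - 1.0 / T) ** (1.0 / (self.lam * self.theta))
        if 1.0 - p > self.zeta:
            raise ValueError("return period too short for the fitted tail")
        return float(self.u + self.beta * np.log(self.zeta / (1.0 - p)))

    def return_period(self, y_event: float) -> float:
        F = self.cdf(y_event)
        return float(1.0 / (1.0 - F ** (self.lam * self.theta)))


def exponential_tail(
    pscores: np.ndarray | pd.Series,
    u: float,
    theta: float,
    lam: float = WEEKS_PER_YEAR,
) -> ExponentialTail:
    """Fit the exponential excess model to p-scores above ``u``."""
    y = np.asarray(pd.Series(pscores).dropna(), dtype=float)
    exc = y[y > u] - u
    if len(exc) < 10:
        raise ValueError(f"need >= 10 exceedances, got {len(exc)}")
    return ExponentialTail(
        u=float(u),
        beta=float(exc.mean()),
        zeta=float(len(exc) / len(y)),
        theta=float(theta),
        lam=float(lam),
        n_exceed=int(len(exc)),
    )
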