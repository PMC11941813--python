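"""Weekly age-standardized mortality rates, median-regression baseline and
p-scores.

The baseline is the conditional median of weekly ASMR fitted on a long-term
trend basis (cubic B-splines) plus a cyclic cubic B-spline seasonal basis,
with quadratic roughness penalties; the p-score of week *t* is the relative
excess ``Y_t = 100 * (ASMR_t - B_t) / B_t`` in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = [
    "ESP_2013",
    "StandardPopulationWeights",
    "BaselineFit",
    "weekly_asmr",
    "interpolate_population",
    "fit_median_baseline",
    "compute_pscores",
]

# European Standard Population 2013, 21 age bands, weights per 100,000.
ESP_2013: dict[str, float] = {
    "0": 1000.0,
    "1-4": 4000.0,
    "5-9": 5500.0,
    "10-14": 5500.0,
    "15-19": 5500.0,
    "20-24": 6000.0,
    "25-29": 6000.0,
    "30-34": 6500.0,
    "35-39": 7000.0,
    "40-44": 7000.0,
    "45-49": 7000.0,
    "50-54": 7000.0,
    "55-59": 6500.0,
    "60-64": 6000.0,
    "65-69": 5500.0,
    "70-74": 5000.0,
    "75-79": 4000.0,
    "80-84": 2500.0,
    "85-89": 1500.0,
    "90-94": 800.0,
    "95+": 200.0,
}
assert sum(ESP_2013.values()) == 100_000.0


@dataclass(frozen=True)
class StandardPopulationWeights:
    """Standard-population weights per 100,000; defaults to ESP 2013."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(ESP_2013))

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if abs(total - 100_000.0) > 1e-6:
            raise ValueError(f"weights must sum to 100,000 (got {total})")


def weekly_asmr(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    weights: Mapping[str, float] | StandardPopulationWeights | None = None,
) -> pd.Series:
    """Directly age-standardized mortality rate per 100,000.

    ``deaths`` and ``population`` are wide tables (rows = weeks, columns =
    age bands).  ASMR_t = sum_a w_a * deaths_{t,a} / pop_{t,a} with the
    standard weights w_a summing to 100,000, so the result is per 100,000.
    """
    if weights is None:
        weights = StandardPopulationWeights()
    if isinstance(weights, StandardPopulationWeights):
        weights = weights.weights
    bands = list(deaths.columns)
    if set(bands) != set(population.columns) or set(bands) - set(weights):
        raise ValueError("age bands of deaths, population and weights must align")
    d = deaths[bands].to_numpy(dtype=float)
    p = population[bands].to_numpy(dtype=float)
    if ((p == 0) & (d > 0)).any():
        raise ValueError("zero population in a band with nonzero deaths")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(p > 0, d / p, 0.0)
    w = np.array([weights[b] for b in bands], dtype=float)
    return pd.Series(rates @ w, index=deaths.index, name="asmr")


def interpolate_population(
    annual: pd.Series | pd.DataFrame, dates: pd.DatetimeIndex
) -> pd.Series | pd.DataFrame:
    """Linear interpolation of annual population (anchored at 1 January) to
    arbitrary dates; flat extension beyond the first/last year."""
    frame = annual.to_frame() if isinstance(annual, pd.Series) else annual
    if len(frame) < 2:
        raise ValueError("need at least two annual population values")
    years = np.asarray(frame.index, dtype=int)
    anchors = pd.to_datetime([f"{y}-01-01" for y in years]).astype("int64")
    t = pd.to_datetime(dates).astype("int64")
    out = {}
    for col in frame.columns:
        out[col] = np.interp(t, anchors, frame[col].to_numpy(dtype=float))
    res = pd.DataFrame(out, index=dates)
    return res.iloc[:, 0].rename(annual.name) if isinstance(annual, pd.Series) else res


# ---------------------------------------------------------------------------
# penalized median regression baseline


def _open_bspline_design(x: np.ndarray, lo: float, hi: float, n_interior: int) -> tuple[np.ndarray, np.ndarray]:
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * 4, interior, [hi] * 4]
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, 3, extrapolate=False).toarray()
    return B, t


def _cyclic_bspline_design(x: np.ndarray, n_basis: int, period: float) -> np.ndarray:
    K = n_basis
    h = period / K
    t = np.arange(-3, K + 4) * h
    B = BSpline.design_matrix(np.mod(x, period), t, 3, extrapolate=False).toarray()
    for j in range(3):
        B[:, j] += B[:, j + K]
    return B[:, :K]


def _diff2(n: int) -> np.ndarray:
    D = np.zeros((max(n - 2, 0), n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _cyclic_diff2(n: int) -> np.ndarray:
    D = np.zeros((n, n))
    for i in range(n):
        D[i, i] = -2.0
        D[i, (i - 1) % n] = 1.0
        D[i, (i + 1) % n] = 1.0
    return D


def _check_loss(r: np.ndarray, tau: float = 0.5) -> float:
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


@dataclass
class BaselineFit:
    """Fitted median baseline: design description and coefficients."""

    t0: pd.Timestamp
    trend_interior: int
    trend_hi: float
    n_seasonal: int
    coef: np.ndarray
    lam: float
    quantile: float = 0.5

    def _design(self, dates: pd.DatetimeIndex) -> np.ndarray:
        t_years = (pd.to_datetime(dates) - self.t0).days.to_numpy() / 365.25
        phase = _year_phase(pd.to_datetime(dates))
        Bt, _ = _open_bspline_design(t_years, 0.0, self.trend_hi, self.trend_interior)
        Bs = _cyclic_bspline_design(phase, self.n_seasonal, 1.0)
        return np.hstack([Bt, Bs])

    def predict(self, dates: pd.DatetimeIndex) -> pd.Series:
        X = self._design(dates)
        return pd.Series(X @ self.coef, index=pd.to_datetime(dates), name="baseline")

    def to_json(self) -> str:
        return json.dumps(
            {
                "t0": str(self.t0.date()),
                "trend_interior": self.trend_interior,
                "trend_hi": self.trend_hi,
                "n_seasonal": self.n_seasonal,
                "coef": list(self.coef),
                "lam": self.lam,
                "quantile": self.quantile,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BaselineFit":
        d = json.loads(text)
        return cls(
            t0=pd.Timestamp(d["t0"]),
            trend_interior=int(d["trend_interior"]),
            trend_hi=float(d["trend_hi"]),
            n_seasonal=int(d["n_seasonal"]),
            coef=np.asarray(d["coef"], dtype=float),
            lam=float(d["lam"]),
            quantile=float(d["quantile"]),
        )


def _year_phase(dates: pd.DatetimeIndex) -> np.ndarray:
    return ((dates.dayofyear.to_numpy() - 1) % 365.25) / 365.25


def _fit_penalized_median(
    X: np.ndarray, y: np.ndarray, P: np.ndarray, lam: float, eps: float
) -> np.ndarray:
    """Minimize smoothed check loss + lam * coef' P coef by L-BFGS."""

    def objective(beta: np.ndarray):
        r = y - X @ beta
        s = np.sqrt(r * r + eps * eps)
        val = 0.5 * np.sum(s) + lam * beta @ P @ beta
        grad = -0.5 * X.T @ (r / s) + 2.0 * lam * P @ beta
        return val, grad

    beta0 = np.linalg.lstsq(X.T @ X + 1e-8 * np.eye(X.shape[1]) + lam * P, X.T @ y, rcond=None)[0]
    res = minimize(objective, beta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    return res.x


def fit_median_baseline(
    asmr: pd.Series,
    trend_knot_spacing_years: float = 2.0,
    n_seasonal: int = 10,
    lam_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[BaselineFit, pd.Series]:
    """Fit the median (quantile-0.5) baseline of a weekly ASMR series.

    The design is a cubic B-spline long-term trend (one interior knot per
    ``trend_knot_spacing_years``) plus a cyclic cubic B-spline seasonal
    basis of dimension ``n_seasonal`` with period one year.  Both blocks
    carry second-difference roughness penalties; a single penalty weight is
    chosen from ``lam_grid`` by K-fold cross-validated check loss.  Returns
    the fit and the in-sample baseline series ``B_t``.
    """
    asmr = asmr.dropna()
    dates = pd.to_datetime(asmr.index)
    if (dates[-1] - dates[0]).days < 3 * 365:
        raise ValueError("need at least 3 years of weekly ASMR")
    y = asmr.to_numpy(dtype=float)
    t0 = dates[0]
    t_years = (dates - t0).days.to_numpy() / 365.25
    hi = float(t_years.max())
    n_interior = max(1, int(np.floor(hi / trend_knot_spacing_years)) - 1)

    Bt, _ = _open_bspline_design(t_years, 0.0, hi, n_interior)
    Bs = _cyclic_bspline_design(_year_phase(dates), n_seasonal, 1.0)
    X = np.hstack([Bt, Bs])
    pt, ps = Bt.shape[1], Bs.shape[1]

    P = np.zeros((pt + ps, pt + ps))
    Dt = _diff2(pt)
    Ds = _cyclic_diff2(ps)
    P[:pt, :pt] = Dt.T @ Dt
    P[pt:, pt:] = Ds.T @ Ds
    # the cyclic block also needs a null-space tie to the trend intercept:
    # penalize the seasonal mean lightly so level lives in the trend block
    ones = np.ones((1, ps)) / ps
    P[pt:, pt:] += 1e-4 * (ones.T @ ones) * ps

    eps = max(1e-3 * np.median(np.abs(y - np.median(y))), 1e-9)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv_folds)
    best_lam, best_score = lam_grid[0], np.inf
    if len(lam_grid) > 1:
        for lam in lam_grid:
            score = 0.0
            for hold in folds:
                mask = np.ones(len(y), bool)
                mask[hold] = False
                beta = _fit_penalized_median(X[mask], y[mask], P, lam, eps)
                score += _check_loss(y[hold] - X[hold] @ beta)
            if score < best_score - 1e-12:
                best_score, best_lam = score, lam
    beta = _fit_penalized_median(X, y, P, best_lam, eps)

    fit = BaselineFit(
        t0=t0,
        trend_interior=n_interior,
        trend_hi=hi,
        n_seasonal=n_seasonal,
        coef=beta,
        lam=best_lam,
    )
    B = pd.Series(X @ beta, index=dates, name="baseline")
    return fit, B


def compute_pscores(asmr: pd.Series, baseline: pd.Series) -> pd.DataFrame:
    """p-scores ``Y_t = 100 * (ASMR_t - B_t) / B_t`` plus the one-week lag.

    The first week's lag is missing (NaN).  Raises on nonpositive baseline.
    """
    asmr, baseline = asmr.align(baseline, join="inner")
    if (baseline <= 0).any():
        raise ValueError("baseline must be strictly positive")
    y = 100.0 * (asmr - baseline) / baseline
    out = pd.DataFrame({"pscore": y, "pscore_lag1": y.shift(1)})
    return out
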