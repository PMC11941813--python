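"""Mortality attributable to environmental covariates.

For a covariate *j* with fitted location coefficient ``mu_j`` and weekly
two-week cumulative exposure ``X_{t,j}``, the attributable burden in year
*k* is

    deaths:  sum_{t in k} n_t  * mu_j * X_{t,j} / 100
    ASMR:    sum_{t in k} B_t  * mu_j * X_{t,j} / 100

where ``n_t`` are observed weekly deaths and ``B_t`` the baseline ASMR.
Negative weekly contributions are never clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distreg import LogisticDistFit

__all__ = [
    "attributable_deaths",
    "attributable_asmr",
    "yearly_attribution",
    "summarize_attribution",
]


def _weekly_terms(
    fit: LogisticDistFit, weekly: pd.DataFrame, covariate: str, weight_col: str
) -> pd.Series:
    if covariate not in fit.mu_terms:
        raise ValueError(f"covariate {covariate!r} is not in the fitted mu roster")
    mu_j = fit.mu_coeffs[covariate]
    x = weekly[covariate].astype(float)
    w = weekly[weight_col].astype(float)
    return w * mu_j * x / 100.0


def attributable_deaths(
    fit: LogisticDistFit,
    weekly: pd.DataFrame,
    covariate: str,
    year: int | None = None,
    deaths_col: str = "deaths",
    year_col: str = "year",
) -> float:
    """Deaths attributable to ``covariate`` (optionally within one year)."""
    terms = _weekly_terms(fit, weekly, covariate, deaths_col)
    if year is not None:
        terms = terms[weekly[year_col] == year]
    return float(terms.sum())


def attributable_asmr(
    fit: LogisticDistFit,
    weekly: pd.DataFrame,
    covariate: str,
    year: int | None = None,
    baseline_col: str = "baseline",
    year_col: str = "year",
) -> float:
    """ASMR (per 100,000) attributable to ``covariate``."""
    terms = _weekly_terms(fit, weekly, covariate, baseline_col)
    if year is not None:
        terms = terms[weekly[year_col] == year]
    return float(terms.sum())


def yearly_attribution(
    fit: LogisticDistFit,
    weekly: pd.DataFrame,
    covariates: list[str],
    deaths_col: str = "deaths",
    baseline_col: str = "baseline",
    year_col: str = "year",
) -> pd.DataFrame:
    """Yearly attributable deaths and ASMR for each covariate."""
    rows = []
    for year in sorted(weekly[year_col].unique()):
        for cov in covariates:
            rows.append(
                {
                    "year": int(year),
                    "covariate": cov,
                    "attributable_deaths": attributable_deaths(
                        fit, weekly, cov, year, deaths_col, year_col
                    ),
                    "attributable_asmr": attributable_asmr(
                        fit, weekly, cov, year, baseline_col, year_col
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_attribution(
    yearly: pd.DataFrame,
    period: tuple[int, int],
    episode_days: pd.Series | None = None,
) -> pd.DataFrame:
    """Period totals and yearly averages of attributable burden.

    ``period`` is an inclusive (first_year, last_year) pair.  If
    ``episode_days`` (yearly per-covariate day counts, MultiIndex
    (year, covariate)) is given, the mean annual episode frequency is added.
    """
    lo, hi = period
    sel = yearly[(yearly["year"] >= lo) & (yearly["year"] <= hi)]
    if len(sel) == 0:
        raise ValueError(f"no attribution results in period {period}")
    n_years = hi - lo + 1
    out = (
        sel.groupby("covariate")[["attributable_deaths", "attributable_asmr"]]
        .sum()
        .rename(
            columns={
                "attributable_deaths": "total_deaths",
                "attributable_asmr": "total_asmr",
            }
        )
    )
    out["yearly_avg_deaths"] = out["total_deaths"] / n_years
    out["yearly_avg_asmr"] = out["total_asmr"] / n_years
    out["period"] = f"{lo}-{hi}"
    if episode_days is not None:
        freq = (
            episode_days.loc[
                (episode_days.index.get_level_values(0) >= lo)
                & (episode_days.index.get_level_values(0) <= hi)
            ]
            .groupby(level=1)
            .sum()
            / n_years
        )
        out["episode_days_per_year"] = freq.reindex(out.index)
    return out.reset_index()
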