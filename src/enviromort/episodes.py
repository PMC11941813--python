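"""Episode-day classification and weekly cumulative exposure covariates.

A national daily exposure series is scanned for days exceeding absolute
health-risk thresholds (heat, cold, PM2.5, NO2, O3).  Episode days are then
aggregated to ISO weeks and turned into two-week cumulative covariates
``X_{t,j}`` = episode days in week *t* plus episode days in week *t-1*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "EpisodeThresholds",
    "RISKS",
    "detect_episode_days",
    "weekly_cumulative_counts",
    "iso_week_label",
]

#: Risk names, in the order used throughout the package.
RISKS = ("heat", "cold", "pm25", "no2", "o3")

#: Covariate column names used by the regression stage, keyed by risk.
COVARIATE_NAMES = {
    "heat": "HEAT",
    "cold": "COLD",
    "pm25": "PM25",
    "no2": "NO2",
    "o3": "O3",
}


@dataclass(frozen=True)
class EpisodeThresholds:
    """Absolute episode thresholds.

    Defaults are the national red-alert temperature criteria and the EU 2030
    air-quality standards (O3 expressed as a 1-h daily maximum equivalent).
    All comparisons are inclusive: heat requires ``tmax >= heat_tmax_min``
    and the previous day's ``tmean >= heat_prev_tmean_min``; cold requires
    ``tmin <= cold_tmin_max``; pollutants require concentration >= threshold.
    """

    heat_tmax_min: float = 35.0
    heat_prev_tmean_min: float = 23.0
    cold_tmin_max: float = -15.0
    pm25_min: float = 25.0
    no2_min: float = 50.0
    o3_1h_min: float = 160.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"threshold {f.name!r} must be finite, got {v!r}")


def _validate_daily(series: pd.DataFrame) -> pd.DataFrame:
    if "date" not in series.columns:
        raise ValueError("daily series must have a 'date' column")
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"])
    d = out["date"]
    if len(d) == 0:
        raise ValueError("daily series is empty")
    step = d.diff().dropna()
    if not (step == pd.Timedelta(days=1)).all():
        raise ValueError("dates must be strictly increasing with a daily step")
    present = out[["tmin", "tmean", "tmax"]].notna().all(axis=1) if set(
        ["tmin", "tmean", "tmax"]
    ) <= set(out.columns) else pd.Series(False, index=out.index)
    if present.any():
        sub = out.loc[present]
        if ((sub["tmin"] > sub["tmean"]) | (sub["tmean"] > sub["tmax"])).any():
            raise ValueError("tmin <= tmean <= tmax violated")
    return out


def detect_episode_days(
    series: pd.DataFrame, thresholds: EpisodeThresholds | None = None
) -> pd.DataFrame:
    """Flag episode days in a daily national exposure series.

    Parameters
    ----------
    series
        Columns ``date, tmax, tmin, tmean, pm25, no2, o3`` (temperatures in
        deg C, pollutants in ug/m3; ``pm25``/``no2`` are 24-h means, ``o3``
        the 1-h daily maximum).  Missing variables or missing values yield
        missing flags (``pd.NA``), never silent ``False``.
    thresholds
        Episode thresholds; defaults as documented on :class:`EpisodeThresholds`.

    Returns
    -------
    DataFrame with columns ``date`` plus nullable-boolean flags
    ``heat, cold, pm25, no2, o3`` (one row per input day).

    Notes
    -----
    A heat day requires both the day's ``tmax`` and the *previous* day's
    ``tmean`` to exceed their thresholds; the first day of the series has no
    predecessor and therefore cannot be a heat day.
    """
    thr = thresholds or EpisodeThresholds()
    df = _validate_daily(series)
    n = len(df)
    out = pd.DataFrame({"date": df["date"].to_numpy()})

    def _flag(col: str, fn) -> pd.Series:
        if col not in df.columns:
            return pd.Series(pd.NA, index=range(n), dtype="boolean")
        v = df[col].astype(float)
        res = pd.Series(fn(v), dtype="boolean")
        res[v.isna().to_numpy()] = pd.NA
        return res

    if "tmax" in df.columns and "tmean" in df.columns:
        tmax = df["tmax"].astype(float).to_numpy()
        prev_tmean = df["tmean"].astype(float).shift(1).to_numpy()
        heat = pd.array(
            (tmax >= thr.heat_tmax_min) & (prev_tmean >= thr.heat_prev_tmean_min),
            dtype="boolean",
        )
        heat[np.isnan(tmax) | np.isnan(prev_tmean)] = pd.NA
        heat[0] = False  # no predecessor: cannot satisfy the conjunctive rule
        out["heat"] = heat
    else:
        out["heat"] = pd.Series(pd.NA, index=range(n), dtype="boolean")

    out["cold"] = _flag("tmin", lambda v: v.to_numpy() <= thr.cold_tmin_max)
    out["pm25"] = _flag("pm25", lambda v: v.to_numpy() >= thr.pm25_min)
    out["no2"] = _flag("no2", lambda v: v.to_numpy() >= thr.no2_min)
    out["o3"] = _flag("o3", lambda v: v.to_numpy() >= thr.o3_1h_min)
    return out


def iso_week_label(dates: pd.Series) -> pd.Series:
    """ISO-8601 week labels like ``'2020-W50'`` for a datetime series."""
    iso = pd.to_datetime(dates).dt.isocalendar()
    return iso["year"].astype(str) + "-W" + iso["week"].astype(int).astype(str).str.zfill(2)


def weekly_cumulative_counts(calendar: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an episode calendar to whole ISO weeks and build covariates.

    Partial leading/trailing ISO weeks (fewer than 7 calendar days present)
    are dropped.  For each retained week *t* and risk *j* the covariate is

        ``X_{t,j} = days_j(week t) + days_j(week t-1)``

    the first retained week has no predecessor, uses 0 for the previous-week
    term and is flagged via ``first_week``.

    Missing daily flags are excluded from the counts; weeks containing any
    missing flag raise a completeness warning.

    Returns a DataFrame with ``iso_week``, per-risk within-week day counts
    (``heat_days`` ...), covariates (``HEAT`` ...) and ``first_week``.
    """
    if len(calendar) == 0:
        raise ValueError("empty episode calendar")
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    iso = cal["date"].dt.isocalendar()
    cal["_yr"], cal["_wk"] = iso["year"].to_numpy(), iso["week"].to_numpy()

    grouped = cal.groupby(["_yr", "_wk"], sort=False)
    sizes = grouped.size()
    keep = sizes[sizes == 7].index
    if len(keep) == 0:
        raise ValueError("no complete ISO weeks in calendar")

    rows = []
    incomplete = []
    for (yr, wk), g in grouped:
        if (yr, wk) not in set(keep):
            continue
        rec = {"iso_week": f"{yr}-W{int(wk):02d}", "iso_year": int(yr)}
        for risk in RISKS:
            flags = g[risk]
            if flags.isna().any():
                incomplete.append((rec["iso_week"], risk))
            rec[f"{risk}_days"] = int(flags.fillna(False).sum())
        rec["_start"] = g["date"].min()
        rows.append(rec)
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} week/risk cells have missing daily flags; "
            "missing days excluded from counts",
            stacklevel=2,
        )
    weekly = pd.DataFrame(rows).sort_values("_start").reset_index(drop=True)
    for risk in RISKS:
        cnt = weekly[f"{risk}_days"]
        weekly[COVARIATE_NAMES[risk]] = cnt + cnt.shift(1, fill_value=0)
    weekly["first_week"] = False
    weekly.loc[0, "first_week"] = True
    weekly["week_start"] = weekly.pop("_start")
    return weekly
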