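"""National exposure construction: IDW downscaling, monthly empirical
quantile mapping, and population-weighted aggregation.

Grids are regular, on projected planar coordinates in km.  The three
operations compose into the exposure-construction chain: station / coarse
model values are interpolated to a fine grid, the model grid is
bias-corrected against the observation grid per calendar month, and the
corrected fields are collapsed to a single national daily series using
gridded population weights (cell -> region -> national).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StationSet",
    "GridField",
    "PopulationGrid",
    "idw_interpolate",
    "eqm_correct",
    "population_weight_aggregate",
]


@dataclass
class StationSet:
    """Point observations: station ids, projected x/y (km) and a daily value
    table (rows = dates, columns = station ids)."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x, y must have equal length")
        coords = np.column_stack([self.x, self.y])
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("duplicate station coordinates")
        if list(self.values.columns) != list(self.ids):
            self.values = self.values[list(self.ids)]


@dataclass
class GridField:
    """Daily values on a regular grid.

    ``values`` has shape (n_days, ny, nx); node (i, j) sits at
    ``(x0 + j * cell_size, y0 + i * cell_size)``.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    dates: pd.DatetimeIndex

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_days, ny, nx)")
        if self.values.shape[0] != len(self.dates):
            raise ValueError("value array length does not match dates")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        xs = self.x0 + self.cell_size * np.arange(nx)
        ys = self.y0 + self.cell_size * np.arange(ny)
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()


@dataclass
class PopulationGrid:
    """Grid-aligned population counts with a region label per cell."""

    population: np.ndarray
    regions: np.ndarray

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.regions = np.asarray(self.regions)
        if self.population.shape != self.regions.shape:
            raise ValueError("population and region grids must share a shape")
        if (self.population < 0).any():
            raise ValueError("population must be >= 0")


def idw_interpolate(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    target_x: np.ndarray,
    target_y: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse distance-weighted interpolation.

    ``values`` is (n_points,) for a single day or (n_days, n_points); the
    result matches with targets along the last axis.  Weights are
    ``d^(-power)``; a target coinciding with a source point copies that
    point's value exactly.  NaN source values are excluded per day; days on
    which every source is NaN yield NaN at all targets.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v = np.atleast_2d(np.asarray(values, float))
    if x.size == 0:
        raise ValueError("empty source point set")
    tx = np.asarray(target_x, float).ravel()
    ty = np.asarray(target_y, float).ravel()

    d = np.hypot(tx[:, None] - x[None, :], ty[:, None] - y[None, :])
    exact = d <= 1e-12
    with np.errstate(divide="ignore", over="ignore"):
        w = d ** (-power)  # overflowed weights land in the exact-hit branch
    w[exact] = np.inf

    out = np.empty((v.shape[0], tx.size))
    finite = np.isfinite(v)
    for t in range(v.shape[0]):
        ok = finite[t]
        if not ok.any():
            out[t] = np.nan
            continue
        wt = w[:, ok]
        vt = v[t, ok]
        hit = np.isinf(wt)
        row_hit = hit.any(axis=1)
        wn = np.where(np.isinf(wt), 0.0, wt)
        denom = wn.sum(axis=1)
        with np.errstate(invalid="ignore"):
            res = wn @ vt / denom
        if row_hit.any():
            idx = hit.argmax(axis=1)
            res[row_hit] = vt[idx[row_hit]]
        out[t] = res
    return out[0] if np.asarray(values).ndim == 1 else out


def _monthly_knots(values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.quantile(values, probs, method="linear")


def eqm_correct(
    sim: pd.Series,
    obs: pd.Series,
    probs: np.ndarray | None = None,
    min_train: int = 30,
) -> pd.Series:
    """Monthly empirical quantile mapping of ``sim`` onto ``obs``.

    For each calendar month (pooled across years), quantile knots of sim and
    obs are computed on the overlapping training period: by default one knot
    per order statistic (the full empirical mapping, which reproduces the
    obs quantiles on training data exactly); pass ``probs`` (e.g. percentiles
    1..99) for a coarser knot grid.  Each sim value is mapped through linear
    interpolation between the (sim knot, obs knot) pairs; beyond the outer
    knots the edge difference ``obs_knot - sim_knot`` is added unchanged.
    The mapping is monotone within each month.

    Raises ``ValueError`` if any month has fewer than ``min_train``
    overlapping training values.
    """
    sim = sim.copy()
    sim.index = pd.to_datetime(sim.index)
    obs = obs.copy()
    obs.index = pd.to_datetime(obs.index)
    common = sim.index.intersection(obs.index)
    if len(common) == 0:
        raise ValueError("sim and obs do not overlap")

    corrected = pd.Series(np.nan, index=sim.index, dtype=float)
    for month in range(1, 13):
        apply_mask = sim.index.month == month
        if not apply_mask.any():
            continue
        train = common[common.month == month]
        pairs = pd.DataFrame({"sim": sim.loc[train], "obs": obs.loc[train]}).dropna()
        if len(pairs) < min_train:
            raise ValueError(
                f"month {month}: only {len(pairs)} training values "
                f"(minimum {min_train})"
            )
        if probs is None:
            sk = np.sort(pairs["sim"].to_numpy())
            ok = np.sort(pairs["obs"].to_numpy())
        else:
            sk = _monthly_knots(pairs["sim"].to_numpy(), probs)
            ok = _monthly_knots(pairs["obs"].to_numpy(), probs)
        # collapse duplicate sim knots (ties) to keep np.interp well defined
        sk_u, idx = np.unique(sk, return_index=True)
        ok_u = ok[idx]
        vals = sim.loc[apply_mask].to_numpy(dtype=float)
        if len(sk_u) == 1:
            res = vals + (ok_u[0] - sk_u[0])
        else:
            res = np.interp(vals, sk_u, ok_u)
            low = vals < sk_u[0]
            high = vals > sk_u[-1]
            res[low] = vals[low] + (ok_u[0] - sk_u[0])
            res[high] = vals[high] + (ok_u[-1] - sk_u[-1])
        corrected.loc[apply_mask] = res
    return corrected


def population_weight_aggregate(field: GridField, pop: PopulationGrid) -> pd.Series:
    """Two-stage population-weighted national mean of a gridded daily field.

    Stage 1 averages cells to regions using cell population; stage 2
    averages regions to a national value using region population.  The
    composition is algebraically identical to the single-stage
    population-weighted mean over all cells.
    """
    if pop.population.shape != field.shape:
        raise ValueError("population grid does not match field grid")
    total = pop.population.sum()
    if total <= 0:
        raise ValueError("total population is zero")
    p = pop.population.ravel()
    r = pop.regions.ravel()
    v = field.values.reshape(len(field.dates), -1)

    labels = np.unique(r)
    region_pop = np.array([p[r == lab].sum() for lab in labels])
    region_means = np.empty((v.shape[0], len(labels)))
    for k, lab in enumerate(labels):
        m = r == lab
        if region_pop[k] > 0:
            region_means[:, k] = v[:, m] @ p[m] / region_pop[k]
        else:
            region_means[:, k] = 0.0
    national = region_means @ region_pop / region_pop.sum()
    return pd.Series(national, index=field.dates, name="value")
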