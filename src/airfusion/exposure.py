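"""Population-weighted exposure and long-term trend utilities.

Census-tract populations are gridded by the centroid rule: a cell belongs to
the tract containing its centroid, and each tract's population is divided
equally among its cells.  Daily exposure is then the population-fraction
weighted sum of the fused concentration field, and trends are ordinary
least-squares slopes of the exposure series against day index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from scipy import stats

from .errors import InsufficientDataError
from .grid import GridDefinition, haversine_km

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TractRecord:
    """A census tract: id, total population, and polygon boundary."""

    tract_id: str
    population: float
    polygon: shapely.Geometry

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if not self.polygon.is_valid:
            raise ValueError(f"tract {self.tract_id}: invalid polygon")


@dataclass(frozen=True)
class PopulationGrid:
    """Fractional population per grid cell; fractions sum to 1."""

    fractions: np.ndarray
    total_population: float

    def __post_init__(self):
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        if np.any(self.fractions < 0):
            raise ValueError("population fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")


def normalize_decadal_field(fused: xr.DataArray) -> np.ndarray:
    """Per-cell time mean divided by the maximum per-cell mean.

    Output lies in (0, 1]; an all-zero input raises ValueError.
    """
    mean = np.asarray(fused.mean(dim="time").values, dtype=float)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero field")
    return mean / peak


def build_population_grid(tracts: list[TractRecord], grid: GridDefinition) -> PopulationGrid:
    """Grid tract populations by the centroid containment rule.

    Each cell is assigned to the first tract containing its centroid
    (overlaps warn); a populated tract containing no centroid sends its
    population to the cell nearest the tract centroid.
    """
    pop = np.zeros(grid.n_cells)
    assigned = np.zeros(grid.n_cells, dtype=bool)
    total = float(sum(t.population for t in tracts))
    if total <= 0:
        raise ValueError("total tract population must be positive")
    for tract in tracts:
        inside = shapely.contains_xy(tract.polygon, grid.lon, grid.lat)
        overlap = inside & assigned
        if overlap.any():
            warnings.warn(f"tract {tract.tract_id}: {int(overlap.sum())} cells already "
                          "assigned to an earlier tract; first match kept")
            inside = inside & ~assigned
        n_cells = int(inside.sum())
        if n_cells == 0:
            if tract.population > 0:
                centroid = tract.polygon.centroid
                nearest = int(np.argmin(haversine_km(centroid.y, centroid.x,
                                                     grid.lat, grid.lon)))
                warnings.warn(f"tract {tract.tract_id} contains no cell centroid; "
                              f"population assigned to nearest cell {nearest}")
                pop[nearest] += tract.population
            continue
        assigned |= inside
        pop[inside] += tract.population / n_cells
    return PopulationGrid(fractions=pop / total, total_population=total)


def population_weighted_exposure(field, pop: PopulationGrid):
    """Population-fraction weighted concentration.

    ``field`` may be a single raster (n_cells,) giving a scalar, or a daily
    DataArray (time, cell) giving a per-day series.
    """
    if isinstance(field, xr.DataArray):
        vals = field.values
        if vals.shape[-1] != pop.fractions.shape[0]:
            raise ValueError("field and population grids differ in size")
        return pd.Series(vals @ pop.fractions,
                         index=pd.DatetimeIndex(field.coords["time"].values),
                         name="exposure")
    vals = np.asarray(field, dtype=float)
    if vals.shape != pop.fractions.shape:
        raise ValueError("field and population grids differ in size")
    return float(vals @ pop.fractions)


def trend_slope(series: pd.Series) -> tuple[float, float]:
    """OLS slope and intercept of an exposure series against day index.

    The slope's units are concentration per day.  Requires at least two
    distinct dates.
    """
    if len(series) < 2:
        raise InsufficientDataError("trend requires at least 2 days")
    if isinstance(series.index, pd.DatetimeIndex):
        t = (series.index - series.index[0]).days.to_numpy(float)
    else:
        t = np.asarray(series.index, dtype=float)
    if np.ptp(t) == 0.0:
        raise ValueError("trend undefined for constant dates")
    fit = stats.linregress(t, series.to_numpy(float))
    return float(fit.slope), float(fit.intercept)
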