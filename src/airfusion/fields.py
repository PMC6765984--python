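"""Daily raster container helpers.

A sequence of daily fields is an :class:`xarray.DataArray` with dims
``("time", "cell")`` — ``time`` holds calendar days, ``cell`` the row-major
cell ids of a :class:`~airfusion.grid.GridDefinition`.  These helpers build
and validate that container and reshape it to/from (time, row, col).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridDefinition


def daily_field(values: np.ndarray, dates, grid: GridDefinition,
                name: str = "conc", attrs: dict | None = None) -> xr.DataArray:
    """Wrap (n_days, n_cells) values as a daily-field DataArray."""
    values = np.asarray(values, dtype=float)
    dates = pd.DatetimeIndex(pd.to_datetime(dates)).rename("time")
    if values.shape != (len(dates), grid.n_cells):
        raise ValueError(f"values shape {values.shape} != ({len(dates)}, {grid.n_cells})")
    return xr.DataArray(
        values,
        dims=("time", "cell"),
        coords={"time": dates, "cell": grid.cell_ids},
        name=name,
        attrs=attrs or {},
    )


def to_rowcol(field: xr.DataArray, grid: GridDefinition) -> xr.DataArray:
    """Reshape a (time, cell) field to (time, row, col)."""
    data = field.values.reshape(field.sizes["time"], grid.n_rows, grid.n_cols)
    return xr.DataArray(
        data,
        dims=("time", "row", "col"),
        coords={"time": field.coords["time"].values,
                "row": np.arange(grid.n_rows), "col": np.arange(grid.n_cols)},
        name=field.name,
        attrs=dict(field.attrs),
    )


def from_rowcol(field: xr.DataArray, grid: GridDefinition) -> xr.DataArray:
    """Reshape a (time, row, col) field back to (time, cell)."""
    data = field.values.reshape(field.sizes["time"], grid.n_cells)
    return daily_field(data, field.coords["time"].values, grid,
                       name=field.name or "conc", attrs=dict(field.attrs))
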