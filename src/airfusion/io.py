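"""Readers and writers for the package's on-disk formats.

Monitors travel as tidy CSV (``site_id, lat, lon, pollutant, date, value``),
grid geometry as CSV (``cell_id, row, col, lat, lon``), gridded daily fields
as NetCDF (``time x row x col``, via the SciPy NetCDF backend) or long CSV
(``cell_id, date, value``), tracts as GeoJSON FeatureCollections with a
``population`` property, and regression parameters / provenance as JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .errors import GriddedDataError
from .exposure import TractRecord
from .fields import daily_field, to_rowcol
from .grid import GridDefinition, clamp_nonnegative
from .regression import RegressionParams

logger = logging.getLogger(__name__)

MONITOR_COLUMNS = ["site_id", "lat", "lon", "pollutant", "date", "value"]


def infer_sampling_frequency(dates: pd.Series) -> str:
    """Classify a site's schedule from the mode of its day gaps.

    Gap mode 1 -> ``daily``, 3 -> ``1-in-3``, 6 -> ``1-in-6``, anything
    else (or a single observation) -> ``irregular``.
    """
    dates = pd.to_datetime(pd.Series(dates)).sort_values().drop_duplicates()
    if len(dates) < 2:
        return "irregular"
    gaps = dates.diff().dropna().dt.days
    mode = int(gaps.mode().iloc[0])
    return {1: "daily", 3: "1-in-3", 6: "1-in-6"}.get(mode, "irregular")


def read_monitor_csv(path) -> pd.DataFrame:
    """Read and validate a monitor observation table.

    Duplicate (site, date) rows are averaged with a warning; negative values
    are dropped with a warning; the per-site sampling frequency is inferred
    from observed day spacing and attached as ``sampling_freq``.
    """
    df = pd.read_csv(path)
    missing = [c for c in MONITOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable dates ({exc})") from exc
    bad = ~np.isfinite(df["value"].astype(float))
    if bad.any():
        raise ValueError(f"{path}: non-finite values at rows {list(df.index[bad])}")
    neg = df["value"] < 0
    if neg.any():
        warnings.warn(f"{path}: dropped {int(neg.sum())} negative observations")
        df = df[~neg]
    dup_keys = df.duplicated(["site_id", "pollutant", "date"], keep=False)
    if dup_keys.any():
        warnings.warn(f"{path}: averaged duplicate (site, date) rows")
        group_cols = ["site_id", "lat", "lon", "pollutant", "date"]
        df = df.groupby(group_cols, as_index=False)["value"].mean()
    freq = (df.groupby("site_id")["date"].apply(infer_sampling_frequency)
            .rename("sampling_freq"))
    return df.merge(freq, on="site_id").sort_values(["site_id", "date"]).reset_index(drop=True)


def write_monitor_csv(monitors: pd.DataFrame, path) -> None:
    cols = [c for c in MONITOR_COLUMNS if c in monitors.columns]
    out = monitors[cols].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_grid_csv(grid: GridDefinition, path) -> None:
    rows, cols = np.divmod(grid.cell_ids, grid.n_cols)
    pd.DataFrame({"cell_id": grid.cell_ids, "row": rows, "col": cols,
                  "lat": grid.lat, "lon": grid.lon}).to_csv(path, index=False)


def read_grid_csv(path) -> GridDefinition:
    df = pd.read_csv(path).sort_values("cell_id")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    if len(df) != n_rows * n_cols:
        raise GriddedDataError(f"{path}: expected {n_rows * n_cols} cells, got {len(df)}")
    return GridDefinition(n_rows, n_cols, df["lat"].to_numpy(), df["lon"].to_numpy())


def write_gridded_netcdf(field: xr.DataArray, grid: GridDefinition, path,
                         attrs: dict | None = None) -> None:
    """Write a (time, cell) daily field as time x row x col NetCDF."""
    cube = to_rowcol(field, grid)
    ds = xr.Dataset(
        {"conc": cube,
         "lat": (("row", "col"), grid.lat.reshape(grid.n_rows, grid.n_cols)),
         "lon": (("row", "col"), grid.lon.reshape(grid.n_rows, grid.n_cols))},
        attrs={**dict(field.attrs), **(attrs or {})})
    ds.to_netcdf(path, engine="scipy")


def write_gridded_csv(field: xr.DataArray, path) -> None:
    """Write a (time, cell) daily field as long CSV (cell_id, date, value)."""
    df = field.to_pandas().stack().rename("value").reset_index()
    df.columns = ["date", "cell_id", "value"]
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df[["cell_id", "date", "value"]].to_csv(path, index=False)


def _validate_complete(df: pd.DataFrame, n_cells: int) -> None:
    dates = df["date"].unique()
    counts = df.groupby("date")["cell_id"].nunique()
    short = counts[counts != n_cells]
    if not short.empty:
        day = short.index[0]
        have = set(df.loc[df["date"] == day, "cell_id"])
        gaps = sorted(set(range(n_cells)) - have)[:10]
        raise GriddedDataError(
            f"day {pd.Timestamp(day).date()} missing cells {gaps} "
            f"({n_cells - int(short.iloc[0])} absent)")
    if len(df) != len(dates) * n_cells:
        raise GriddedDataError("duplicate (cell, date) rows in gridded input")


def read_gridded(path, grid: GridDefinition | None = None):
    """Read a gridded daily field; returns ``(field, grid)``.

    NetCDF inputs carry their own geometry; long-CSV inputs need ``grid``.
    Negative values are clamped to zero (counted in the log); incomplete
    rasters raise :class:`GriddedDataError` naming the gaps.
    """
    path = Path(path)
    if path.suffix in (".nc", ".nc4", ".cdf"):
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        n_rows, n_cols = ds.sizes["row"], ds.sizes["col"]
        grid = GridDefinition(n_rows, n_cols, ds["lat"].values.ravel(),
                              ds["lon"].values.ravel())
        vals = clamp_nonnegative(
            ds["conc"].values.reshape(ds.sizes["time"], grid.n_cells), str(path))
        if np.any(~np.isfinite(vals)):
            raise GriddedDataError(f"{path}: non-finite values in raster")
        field = daily_field(vals, ds["time"].values, grid,
                            attrs=dict(ds.attrs))
        return field, grid
    if grid is None:
        raise ValueError("long-CSV gridded input requires a GridDefinition")
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    _validate_complete(df, grid.n_cells)
    wide = df.pivot(index="date", columns="cell_id", values="value").sort_index()
    wide = wide.reindex(columns=grid.cell_ids)
    vals = clamp_nonnegative(wide.to_numpy(float), str(path))
    return daily_field(vals, wide.index, grid), grid


def write_tracts_geojson(tracts, path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"tract_id": t.tract_id, "population": t.population},
        "geometry": json.loads(shapely.to_geojson(t.polygon)),
    } for t in tracts]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_tracts_geojson(path) -> list:
    data = json.loads(Path(path).read_text())
    tracts = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        tracts.append(TractRecord(
            tract_id=str(props.get("tract_id", len(tracts))),
            population=float(props.get("population", 0.0)),
            polygon=shapely.geometry.shape(feat["geometry"])))
    return tracts


def write_params_json(params: RegressionParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def read_params_json(path) -> RegressionParams:
    return RegressionParams(**json.loads(Path(path).read_text()))


def write_provenance(path, **entries) -> None:
    """Record run inputs, seeds and parameters as JSON for audit."""
    import airfusion
    entries.setdefault("airfusion_version", airfusion.__version__)
    Path(path).write_text(json.dumps(entries, indent=1, default=str))
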