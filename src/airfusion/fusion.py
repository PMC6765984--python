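"""Daily fusion of calibrated model fields with monitor ratios.

Each monitor cell yields a dimensionless daily ratio

    r = (OBS / OBS_mean) * (alpha * MODEL_mean**beta) / (alpha * MODEL**beta)

where the means run over the monitor's observation days.  Ratios on
non-sampling days are filled by linear interpolation in time, clipped to
[0.1, 10] to stop outliers propagating, and spread across the raster with
inverse-distance weighting (exact at monitor cells).  The fused field is the
elementwise product of the interpolated ratio raster and the power-law
corrected model field, so it reproduces the observations at monitor cells
while inheriting the model's spatial texture everywhere else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InsufficientDataError, UndefinedRatioError
from .grid import GridDefinition, haversine_km
from .regression import (RegressionParams, apply_correction,
                         build_annual_pairs, fit_power_regression,
                         merge_monitors_to_cells)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdwSettings:
    """Inverse-distance-weighting configuration.

    ``power`` is the distance-decay exponent (weights ``d**-power``);
    ``neighbor_count=None`` uses every point.  ``ratio_bounds`` clip the
    dimensionless ratios; with ``clip_stage="points"`` the clip is applied to
    the point ratios before interpolation (which also bounds the interpolated
    field, a convex combination), ``"field"`` clips the raster afterwards.
    ``node_epsilon_km`` is the distance below which a cell is treated as
    coincident with a point and takes its ratio exactly.
    """

    power: float = 2.0
    neighbor_count: int | None = None
    ratio_bounds: tuple[float, float] = (0.1, 10.0)
    clip_stage: str = "points"
    node_epsilon_km: float = 0.001

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        lo, hi = self.ratio_bounds
        if not lo < hi:
            raise ValueError("ratio bounds must satisfy lo < hi")
        if self.clip_stage not in ("points", "field"):
            raise ValueError("clip_stage must be 'points' or 'field'")


@dataclass
class RatioPointSet:
    """Dimensionless monitor ratios for one day, at most one per cell."""

    date: object
    cell_ids: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    ratios: np.ndarray
    clipped: bool = False


@dataclass
class FusionResult:
    """Output of a fusion run: fused and corrected daily fields plus provenance."""

    fused: xr.DataArray
    corrected: xr.DataArray
    params: RegressionParams
    settings: IdwSettings
    n_monitor_cells: int
    provenance: dict = dc_field(default_factory=dict)


def compute_point_ratio(obs: float, obs_mean: float, model: float,
                        model_mean: float, params: RegressionParams) -> float:
    """Normalized dimensionless ratio at a monitor for one day.

    The scale ``alpha`` cancels algebraically; it is carried through anyway
    so the expression mirrors the calibration it normalizes against.
    """
    if obs_mean <= 0 or model <= 0 or model_mean <= 0:
        raise UndefinedRatioError(
            f"ratio undefined: obs_mean={obs_mean}, model={model}, model_mean={model_mean}")
    corrected_mean = params.alpha * model_mean ** params.beta
    corrected = params.alpha * model ** params.beta
    return (obs / obs_mean) * corrected_mean / corrected


def interpolate_ratio_series(sample_days: np.ndarray, sample_ratios: np.ndarray,
                             calendar_days: np.ndarray) -> np.ndarray:
    """Fill a sparse daily ratio series onto the full calendar.

    Linear interpolation in day number between consecutive samples; before
    the first and after the last sample the nearest sampled ratio is held
    constant.
    """
    sample_days = np.asarray(sample_days, dtype=float)
    sample_ratios = np.asarray(sample_ratios, dtype=float)
    if sample_days.size == 0:
        raise InsufficientDataError("cannot interpolate an empty ratio series")
    order = np.argsort(sample_days)
    return np.interp(np.asarray(calendar_days, dtype=float),
                     sample_days[order], sample_ratios[order])


def clip_ratios(ratios: np.ndarray, bounds: tuple[float, float] = (0.1, 10.0)) -> np.ndarray:
    """Clip ratios into ``bounds``; the number of clipped values is logged."""
    ratios = np.asarray(ratios, dtype=float)
    lo, hi = bounds
    n_clipped = int(np.sum((ratios < lo) | (ratios > hi)))
    if n_clipped:
        logger.info("clipped %d ratio values into [%g, %g]", n_clipped, lo, hi)
    return np.clip(ratios, lo, hi)


def _merge_duplicate_points(lat, lon, values):
    coords = np.stack([np.asarray(lat, float), np.asarray(lon, float)], axis=1)
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return np.asarray(lat, float), np.asarray(lon, float), np.asarray(values, float)
    values = np.asarray(values, float)
    merged = np.zeros((len(uniq),) + values.shape[1:])
    counts = np.bincount(inverse, minlength=len(uniq))
    np.add.at(merged, inverse, values)
    merged /= counts.reshape(-1, *([1] * (values.ndim - 1)))
    return uniq[:, 0], uniq[:, 1], merged


def idw_weights(point_lat, point_lon, grid: GridDefinition,
                settings: IdwSettings) -> tuple[np.ndarray, np.ndarray]:
    """Weight matrix (n_cells, n_points) and node-coincidence mask.

    Cells closer than ``node_epsilon_km`` to a point get a one-hot row so the
    interpolator is exact there.  With ``neighbor_count=k``, only each cell's
    k nearest points keep nonzero weight.
    """
    d = haversine_km(grid.lat[:, None], grid.lon[:, None],
                     np.asarray(point_lat)[None, :], np.asarray(point_lon)[None, :])
    node = d < settings.node_epsilon_km
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d, np.inf) ** (-settings.power)
    if settings.neighbor_count is not None and settings.neighbor_count < d.shape[1]:
        k = settings.neighbor_count
        cutoff = np.partition(d, k - 1, axis=1)[:, k - 1:k]
        w = np.where(d <= cutoff, w, 0.0)
    node_rows = node.any(axis=1)
    w[node_rows] = 0.0
    w[node] = 1.0
    return w, node_rows


def idw_interpolate(points: RatioPointSet, grid: GridDefinition,
                    settings: IdwSettings) -> np.ndarray:
    """IDW-interpolate one day's ratio points onto the whole raster."""
    if len(points.ratios) == 0:
        raise InsufficientDataError("IDW requires at least one point")
    lat, lon, vals = _merge_duplicate_points(points.lat, points.lon, points.ratios)
    w, _ = idw_weights(lat, lon, grid, settings)
    return (w @ vals) / w.sum(axis=1)


def fuse_day(ratio_raster: np.ndarray, corrected: np.ndarray) -> np.ndarray:
    """Elementwise product of the ratio raster and the corrected model field."""
    ratio_raster = np.asarray(ratio_raster, float)
    corrected = np.asarray(corrected, float)
    if ratio_raster.shape != corrected.shape:
        raise ValueError(f"shape mismatch {ratio_raster.shape} vs {corrected.shape}")
    return ratio_raster * corrected


def build_cell_ratio_matrix(monitors: pd.DataFrame, model_daily: xr.DataArray,
                            grid: GridDefinition, params: RegressionParams,
                            pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Dense daily ratio series for every usable monitor cell.

    Returns ``(cell_ids, R)`` with ``R`` of shape (n_cells_used, n_days):
    per cell, ratios on observed days (undefined points dropped and logged)
    linearly interpolated onto the full model calendar.
    """
    cell_obs = merge_monitors_to_cells(monitors, grid)
    model_df = model_daily.to_pandas()
    calendar = model_df.index
    day_index = pd.Series(np.arange(len(calendar)), index=calendar)
    stats = pairs.set_index("cell_id")

    kept_cells, rows = [], []
    for cell_id, g in cell_obs.groupby("cell_id"):
        if cell_id not in stats.index:
            continue
        obs_mean = stats.at[cell_id, "obs_mean"]
        model_mean = stats.at[cell_id, "model_mean"]
        if obs_mean <= 0 or model_mean <= 0:
            logger.info("cell %d: non-positive annual mean; ratios skipped", cell_id)
            continue
        g = g[g["date"].isin(calendar)]
        days, ratios = [], []
        for _, row in g.iterrows():
            model_val = model_df.at[row["date"], cell_id]
            try:
                r = compute_point_ratio(row["obs"], obs_mean, model_val, model_mean, params)
            except UndefinedRatioError:
                logger.info("cell %d %s: undefined ratio dropped", cell_id, row["date"].date())
                continue
            days.append(day_index[row["date"]])
            ratios.append(r)
        if not days:
            continue
        kept_cells.append(int(cell_id))
        rows.append(interpolate_ratio_series(np.array(days), np.array(ratios),
                                             np.arange(len(calendar))))
    if not kept_cells:
        return np.array([], dtype=int), np.empty((0, len(calendar)))
    return np.array(kept_cells), np.vstack(rows)


def run_fusion_year(monitors: pd.DataFrame, model_daily: xr.DataArray,
                    grid: GridDefinition, pollutant: str = "",
                    settings: IdwSettings = IdwSettings(),
                    params: RegressionParams | None = None) -> FusionResult:
    """Run the full fusion pipeline for one calendar year of daily fields.

    Orchestrates: annual pairs -> power regression (unless ``params`` is
    supplied) -> per-cell daily ratios with temporal fill -> clip -> IDW ->
    elementwise fusion.  With no usable monitors the ratio raster is 1
    everywhere (fused = corrected model) and a warning is emitted.
    """
    dates = pd.to_datetime(model_daily.coords["time"].values)
    year = int(dates[0].year)
    pairs = build_annual_pairs(monitors, model_daily, grid)
    if params is None:
        params = fit_power_regression(pairs, pollutant=pollutant, year=year)
    corrected = apply_correction(model_daily, params)

    cells, R = build_cell_ratio_matrix(monitors, model_daily, grid, params, pairs)
    n_days = len(dates)
    if len(cells) == 0:
        warnings.warn("no usable monitor ratios; fused field equals corrected model")
        ratio_raster = np.ones((n_days, grid.n_cells))
    else:
        if settings.clip_stage == "points":
            R = clip_ratios(R, settings.ratio_bounds)
        w, _ = idw_weights(grid.lat[cells], grid.lon[cells], grid, settings)
        # (n_cells, n_pts) @ (n_pts, n_days) -> every day in one product
        ratio_raster = ((w @ R) / w.sum(axis=1, keepdims=True)).T
        if settings.clip_stage == "field":
            ratio_raster = clip_ratios(ratio_raster, settings.ratio_bounds)

    fused = corrected.copy(data=fuse_day(ratio_raster, corrected.values))
    fused.attrs.update(alpha=params.alpha, beta=params.beta,
                       idw_power=settings.power,
                       ratio_lo=settings.ratio_bounds[0],
                       ratio_hi=settings.ratio_bounds[1],
                       n_monitors=int(len(cells)))
    provenance = {
        "pollutant": pollutant, "year": year,
        "regression": params.to_dict(),
        "idw": {"power": settings.power, "neighbor_count": settings.neighbor_count,
                "ratio_bounds": list(settings.ratio_bounds),
                "clip_stage": settings.clip_stage},
        "n_monitor_cells": int(len(cells)),
        "n_days": n_days,
    }
    return FusionResult(fused=fused, corrected=corrected, params=params,
                        settings=settings, n_monitor_cells=int(len(cells)),
                        provenance=provenance)
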