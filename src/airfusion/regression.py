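"""Annual power-law calibration of the model field against monitors.

The calibration model is ``OBS ≈ alpha * MODEL**beta``, fitted per pollutant
and per year between annual-mean observations and annual-mean model values
taken at monitor cells *restricted to each monitor's observation days* — the
day-set restriction is what makes partial-year monitors comparable.  The
exponent ``beta`` is constrained to [0, 1] so the correction can never become
an amplifying (super-linear) function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize, stats

from .errors import DegenerateFitError, InsufficientDataError
from .grid import GridDefinition, assign_monitors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionParams:
    """Per-pollutant, per-year calibration parameters.

    ``alpha`` is the positive scale, ``beta`` the exponent in [0, 1], and
    ``r2`` the squared Pearson correlation between the observed annual means
    and the calibrated model annual means.
    """

    pollutant: str
    year: int
    alpha: float
    beta: float
    r2: float
    n_pairs: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def merge_monitors_to_cells(monitors: pd.DataFrame, grid: GridDefinition) -> pd.DataFrame:
    """Collapse monitor observations to one value per (cell, day).

    Each site is assigned to its nearest-centroid cell; when several sites
    share a cell, their same-day observations are averaged so the cell
    behaves as a single composite monitor.

    Returns a frame with columns ``cell_id, date, obs`` (one row per
    cell-day with data).
    """
    monitors = monitors.copy()
    sites = monitors.drop_duplicates("site_id")[["site_id", "lat", "lon"]]
    sites = sites.assign(cell_id=assign_monitors(sites["lat"], sites["lon"], grid))
    monitors = monitors.merge(sites[["site_id", "cell_id"]], on="site_id")
    out = (monitors.groupby(["cell_id", "date"], as_index=False)["value"]
           .mean().rename(columns={"value": "obs"}))
    out["date"] = pd.to_datetime(out["date"])
    return out


def build_annual_pairs(monitors: pd.DataFrame, model: xr.DataArray,
                       grid: GridDefinition) -> pd.DataFrame:
    """Annual (observation mean, model mean) pairs per occupied cell.

    For each cell holding at least one monitor, the observation mean runs
    over the cell's observed days and the model mean over *the same days* at
    that cell.  Cells whose monitors report nothing are simply absent.

    Returns a frame with columns ``cell_id, obs_mean, model_mean, n_obs``.
    """
    cell_obs = merge_monitors_to_cells(monitors, grid)
    if cell_obs.empty:
        return pd.DataFrame(columns=["cell_id", "obs_mean", "model_mean", "n_obs"])
    model_df = model.to_pandas()  # index: time, columns: cell
    rows = []
    for cell_id, g in cell_obs.groupby("cell_id"):
        dates = g["date"]
        available = dates[dates.isin(model_df.index)]
        if available.empty:
            logger.info("cell %d: no observation days overlap the model period; excluded", cell_id)
            continue
        if len(available) < len(dates):
            g = g[g["date"].isin(model_df.index)]
        rows.append({
            "cell_id": int(cell_id),
            "obs_mean": float(g["obs"].mean()),
            "model_mean": float(model_df.loc[g["date"], cell_id].mean()),
            "n_obs": int(len(g)),
        })
    return pd.DataFrame(rows)


def _clamped_refit(logx: np.ndarray, logy: np.ndarray, beta: float) -> float:
    # with beta pinned at a bound, log(alpha) is the mean log residual
    return float(np.mean(logy - beta * logx))


def fit_power_regression(pairs: pd.DataFrame, pollutant: str = "", year: int = 0,
                         method: str = "loglog") -> RegressionParams:
    """Fit ``obs_mean = alpha * model_mean**beta`` over annual pairs.

    The default fit is ordinary least squares of ``log(obs_mean)`` on
    ``log(model_mean)``; if the unconstrained slope falls outside [0, 1] it
    is clamped to the nearest bound and ``log(alpha)`` re-estimated as the
    mean log-ratio at that fixed exponent.  ``method="nls"`` instead solves
    the bounded nonlinear least-squares problem in the original scale.

    Pairs with a non-positive mean are dropped (counted in the log); fewer
    than 3 usable pairs raises :class:`InsufficientDataError`, and zero
    variance in the model means raises :class:`DegenerateFitError`.
    """
    usable = pairs[(pairs["obs_mean"] > 0) & (pairs["model_mean"] > 0)]
    n_dropped = len(pairs) - len(usable)
    if n_dropped:
        logger.info("%s %s: dropped %d pairs with non-positive annual means",
                    pollutant, year, n_dropped)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 pairs with positive means, got {len(usable)}")
    x = usable["model_mean"].to_numpy(float)
    y = usable["obs_mean"].to_numpy(float)
    logx, logy = np.log(x), np.log(y)
    if np.ptp(logx) == 0.0:
        raise DegenerateFitError("model annual means have zero variance")

    beta = float(np.polyfit(logx, logy, 1)[0])
    if beta < 0.0 or beta > 1.0:
        beta = min(max(beta, 0.0), 1.0)
        log_alpha = _clamped_refit(logx, logy, beta)
    else:
        log_alpha = float(np.mean(logy) - beta * np.mean(logx))
    alpha = float(np.exp(log_alpha))

    if method == "nls":
        p0 = [alpha, min(max(beta, 1e-6), 1.0 - 1e-6)]
        (alpha, beta), _ = optimize.curve_fit(
            lambda m, a, b: a * m ** b, x, y, p0=p0,
            bounds=([1e-12, 0.0], [np.inf, 1.0]), maxfev=10000)
        alpha, beta = float(alpha), float(min(max(beta, 0.0), 1.0))

    pred = alpha * x ** beta
    if np.ptp(pred) == 0.0 or np.ptp(y) == 0.0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(y, pred).statistic ** 2)
    return RegressionParams(pollutant=pollutant, year=int(year), alpha=alpha,
                            beta=beta, r2=r2, n_pairs=int(len(usable)))


def apply_correction(field, params: RegressionParams):
    """Apply ``x -> alpha * x**beta`` elementwise, with ``0**beta`` taken as 0.

    Accepts an ndarray or a DataArray and returns the same kind.
    """
    is_xr = isinstance(field, xr.DataArray)
    vals = np.asarray(field.values if is_xr else field, dtype=float)
    if np.any(vals < 0):
        raise ValueError("corrected field requires non-negative input")
    with np.errstate(divide="ignore"):
        out = params.alpha * np.power(vals, params.beta)
    out = np.where(vals == 0.0, 0.0, out)
    if is_xr:
        return field.copy(data=out)
    return out
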