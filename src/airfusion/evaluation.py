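"""Performance metrics and monitor-withholding cross-validation.

Temporal R² is the squared Pearson correlation between a monitor's daily
series and the matched prediction, averaged over monitors; spatial R² is the
cross-site correlation per day, averaged over days.  Withholding evaluation
removes a random 10% of monitor sites, refits and re-fuses with the rest,
and scores the fused field at the withheld site-days with pooled R² and
NRMSE (RMSE divided by the mean observation), alongside the raw model
baseline at the same site-days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import InsufficientDataError, UndefinedMetricError
from .fusion import IdwSettings, run_fusion_year
from .grid import GridDefinition
from .regression import merge_monitors_to_cells

logger = logging.getLogger(__name__)

#: Longitude separating the western from the eastern monitoring domain.
EAST_WEST_LON = -94.6046


def _r2(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) < 3 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return None
    return float(stats.pearsonr(a, b).statistic ** 2)


def temporal_r2(paired: pd.DataFrame, min_pairs: int = 3, agg: str = "mean") -> float:
    """Mean over monitors of the squared daily-series correlation.

    ``paired`` needs columns ``site_id, obs, pred``.  Sites with fewer than
    ``min_pairs`` paired days or zero variance in either series are excluded
    (and counted in the log); if none qualify an
    :class:`UndefinedMetricError` is raised.
    """
    vals, n_excluded = [], 0
    for _, g in paired.groupby("site_id"):
        r2 = _r2(g["obs"].to_numpy(float), g["pred"].to_numpy(float))
        if len(g) < min_pairs or r2 is None:
            n_excluded += 1
            continue
        vals.append(r2)
    if n_excluded:
        logger.info("temporal_r2: excluded %d degenerate sites", n_excluded)
    if not vals:
        raise UndefinedMetricError("no site qualifies for temporal R2")
    return float(np.median(vals) if agg == "median" else np.mean(vals))


def spatial_r2(paired: pd.DataFrame, min_sites: int = 3, agg: str = "mean") -> float:
    """Mean over days of the squared cross-site correlation.

    ``paired`` needs columns ``date, obs, pred``; degenerate days (fewer
    than ``min_sites`` sites or zero variance) are excluded.
    """
    vals, n_excluded = [], 0
    for _, g in paired.groupby("date"):
        r2 = _r2(g["obs"].to_numpy(float), g["pred"].to_numpy(float))
        if len(g) < min_sites or r2 is None:
            n_excluded += 1
            continue
        vals.append(r2)
    if n_excluded:
        logger.info("spatial_r2: excluded %d degenerate days", n_excluded)
    if not vals:
        raise UndefinedMetricError("no day qualifies for spatial R2")
    return float(np.median(vals) if agg == "median" else np.mean(vals))


def pooled_r2(obs, pred) -> float:
    """Squared Pearson correlation over all pooled site-days."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    r2 = _r2(obs, pred)
    if r2 is None:
        raise UndefinedMetricError("pooled R2 undefined (degenerate input)")
    return r2


def nrmse(obs, pred) -> float:
    """Root-mean-square error normalized by the mean observation."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size == 0:
        raise InsufficientDataError("nrmse requires at least one pair")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("nrmse undefined for non-positive mean observation")
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / mean_obs)


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded random partition of sites into k near-equal folds."""

    folds: tuple
    seed: int
    k: int

    def sites_in(self, fold_id: int) -> list:
        return list(self.folds[fold_id])

    def all_sites(self) -> set:
        return set().union(*map(set, self.folds))


def make_folds(sites, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly partition sites into k folds whose sizes differ by at most 1."""
    sites = sorted(set(sites))
    if len(sites) < k:
        raise InsufficientDataError(f"{len(sites)} sites cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    shuffled = [sites[i] for i in order]
    folds = tuple(tuple(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), k))
    return FoldAssignment(folds=folds, seed=seed, k=k)


def _withheld_pairs(withheld: pd.DataFrame, field: xr.DataArray,
                    grid: GridDefinition) -> pd.DataFrame:
    """Pair withheld observations with field values at their cell-days."""
    cell_obs = merge_monitors_to_cells(withheld, grid)
    time_index = pd.DatetimeIndex(field.coords["time"].values)
    t_pos = time_index.get_indexer(cell_obs["date"])
    cell_obs = cell_obs[t_pos >= 0]
    t_pos = t_pos[t_pos >= 0]
    pred = field.values[t_pos, cell_obs["cell_id"].to_numpy()]
    return cell_obs.assign(pred=pred)


@dataclass
class CrossValResult:
    """Per-fold and averaged withheld metrics for fused and raw-model fields."""

    per_fold: list
    summary: dict
    folds: FoldAssignment
    extras: dict = dc_field(default_factory=dict)


def cross_validate(monitors: pd.DataFrame, model_daily: xr.DataArray,
                   grid: GridDefinition, pollutant: str = "",
                   settings: IdwSettings = IdwSettings(),
                   k: int = 10, seed: int = 0,
                   folds: FoldAssignment | None = None) -> CrossValResult:
    """k-fold monitor-site withholding evaluation.

    For each fold the regression is refit and the fusion rerun using only
    the retained sites; pooled R² and NRMSE are computed at the withheld
    site-days for the fused field and, as a baseline, for the raw
    (uncorrected) model.  The summary is the unweighted mean over folds.
    """
    sites = monitors["site_id"].unique()
    if folds is None:
        folds = make_folds(sites, k=k, seed=seed)
    per_fold = []
    for fold_id in range(folds.k):
        withheld_sites = set(folds.sites_in(fold_id))
        train = monitors[~monitors["site_id"].isin(withheld_sites)]
        test = monitors[monitors["site_id"].isin(withheld_sites)]
        if train["site_id"].nunique() < 3:
            raise InsufficientDataError(
                f"fold {fold_id} leaves only {train['site_id'].nunique()} training sites")
        result = run_fusion_year(train, model_daily, grid, pollutant=pollutant,
                                 settings=settings)
        fused_pairs = _withheld_pairs(test, result.fused, grid)
        raw_pairs = _withheld_pairs(test, model_daily, grid)
        per_fold.append({
            "fold": fold_id,
            "n_withheld_obs": int(len(fused_pairs)),
            "pooled_r2_fused": pooled_r2(fused_pairs["obs"], fused_pairs["pred"]),
            "pooled_r2_raw": pooled_r2(raw_pairs["obs"], raw_pairs["pred"]),
            "nrmse_fused": nrmse(fused_pairs["obs"], fused_pairs["pred"]),
            "nrmse_raw": nrmse(raw_pairs["obs"], raw_pairs["pred"]),
        })
    keys = ["pooled_r2_fused", "pooled_r2_raw", "nrmse_fused", "nrmse_raw"]
    summary = {key: float(np.mean([f[key] for f in per_fold])) for key in keys}
    summary["n_folds"] = folds.k
    return CrossValResult(per_fold=per_fold, summary=summary, folds=folds)


def label_sampling_days(obs: pd.DataFrame) -> pd.Series:
    """Label each calendar day by which sampling-frequency networks report.

    Day "A": only 1-in-3 monitors report (sparsest for speciated networks);
    day "B": 1-in-3 and 1-in-6 schedules coincide (densest); day "C": only
    daily monitors report.  ``obs`` needs columns ``date`` and
    ``sampling_freq`` with values among ``daily, 1-in-3, 1-in-6``.
    """
    labels = {}
    for date, g in obs.groupby("date"):
        freqs = set(g["sampling_freq"])
        if "1-in-3" in freqs and "1-in-6" in freqs:
            labels[date] = "B"
        elif "1-in-3" in freqs:
            labels[date] = "A"
        elif "daily" in freqs:
            labels[date] = "C"
        else:
            labels[date] = "other"
    return pd.Series(labels, name="day_label")


def stratify_by_sampling_day(paired: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum pooled R² and NRMSE by sampling-day label.

    ``paired`` needs columns ``date, obs, pred, sampling_freq``.  Returns a
    tidy frame with one row per (label, metric).
    """
    labels = label_sampling_days(paired)
    paired = paired.assign(day_label=paired["date"].map(labels))
    rows = []
    for label, g in paired.groupby("day_label"):
        try:
            r2 = pooled_r2(g["obs"], g["pred"])
        except UndefinedMetricError:
            r2 = np.nan
        rows.append({"day_label": label, "metric": "pooled_r2",
                     "value": r2, "n": int(len(g))})
        rows.append({"day_label": label, "metric": "nrmse",
                     "value": nrmse(g["obs"], g["pred"]), "n": int(len(g))})
    return pd.DataFrame(rows)


def split_east_west(sites: pd.DataFrame, threshold_lon: float = EAST_WEST_LON):
    """Split a site table at a longitude line: (west, east).

    A site exactly on the line counts as eastern (``lon >= threshold``).
    """
    west = sites[sites["lon"] < threshold_lon]
    east = sites[sites["lon"] >= threshold_lon]
    return west, east
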