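"""Seeded synthetic scenarios with the structure the fusion method assumes.

A scenario consists of a rectangular lat/lon grid, a spatially smooth and
strictly positive "true" concentration field with a seasonal cycle, a model
field whose power-law-corrected values differ from truth by a smooth
multiplicative error (the regime in which ratio interpolation can help), a
monitor network mixing daily, 1-in-3-day and 1-in-6-day sampling schedules,
and rectangular census tracts with random populations.  Everything derives
from a single integer seed and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .exposure import TractRecord
from .fields import daily_field
from .grid import GridDefinition, HourlyFieldDay, local_offset_hours

DAYS_IN_YEAR = 365

#: Observation schedules: day indices (0-based) on which each network reports.
#: The 1-in-3 and 1-in-6 schedules coincide on every sixth day.
SCHEDULES = {
    "daily": lambda idx: np.ones_like(idx, dtype=bool),
    "1-in-3": lambda idx: idx % 3 == 0,
    "1-in-6": lambda idx: idx % 6 == 0,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a synthetic study.

    The true field is ``mean_level * exp(S(x)) * exp(a_s sin(2pi (t - phi)/365))``
    with ``S`` a mixture of Gaussian bumps; the model field satisfies
    ``alpha * model**beta = truth * exp(eps)`` for a smooth zero-mean error
    surface ``eps``, and observations are truth at monitor cells with
    multiplicative lognormal measurement noise of log-sd ``noise_sigma``.
    """

    n_rows: int = 30
    n_cols: int = 40
    lat0: float = 33.0
    lon0: float = -100.0
    dlat: float = 0.1
    dlon: float = 0.1
    year: int = 2011
    n_days: int = DAYS_IN_YEAR
    mean_level: float = 10.0          # domain-mean concentration, ug/m3
    seasonal_amplitude: float = 0.3   # log-scale seasonal swing
    seasonal_phase_day: float = 15.0
    n_bumps: int = 5
    bump_sd_deg: float = 1.0          # spatial correlation length of truth
    bump_amplitude: float = 0.5       # log-scale spatial contrast
    alpha: float = 1.5                # true power-law scale
    beta: float = 0.8                 # true power-law exponent
    bias_amplitude: float = 0.3       # log-scale static smooth model error
    bias_sd_deg: float = 1.5
    bias_temporal_amplitude: float = 0.3  # log-scale day-varying model error
    bias_temporal_corr_days: float = 15.0
    noise_sigma: float = 0.1          # lognormal measurement noise, log-sd
    n_sites: int = 40
    freq_mix: tuple = (("daily", 0.4), ("1-in-3", 0.4), ("1-in-6", 0.2))
    pollutant: str = "pm25"
    tract_shape: tuple = (3, 4)
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_sites > self.n_rows * self.n_cols:
            raise ValueError("more sites than grid cells")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


@dataclass
class ScenarioData:
    """Generated scenario: grid, truth/model fields, monitors, and tracts."""

    scenario: SyntheticScenario
    grid: GridDefinition
    truth: xr.DataArray
    model: xr.DataArray
    monitors: pd.DataFrame
    tracts: list = dc_field(default_factory=list)


def _gaussian_mixture_surface(grid: GridDefinition, rng, n_bumps, sd_deg, amplitude):
    surface = np.zeros(grid.n_cells)
    lat_lo, lat_hi = grid.lat.min(), grid.lat.max()
    lon_lo, lon_hi = grid.lon.min(), grid.lon.max()
    for _ in range(n_bumps):
        c_lat = rng.uniform(lat_lo, lat_hi)
        c_lon = rng.uniform(lon_lo, lon_hi)
        amp = rng.uniform(-amplitude, amplitude)
        d2 = (grid.lat - c_lat) ** 2 + (grid.lon - c_lon) ** 2
        surface += amp * np.exp(-d2 / (2.0 * sd_deg ** 2))
    return surface


def _model_error_field(grid: GridDefinition, rng, scn: "SyntheticScenario") -> np.ndarray:
    """Smooth multiplicative model-error exponent eps(day, cell).

    A chemical-transport model errs both persistently (emissions, terrain)
    and day to day (meteorology), so eps combines a static spatially smooth
    bias with a day-varying component: the same Gaussian spatial kernels
    modulated by zero-mean AR-smoothed daily paths.  Every slice is spatially
    smooth; eps vanishes identically when both amplitudes are zero.
    """
    from scipy.ndimage import gaussian_filter1d

    static = np.zeros(grid.n_cells)
    if scn.bias_amplitude > 0:
        static = _gaussian_mixture_surface(grid, rng, scn.n_bumps,
                                           scn.bias_sd_deg, scn.bias_amplitude)
        static -= static.mean()
    eps = np.broadcast_to(static, (scn.n_days, grid.n_cells)).copy()
    if scn.bias_temporal_amplitude > 0:
        lat_lo, lat_hi = grid.lat.min(), grid.lat.max()
        lon_lo, lon_hi = grid.lon.min(), grid.lon.max()
        for _ in range(scn.n_bumps):
            c_lat = rng.uniform(lat_lo, lat_hi)
            c_lon = rng.uniform(lon_lo, lon_hi)
            d2 = (grid.lat - c_lat) ** 2 + (grid.lon - c_lon) ** 2
            kernel = np.exp(-d2 / (2.0 * scn.bias_sd_deg ** 2))
            path = gaussian_filter1d(rng.normal(size=scn.n_days),
                                     scn.bias_temporal_corr_days, mode="wrap")
            sd = path.std()
            if sd > 0:
                path = (path - path.mean()) / sd
            eps += scn.bias_temporal_amplitude * path[:, None] * kernel[None, :]
    return eps


def _site_counts(n_sites: int, freq_mix) -> dict:
    counts, assigned = {}, 0
    for i, (freq, frac) in enumerate(freq_mix):
        c = round(n_sites * frac) if i < len(freq_mix) - 1 else n_sites - assigned
        counts[freq] = int(c)
        assigned += int(c)
    return counts


def generate_scenario(scn: SyntheticScenario) -> ScenarioData:
    """Generate the full scenario from its seed.

    The model field is constructed as ``((truth * exp(eps)) / alpha)**(1/beta)``
    so the power-law correction with the true parameters recovers truth up to
    the smooth error surface ``eps`` — exactly the spatial bias the ratio
    interpolation is meant to remove.
    """
    rng = np.random.default_rng(scn.seed)
    grid = GridDefinition.regular(scn.n_rows, scn.n_cols, scn.lat0, scn.lon0,
                                  scn.dlat, scn.dlon)
    dates = pd.date_range(f"{scn.year}-01-01", periods=scn.n_days, freq="D")
    t = np.arange(scn.n_days)

    spatial = _gaussian_mixture_surface(grid, rng, scn.n_bumps,
                                        scn.bump_sd_deg, scn.bump_amplitude)
    seasonal = scn.seasonal_amplitude * np.sin(
        2.0 * np.pi * (t - scn.seasonal_phase_day) / DAYS_IN_YEAR)
    truth_vals = scn.mean_level * np.exp(seasonal)[:, None] * np.exp(spatial)[None, :]

    eps = _model_error_field(grid, rng, scn)
    model_vals = ((truth_vals * np.exp(eps)) / scn.alpha) ** (1.0 / scn.beta)

    site_cells = rng.choice(grid.n_cells, size=scn.n_sites, replace=False)
    counts = _site_counts(scn.n_sites, scn.freq_mix)
    freqs = [f for f, c in counts.items() for _ in range(c)]
    records = []
    for i, (cell, freq) in enumerate(zip(site_cells, freqs)):
        sampled = SCHEDULES[freq](t)
        noise = rng.normal(0.0, scn.noise_sigma, size=int(sampled.sum()))
        obs = truth_vals[sampled, cell] * np.exp(noise)
        for d, v in zip(dates[sampled], obs):
            records.append({"site_id": f"site{i:03d}", "lat": grid.lat[cell],
                            "lon": grid.lon[cell], "pollutant": scn.pollutant,
                            "date": d, "value": v, "sampling_freq": freq})
    monitors = pd.DataFrame.from_records(records)

    tracts = generate_tracts(grid, rng, scn.tract_shape)
    return ScenarioData(
        scenario=scn, grid=grid,
        truth=daily_field(truth_vals, dates, grid, name="truth"),
        model=daily_field(model_vals, dates, grid, name="model",
                          attrs={"units": "ug/m3", "pollutant": scn.pollutant}),
        monitors=monitors, tracts=tracts)


def generate_tracts(grid: GridDefinition, rng, shape=(3, 4)) -> list:
    """Rectangular tracts tiling the grid bounding box, random populations."""
    half_lat = (grid.lat.max() - grid.lat.min()) / max(grid.n_rows - 1, 1) / 2 or 0.05
    half_lon = (grid.lon.max() - grid.lon.min()) / max(grid.n_cols - 1, 1) / 2 or 0.05
    lat_edges = np.linspace(grid.lat.min() - half_lat, grid.lat.max() + half_lat, shape[0] + 1)
    lon_edges = np.linspace(grid.lon.min() - half_lon, grid.lon.max() + half_lon, shape[1] + 1)
    tracts = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            poly = shapely.box(lon_edges[j], lat_edges[i], lon_edges[j + 1], lat_edges[i + 1])
            tracts.append(TractRecord(tract_id=f"tract{i}{j}",
                                      population=float(rng.integers(500, 5000)),
                                      polygon=poly))
    return tracts


def generate_annual_pairs(n_sites: int, alpha: float, beta: float, sigma: float,
                          rng, log_spread: float = 0.5, level: float = 10.0) -> pd.DataFrame:
    """Annual-mean pairs obeying the power law with lognormal scatter.

    Model means are lognormal around ``level``; observation means are
    ``alpha * model_mean**beta`` times ``exp(N(0, sigma))``.  Used for
    parameter-recovery studies without building full fields.
    """
    model_mean = level * np.exp(rng.normal(0.0, log_spread, size=n_sites))
    obs_mean = alpha * model_mean ** beta * np.exp(rng.normal(0.0, sigma, size=n_sites))
    return pd.DataFrame({"cell_id": np.arange(n_sites),
                         "obs_mean": obs_mean, "model_mean": model_mean,
                         "n_obs": np.full(n_sites, DAYS_IN_YEAR)})


def generate_hourly(scn: SyntheticScenario, day, daily_mean: np.ndarray | None = None,
                    diel_amplitude: float = 0.2, noise_rel_sd: float = 0.02,
                    n_hours: int = 72) -> HourlyFieldDay:
    """UTC-hourly concentrations consistent with a prescribed daily mean.

    Each cell follows a diel cosine cycle (afternoon peak in local time by
    the cell's nautical offset) plus noise that repeats with the local
    hour-of-day and is recentred to zero mean, so the arithmetic mean over
    any complete local day equals ``daily_mean`` exactly.  ``n_hours`` UTC
    hours are emitted starting the UTC midnight before ``day`` so the local
    day stays complete after time-zone shifting.
    """
    rng = np.random.default_rng(scn.seed + 1)
    grid = GridDefinition.regular(scn.n_rows, scn.n_cols, scn.lat0, scn.lon0,
                                  scn.dlat, scn.dlon)
    if daily_mean is None:
        daily_mean = np.full(grid.n_cells, scn.mean_level)
    daily_mean = np.asarray(daily_mean, dtype=float)

    start = np.datetime64(day, "h") - np.timedelta64(24, "h")
    timestamps = start + np.arange(n_hours) * np.timedelta64(1, "h")
    utc_hour = (timestamps - timestamps[0]).astype(int)

    offsets = np.array([local_offset_hours(lo) for lo in grid.lon])
    local_hod = (utc_hour[:, None] + offsets[None, :]) % 24
    diel = 1.0 + diel_amplitude * np.cos(2.0 * np.pi * (local_hod - 14) / 24.0)
    noise_by_hod = rng.normal(0.0, noise_rel_sd, size=(24, grid.n_cells))
    noise_by_hod -= noise_by_hod.mean(axis=0, keepdims=True)
    values = daily_mean[None, :] * (diel + noise_by_hod[local_hod, np.arange(grid.n_cells)[None, :]])
    return HourlyFieldDay(timestamps=timestamps, values=values,
                          cell_ids=grid.cell_ids)
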