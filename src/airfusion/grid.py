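"""Model-raster geometry, monitor-to-cell assignment, and daily aggregation.

The model raster is a rectangular matrix of cells addressed row-major by an
integer ``cell_id``; each cell carries its centroid latitude/longitude.  All
distances are great-circle (haversine) on centroid coordinates.  Hourly model
output arrives in UTC and is aggregated to a pollutant-specific daily metric
in local time: 24-h mean for particulates, daily 1-h maximum for gases, and
daily maximum 8-h running mean for ozone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteDayError, OutOfDomainError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: Daily summary metric per pollutant class (EPA-standard conventions):
#: particulate matter species use the 24-h mean, gaseous species the daily
#: 1-h maximum, and ozone the daily maximum 8-h running mean.
DEFAULT_METRICS = {
    "pm25": "mean24h",
    "pm10": "mean24h",
    "ec": "mean24h",
    "oc": "mean24h",
    "so4": "mean24h",
    "no3": "mean24h",
    "nh4": "mean24h",
    "co": "max1h",
    "no2": "max1h",
    "nox": "max1h",
    "so2": "max1h",
    "o3": "max8h",
}

VALID_METRICS = ("mean24h", "max1h", "max8h")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    All arguments broadcast against each other.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridDefinition:
    """Cell-centroid geometry of the model raster.

    Cells are indexed row-major: ``cell_id = row * n_cols + col``.

    Parameters
    ----------
    n_rows, n_cols : int
        Raster shape.
    lat, lon : ndarray of shape (n_rows * n_cols,)
        Centroid coordinates in decimal degrees, row-major order.
    """

    n_rows: int
    n_cols: int
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        n = self.n_rows * self.n_cols
        if lat.shape != (n,) or lon.shape != (n,):
            raise ValueError(f"expected {n} centroids, got lat {lat.shape} lon {lon.shape}")
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")
        if len(np.unique(np.stack([lat, lon], axis=1), axis=0)) != n:
            raise ValueError("centroids are not all distinct")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row, col) = ({row}, {col}) outside grid")
        return row * self.n_cols + col

    @classmethod
    def regular(cls, n_rows: int, n_cols: int, lat0: float, lon0: float,
                dlat: float, dlon: float) -> "GridDefinition":
        """Regular lat/lon grid with origin centroid (lat0, lon0)."""
        rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        lat = lat0 + rows.ravel() * dlat
        lon = lon0 + cols.ravel() * dlon
        return cls(n_rows, n_cols, lat, lon)

    def typical_diagonal_km(self) -> float:
        """Approximate centroid-to-centroid diagonal spacing in km."""
        if self.n_rows > 1 and self.n_cols > 1:
            j = self.cell_id(1, 1)
        elif self.n_cols > 1:
            j = self.cell_id(0, 1)
        elif self.n_rows > 1:
            j = self.cell_id(1, 0)
        else:
            return 1.0
        return float(haversine_km(self.lat[0], self.lon[0], self.lat[j], self.lon[j]))


@dataclass(frozen=True)
class PollutantSpec:
    """A pollutant name with its daily summary metric and units."""

    name: str
    daily_metric: str = ""
    units: str = "ug/m3"

    def __post_init__(self):
        if not self.daily_metric:
            object.__setattr__(self, "daily_metric",
                               DEFAULT_METRICS.get(self.name.lower(), "mean24h"))
        if self.daily_metric not in VALID_METRICS:
            raise ValueError(f"unknown daily metric {self.daily_metric!r}")


@dataclass
class HourlyFieldDay:
    """Hourly model concentrations for one target day, timestamped in UTC.

    ``values`` has shape (n_hours, n_cells); hours beyond 24 are allowed so
    the local day remains complete after time-zone shifting.
    """

    timestamps: np.ndarray  # datetime64[h], UTC
    values: np.ndarray
    cell_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[h]")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values rows must match timestamps")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[1])


def assign_monitor_to_cell(monitor_lat: float, monitor_lon: float,
                           grid: GridDefinition,
                           max_distance_km: float | None = None) -> int:
    """Return the id of the grid cell whose centroid is nearest the monitor.

    Distance is great-circle; ties break to the lowest ``cell_id``.  A monitor
    farther than ``max_distance_km`` (default: two cell diagonals) from every
    centroid raises :class:`OutOfDomainError`.
    """
    d = haversine_km(monitor_lat, monitor_lon, grid.lat, grid.lon)
    idx = int(np.argmin(d))  # argmin takes the first minimum: lowest cell_id
    tol = 2.0 * grid.typical_diagonal_km() if max_distance_km is None else max_distance_km
    if d[idx] > tol:
        raise OutOfDomainError(
            f"monitor at ({monitor_lat}, {monitor_lon}) is {d[idx]:.1f} km from the "
            f"nearest centroid (tolerance {tol:.1f} km)")
    return idx


def assign_monitors(lats, lons, grid: GridDefinition,
                    max_distance_km: float | None = None) -> np.ndarray:
    """Vectorized nearest-centroid assignment for many monitors."""
    return np.array([assign_monitor_to_cell(la, lo, grid, max_distance_km)
                     for la, lo in zip(np.asarray(lats), np.asarray(lons))], dtype=int)


def local_offset_hours(lon: float, zone_table=None) -> int:
    """Whole-hour UTC offset for a longitude.

    By default the offset is the nautical-zone value ``round(lon / 15)``
    (half-up rounding).  ``zone_table`` — an iterable of
    ``(lon_west, lon_east, offset)`` triples, first match wins — overrides the
    default and can encode civil time zones.
    """
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    if zone_table is not None:
        for lo, hi, off in zone_table:
            if lo <= lon < hi:
                return int(off)
    return int(np.floor(lon / 15.0 + 0.5))


def _max_running_8h(day_values: np.ndarray) -> np.ndarray:
    # 17 complete 8-h windows starting at local hours 0..16
    csum = np.cumsum(day_values, axis=0)
    csum = np.vstack([np.zeros((1, day_values.shape[1])), csum])
    windows = (csum[8:25] - csum[0:17]) / 8.0
    return windows.max(axis=0)


def aggregate_hourly_to_daily(hourly: HourlyFieldDay, spec: PollutantSpec,
                              offset: int, date) -> np.ndarray:
    """Aggregate UTC-hourly values to the daily metric of ``spec`` in local time.

    The local clock is UTC shifted by ``offset`` whole hours; the target day
    runs midnight to midnight local.  ``mean24h`` is the arithmetic mean of
    the 24 local hours, ``max1h`` their maximum, and ``max8h`` the maximum of
    the 17 complete 8-hour running means whose windows lie wholly within the
    local day.

    Returns an array of one value per cell.  Raises
    :class:`IncompleteDayError` naming any missing local hours.
    """
    date = np.datetime64(date, "D")
    local = hourly.timestamps + np.timedelta64(int(offset), "h")
    in_day = local.astype("datetime64[D]") == date
    local_hours = (local[in_day] - date.astype("datetime64[h]")).astype(int)
    expected = set(range(24))
    present = set(int(h) for h in local_hours)
    missing = sorted(expected - present)
    if missing:
        raise IncompleteDayError(f"local day {date} missing hours {missing}")
    # order by local hour; drop duplicates should the input repeat an hour
    sel = np.flatnonzero(in_day)
    order = np.argsort(local_hours, kind="stable")
    first = {}
    for k in order:
        h = int(local_hours[k])
        if h not in first:
            first[h] = sel[k]
    rows = np.array([first[h] for h in range(24)])
    day_values = hourly.values[rows]

    if spec.daily_metric == "mean24h":
        return day_values.mean(axis=0)
    if spec.daily_metric == "max1h":
        return day_values.max(axis=0)
    return _max_running_8h(day_values)


def clamp_nonnegative(values: np.ndarray, context: str = "model field") -> np.ndarray:
    """Clamp negative concentrations (possible in some CTM outputs) to zero."""
    values = np.asarray(values, dtype=float)
    n_neg = int(np.sum(values < 0))
    if n_neg:
        logger.info("clamped %d negative values to 0 in %s", n_neg, context)
        values = np.where(values < 0, 0.0, values)
    return values
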