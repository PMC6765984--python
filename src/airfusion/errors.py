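"""Exception hierarchy for airfusion.

All data-quality problems raise a subclass of :class:`AirFusionError` so
callers (and the CLI) can distinguish bad input from programming errors.
"""


class AirFusionError(Exception):
    """Base class for all airfusion errors."""


class OutOfDomainError(AirFusionError):
    """A monitor lies farther from every grid centroid than the tolerance."""


class IncompleteDayError(AirFusionError):
    """Hourly data do not cover all 24 local hours of the requested day."""


class InsufficientDataError(AirFusionError):
    """Too few usable records to perform the requested fit or metric."""


class DegenerateFitError(AirFusionError):
    """Regression input has zero variance in the predictor."""


class UndefinedRatioError(AirFusionError):
    """A normalized ratio is undefined (non-positive mean or model value)."""


class UndefinedMetricError(AirFusionError):
    """No qualifying site/day remains after degeneracy filtering."""


class GriddedDataError(AirFusionError):
    """A gridded input is incomplete (missing cells or days) or malformed."""
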