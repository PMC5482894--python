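"""Exception hierarchy shared across the pipeline."""


class GrasstrendError(Exception):
    """Base class for all package errors."""


class BandMissingError(GrasstrendError):
    """A spectrum lacks reflectance at a required wavelength."""


class DegenerateSpectrumError(GrasstrendError):
    """NDVI denominator is zero (both bands reflect nothing)."""


class DomainError(GrasstrendError):
    """Input values violate a model family's domain (e.g. x <= 0 for log/power)."""


class SingularFitError(GrasstrendError):
    """Regression design is degenerate (e.g. all x identical)."""


class FitFailureError(GrasstrendError):
    """Nonlinear least squares failed to converge.

    Carries the log-transform fallback model so callers may degrade
    gracefully.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class GridMismatchError(GrasstrendError):
    """Two rasters do not share shape and georeference."""


class DegenerateSeriesError(GrasstrendError):
    """A time series has zero variance in every window (R/S undefined)."""


class EstimationFailedError(GrasstrendError):
    """Too few valid rescaled-range points to fit the log-log line."""


class ConfigError(GrasstrendError):
    """Run configuration is invalid or references missing inputs."""


class StageError(GrasstrendError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
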