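"""Exception hierarchy for the pipeline.

Everything derives from :class:`ProtonfluxError` so callers can catch the
package's failures with a single handler; individual classes also inherit the
closest builtin (``ValueError``, ``TypeError``, ``ZeroDivisionError``) so that
generic error handling keeps working.
"""


class ProtonfluxError(Exception):
    """Base class for all errors raised by protonflux."""


class TraceParseError(ProtonfluxError, ValueError):
    """A delimited trace/series file could not be parsed; names the line."""


class TraceValidationError(ProtonfluxError, ValueError):
    """Input data violate a container invariant (non-monotone time, NaN, ...)."""


class TraceKindError(ProtonfluxError, TypeError):
    """An operation received a trace whose units tag it cannot consume."""


class WindowError(ProtonfluxError, ValueError):
    """A requested analysis window does not intersect the available data."""


class InsufficientDataError(ProtonfluxError, ValueError):
    """Too few samples or calibration points for the requested fit."""


class UnidentifiableFitError(ProtonfluxError, ValueError):
    """Degenerate input makes the fit parameters unidentifiable."""


class CalibrationDomainError(ProtonfluxError, ValueError):
    """A ratio lies outside the invertible range of the calibration sigmoid."""


class ConfigurationError(ProtonfluxError, ValueError):
    """A required physicochemical constant or setting is missing."""


class UnresolvableBufferingError(ProtonfluxError, ValueError):
    """The CO2-pulse pH shift is too small to resolve a buffer capacity."""


class ZeroRateError(ProtonfluxError, ZeroDivisionError):
    """The uncatalyzed depletion rate is zero; enzyme units are undefined."""


class InconsistentAssayError(ProtonfluxError, ValueError):
    """Catalyzed and uncatalyzed depletion rates have opposite signs."""


class PlacementError(ProtonfluxError, RuntimeError):
    """Requested synthetic-nuclei placement is infeasible at this density."""
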