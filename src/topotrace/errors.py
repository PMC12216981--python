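"""Exception hierarchy shared across the pipeline stages."""


class TopotraceError(Exception):
    """Base class for all package errors."""


class FormatError(TopotraceError):
    """Input file or array has the wrong shape/dtype."""


class ValidationError(TopotraceError):
    """Data violates a documented invariant (non-finite heights, ...)."""


class ConfigError(TopotraceError):
    """Invalid configuration value or unknown mode."""


class GeometryError(TopotraceError):
    """Degenerate geometry: intersecting curves, zero-length segments, ..."""


class ParityError(TopotraceError):
    """A crossing node has an odd number of emanating branches."""


class TracingError(TopotraceError):
    """Skeleton segments cannot be ordered into a consistent tour."""


class ClusteredCrossingError(TopotraceError):
    """More than two duplexes pass through a single crossing region."""


class ComplexityError(TopotraceError):
    """Diagram exceeds the configured crossing limit for exact invariants."""


class DegenerateError(TopotraceError):
    """Object too small or empty for the requested measurement."""
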