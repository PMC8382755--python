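"""Exception hierarchy.

All package-specific failures derive from :class:`EyeGabaError` so callers can
catch one base class at pipeline boundaries.
"""


class EyeGabaError(Exception):
    """Base class for all errors raised by this package."""


class MalformedInputError(EyeGabaError):
    """Raw input (event stream, table) violates its format contract."""


class ParameterError(EyeGabaError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class AmbiguousDominanceError(EyeGabaError):
    """Left and right median phase durations tie exactly; dominance cannot be
    assigned without an explicit override."""


class EmptySampleError(EyeGabaError):
    """A duration sample is empty; medians must not be computed from it."""


class InsufficientDataError(EyeGabaError):
    """Too few observations for the requested inference (n < 3)."""


class DegenerateInputError(EyeGabaError):
    """Zero-variance or otherwise degenerate data where a statistic is undefined."""


class PairingError(EyeGabaError):
    """Two measurements that must share subject/eye/reference do not."""


class ConfigurationError(EyeGabaError):
    """Inconsistent pipeline configuration (e.g. water referencing without
    tissue fractions)."""
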