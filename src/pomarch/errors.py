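"""Exception hierarchy shared across the package.

All errors raised by pomarch derive from :class:`PomarchError`, so callers
(and the CLI) can catch one base class.
"""


class PomarchError(Exception):
    """Base class for all pomarch errors."""


class InvalidMeasurementError(PomarchError):
    """A blade measurement is non-positive or otherwise physically invalid."""


class OrientationError(InvalidMeasurementError):
    """Blade width exceeds blade length; the caller must assign the major axis
    to the length before constructing records (the swap is never silent)."""


class ParameterError(PomarchError):
    """A model parameter is outside its admissible domain (e.g. s <= 0)."""


class RankError(PomarchError):
    """A leaf rank is outside 1..nl or ranks are not contiguous."""


class DataError(PomarchError):
    """Input data are missing, malformed, degenerate or insufficient."""


class FitError(PomarchError):
    """A fitting stage failed (non-convergence, degenerate design)."""


class ConfigError(PomarchError):
    """A configuration value is missing or inconsistent."""
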