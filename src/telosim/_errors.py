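"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`TelosimError`,
so callers (and the CLI) can distinguish configuration/state problems from bugs.
"""


class TelosimError(Exception):
    """Base class for all telosim errors."""


class ConfigError(TelosimError, ValueError):
    """A configuration value violates its invariant; message names the field."""


class StateError(TelosimError, RuntimeError):
    """An operation was called before its prerequisites were computed."""


class DomainError(TelosimError, ValueError):
    """An input value lies outside the supported domain."""


class UndefinedStatisticError(TelosimError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class CollinearityError(TelosimError, ValueError):
    """The regression design matrix is rank deficient; names offending columns."""


class GroupingError(TelosimError, ValueError):
    """A grouped analysis received an empty or degenerate group."""


class CalibrationError(TelosimError, RuntimeError):
    """The calibration loss could not be evaluated."""
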