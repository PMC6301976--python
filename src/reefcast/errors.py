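"""Exception hierarchy.

All reefcast errors derive from :class:`ReefcastError` so callers can catch
one base class; the leaves distinguish bad user input from bad configuration
and from data-format problems (the CLI maps these onto distinct exit codes).
"""


class ReefcastError(Exception):
    """Base class for all reefcast errors."""


class InvalidInputError(ReefcastError, ValueError):
    """A function argument is outside its documented domain."""


class ConfigurationError(ReefcastError, ValueError):
    """A configuration object or file is internally inconsistent."""


class DataError(ReefcastError, ValueError):
    """An input data file or table violates its documented schema."""


class MalformedSeriesError(DataError):
    """A time series has gaps, disorder, or out-of-range values."""


class UnderdeterminedFitError(ReefcastError, ValueError):
    """Fewer observations than free parameters in a fit."""


class InsufficientEventsError(ReefcastError, ValueError):
    """Too few events to compute the requested statistic."""


class InsufficientDataError(ReefcastError, ValueError):
    """Too few values to compute the requested summary."""


class SingularityError(ReefcastError, ArithmeticError):
    """A closed-form expression is evaluated at a pole."""
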