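"""Exception hierarchy for woundkin.

All woundkin errors derive from :class:`WoundkinError` so callers can catch
the package's failures with a single except clause while still
distinguishing schema problems from numerical degeneracies.
"""


class WoundkinError(Exception):
    """Base class for all woundkin errors."""


class InvalidInputError(WoundkinError):
    """Input values violate a precondition (e.g. zero initial gap area)."""


class DegenerateSeriesError(WoundkinError):
    """A time series is too short or too flat to support the requested fit."""


class MissingTimepointError(WoundkinError):
    """A requested time is not on the observed sampling grid."""


class InsufficientDataError(WoundkinError):
    """Not enough observations for the requested model."""


class DegenerateDataError(WoundkinError):
    """Flat data with nonzero residuals: goodness-of-fit is undefined."""


class ParameterizationError(WoundkinError):
    """Simulation parameters describe a physically impossible trajectory."""


class SchemaError(WoundkinError):
    """A CSV file does not match the expected schema; message carries line numbers."""
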