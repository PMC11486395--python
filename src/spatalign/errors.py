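"""Exception hierarchy shared across the package."""


class SpatalignError(Exception):
    """Base class for all package errors."""


class ValidationError(SpatalignError, ValueError):
    """Invalid parameter values (nonpositive scales, bad counts, ...)."""


class NoDataError(SpatalignError):
    """An operation requires loaded data and none is present."""


class SchemaError(SpatalignError):
    """Input table is missing a mandatory column or field."""


class ModeError(SpatalignError):
    """Operation attempted in the wrong session phase.

    Elastic drags are only valid after the linear phase has been
    closed, and linear manipulations are frozen afterwards.
    """


class StateError(SpatalignError):
    """A point is in the wrong interaction state for the operation."""


class InsufficientDataError(SpatalignError):
    """Too few observations/bins to compute the requested metric."""


class FormatError(SpatalignError):
    """Unsupported or malformed file format."""


class ReplayError(SpatalignError):
    """A recorded log cannot be replayed (unknown op, missing scale)."""
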