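"""Exception hierarchy for the spkdose pipeline.

Every stage raises a subclass of :class:`SpkError` so callers (and the CLI)
can distinguish user-input problems from genuine bugs.
"""


class SpkError(Exception):
    """Base class for all spkdose errors."""


class DomainError(SpkError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class IntervalError(DomainError):
    """A void interval is empty or reversed (t_c <= t_p), or has zero length."""


class ResolutionError(SpkError):
    """A required field could not be filled by any tier of the default cascade."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"cannot resolve required field {field!r}")


class ParseError(SpkError):
    """A row of an input table is malformed."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class RouteCodeError(ParseError):
    """An exposure route/scenario code is outside the recognised range 1-7."""


class RouteNotSupportedError(SpkError):
    """Inhalation (1) and dermal (2) routes are recognised but not modelled."""


class NonIdentifiableError(SpkError):
    """The averaging window does not overlap the post-exposure era, so the
    observed excretion rate carries no information about the dose."""


class InsufficientDataError(SpkError):
    """Too few complete observations for the requested statistical test."""


class ConfigError(SpkError):
    """A run configuration is invalid or references missing paths."""
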