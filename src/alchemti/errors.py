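"""Exception hierarchy for the package."""


class AlchemtiError(Exception):
    """Base class for package errors."""


class InvalidInputError(AlchemtiError, ValueError):
    """A value violates a documented precondition (non-positive IC50,
    temperature mismatch, malformed schedule, NaN in a time series, ...)."""


class UnitError(InvalidInputError):
    """A quantity was supplied without a recognised unit annotation."""
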