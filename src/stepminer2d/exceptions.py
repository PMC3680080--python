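"""Exception hierarchy.

All errors raised by this package derive from :class:`StepMinerError`, so
callers can catch the package's failures with a single except clause while
still distinguishing malformed input from degenerate-but-well-formed input.
"""


class StepMinerError(Exception):
    """Base class for all errors raised by stepminer2d."""


class InvalidInputError(StepMinerError, ValueError):
    """Input violates a precondition (wrong shape, range, or missing data)."""


class DegenerateInputError(StepMinerError, ValueError):
    """Input is well-formed but admits no meaningful fit.

    Raised when every candidate split has zero signal — e.g. a constant
    series or a constant surface — so no threshold separates anything.
    """


class ParseError(InvalidInputError):
    """A tabular input file could not be parsed or failed validation."""
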