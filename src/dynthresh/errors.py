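"""Exception hierarchy.

All dynthresh errors derive from :class:`DynthreshError` so callers can catch
the package's failures with a single ``except``. Parameter problems (bad
constants) are distinguished from domain problems (a simulation or solve that
left its region of validity) and from data-format problems on file input.
"""


class DynthreshError(Exception):
    """Base class for all package errors."""


class ParameterError(DynthreshError, ValueError):
    """A model, noise, or estimator parameter violates an invariant."""


class DomainError(DynthreshError, ValueError):
    """A computation left its domain of validity (e.g. nonpositive ISI).

    Attributes
    ----------
    index : int or None
        Index of the offending element, when meaningful.
    """

    def __init__(self, message, index=None):
        super().__init__(message)
        self.index = index


class FormatError(DynthreshError, ValueError):
    """Malformed input file.

    Attributes
    ----------
    line : int or None
        1-based line number of the offending entry, when known.
    """

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line


class InsufficientDataError(DynthreshError, ValueError):
    """Not enough samples for the requested estimate."""


class DegenerateBlockError(DynthreshError, ValueError):
    """A correlation block has zero variance (constant intervals)."""


class ValidityError(DynthreshError, ValueError):
    """A supplied autocorrelation function is not positive semidefinite."""


class UnfittablePatternError(DynthreshError, ValueError):
    """The observed correlation pattern is outside the model's families."""
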