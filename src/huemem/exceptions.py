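"""Exception hierarchy for huemem.

All package-specific errors derive from :class:`HuememError` so callers can
catch everything from this package with one clause.
"""


class HuememError(Exception):
    """Base class for all huemem errors."""


class InvalidParameterError(HuememError, ValueError):
    """A model or design parameter violates its stated constraints."""


class StaircaseExhaustedError(HuememError, RuntimeError):
    """A staircase was updated after its trial budget was spent."""


class TrialTableError(HuememError, ValueError):
    """A trial table on disk is malformed (missing column, bad row, ...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyCellError(HuememError, ValueError):
    """No trials available for a requested analysis cell."""


class NonIdentifiableError(HuememError, ValueError):
    """The response data cannot identify a psychometric function."""


class FitNotConvergedError(HuememError, RuntimeError):
    """A quantity was requested from an unconverged psychometric fit."""


class CellMismatchError(HuememError, ValueError):
    """Two fits that must share an analysis cell do not."""


class ExtrapolationError(HuememError, ValueError):
    """A joint-match prediction would extrapolate too far outside the
    measured reference range."""


class UndefinedIndexError(HuememError, ZeroDivisionError):
    """The non-additivity index is undefined (both biases are zero)."""


class UndefinedCorrelationError(HuememError, ValueError):
    """Pearson correlation is undefined (zero variance in an input)."""
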