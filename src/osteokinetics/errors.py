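"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`OsteokineticsError`, so callers (and the CLI) can distinguish
domain failures from genuine bugs.
"""

from __future__ import annotations


class OsteokineticsError(Exception):
    """Base class for all package errors."""

    #: short machine-readable category, used by the CLI exit path
    category = "error"


class InputError(OsteokineticsError, ValueError):
    """Invalid user-supplied data (shapes, signs, ordering, duplicates)."""

    category = "input"


class ParseError(InputError):
    """A CSV cell or header failed validation; carries the offending row."""

    category = "parse"

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class UnsupportedExponentError(InputError):
    """The power-law scale exponent beta = 1 is outside the model domain."""

    category = "unsupported-exponent"


class BlowUpDomainError(OsteokineticsError, ValueError):
    """Evaluation past the finite-time blow-up of a superlinear power law."""

    category = "blow-up-domain"

    def __init__(self, message: str, t_star: float):
        super().__init__(message)
        self.t_star = t_star


class NotYetDetectableError(OsteokineticsError, ValueError):
    """The detectable-radius expression is negative: no visible tumor yet."""

    category = "not-yet-detectable"

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


class DegenerateFitError(OsteokineticsError, ValueError):
    """The data carry no usable signal for the requested fit."""

    category = "degenerate-fit"


class UndefinedCorrelationError(OsteokineticsError, ValueError):
    """A constant column makes a correlation undefined; names the column."""

    category = "undefined-correlation"

    def __init__(self, message: str, column: str):
        super().__init__(message)
        self.column = column


class PipelineError(OsteokineticsError, RuntimeError):
    """The end-to-end pipeline cannot produce any output."""

    category = "pipeline"
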