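"""Exception hierarchy for crash-risk analyses.

Every failure mode that a medicolegal report could be challenged on gets
its own exception type, so callers can surface the precise reason an
analysis refused to proceed.
"""


class CrashCausalError(Exception):
    """Base class for all package errors."""


class MalformedCodeError(CrashCausalError, ValueError):
    """An injury code is not a 7-digit string."""


class InvalidSeverityError(CrashCausalError, ValueError):
    """The severity digit of an injury code is outside 1-7."""


class SchemaError(CrashCausalError, ValueError):
    """An input table is missing a mandatory column or has a bad header."""


class DomainError(CrashCausalError, ValueError):
    """A numeric argument is outside its documented domain."""


class UndefinedRatioError(CrashCausalError, ZeroDivisionError):
    """Risk ratio requested with a zero baseline risk."""


class SeparationError(CrashCausalError, RuntimeError):
    """The logistic fit encountered (quasi-)complete separation."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(
            message or f"complete or quasi-complete separation detected on term {term!r}"
        )


class NotConvergedError(CrashCausalError, RuntimeError):
    """A model fit did not converge and downstream use was refused."""


class RejectRateError(CrashCausalError, ValueError):
    """Too large a fraction of input rows failed to parse."""
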