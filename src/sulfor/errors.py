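"""Exception hierarchy for the sulfor model."""

from __future__ import annotations


class SulforError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SulforError, ValueError):
    """Input data violates a structural invariant (grids, signs, spans)."""


class ParseError(SulforError, ValueError):
    """A delimited input file could not be parsed; names row/column."""


class ConfigError(SulforError, ValueError):
    """Model configuration is internally inconsistent."""


class ExtrapolationError(SulforError, ValueError):
    """A query time falls outside the span of a tabulated series."""


class ModelFailureError(SulforError, RuntimeError):
    """Structured model failure: the run left the physical domain.

    Carries the age (Ma) at which the failure occurred and a short
    machine-readable cause so drivers can report failures as data
    rather than crashes.
    """

    def __init__(self, message: str, *, age: float | None = None,
                 cause: str = "model_failure"):
        super().__init__(message)
        self.age = age
        self.cause = cause
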