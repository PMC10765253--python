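"""Exception hierarchy shared across the package."""


class FalffError(Exception):
    """Base class for all package errors."""


class ParameterError(FalffError, ValueError):
    """An argument is outside its valid range (e.g. nonpositive TR)."""


class DataError(FalffError, ValueError):
    """Input data violate an invariant (non-finite values, too few timepoints)."""


class EmptyBandError(ParameterError):
    """A frequency band contains no spectral bins for the given sampling."""


class DegenerateReferenceError(DataError):
    """The standardisation reference region has zero variance."""


class DesignError(FalffError, ValueError):
    """A model design matrix is rank deficient; carries the aliased columns."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class SeparationError(FalffError, RuntimeError):
    """Logistic propensity model is perfectly separated."""
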