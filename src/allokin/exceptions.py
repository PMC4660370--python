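"""Exception hierarchy shared across the analysis modules."""


class AllokinError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AllokinError, ValueError):
    """A model parameter violates its domain (non-finite, wrong sign)."""


class FitError(AllokinError, RuntimeError):
    """A least-squares fit failed to converge or produced no usable result.

    Carries optional diagnostics (initial guesses, residuals) in ``details``.
    """

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class EstimationError(AllokinError, RuntimeError):
    """A derived quantity (initial velocity, Guinier window, ...) could not
    be estimated from the data; ``details`` holds the diagnostic scan."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class ValidationError(AllokinError, ValueError):
    """Input data violate a documented invariant."""
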