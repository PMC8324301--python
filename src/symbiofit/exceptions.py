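"""Exception hierarchy shared across the package."""


class SymbiofitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SymbiofitError, ValueError):
    """Raised when input data or a design violates a stated invariant."""


class ConvergenceError(SymbiofitError, RuntimeError):
    """Raised when an iterative fit fails to converge."""


class SeparationError(ConvergenceError):
    """Raised when a binomial GLM shows complete or quasi-complete separation."""
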