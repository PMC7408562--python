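"""Exception hierarchy shared across the analysis modules."""


class TmzbindError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TmzbindError, ValueError):
    """Raised when input values violate a documented precondition."""


class InvalidParameterError(TmzbindError, ValueError):
    """Raised when a configuration parameter is out of range."""


class RangeError(TmzbindError, ValueError):
    """Raised when a wavelength or time range is empty or out of bounds."""


class InsufficientDataError(TmzbindError, ValueError):
    """Raised when too few points are supplied for a fit."""


class FitFailureError(TmzbindError, RuntimeError):
    """Raised when a nonlinear fit fails to converge.

    Carries ``best_residual``, the smallest sum of squared residuals seen
    across restarts, to aid diagnosis.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class ModelMismatchError(TmzbindError, ValueError):
    """Raised when data contradict the assumed kinetic/physical model."""
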