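"""Exception hierarchy for spdalign."""


class SPDAlignError(Exception):
    """Base class for all spdalign errors."""


class InvalidInputError(SPDAlignError, ValueError):
    """Input violates a precondition (shape, emptiness, bad parameter)."""


class DimensionMismatchError(InvalidInputError):
    """Operands have incompatible matrix dimensions."""


class NotSymmetricError(InvalidInputError):
    """A matrix expected to be symmetric is not, beyond tolerance."""


class SingularMatrixError(SPDAlignError, ValueError):
    """A matrix expected to be positive definite has an eigenvalue at or
    below the floor."""


class ConvergenceError(SPDAlignError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget.

    Carries the last residual in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateDispersionError(SPDAlignError, ValueError):
    """A dataset has zero dispersion where a positive one is required
    (e.g. the stretch factor would be infinite)."""


class NotFittedError(SPDAlignError, RuntimeError):
    """A transform or model was used before being fitted."""
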