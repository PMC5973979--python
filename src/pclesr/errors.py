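"""Exception types shared across the package."""


class PcleSrError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PcleSrError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(PcleSrError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class DegenerateGeometryError(PcleSrError, ValueError):
    """Geometry is degenerate (e.g. all fibre positions collinear)."""


class DegenerateInputError(PcleSrError, ValueError):
    """Numerically degenerate input (e.g. constant frame where spread is required)."""


class TrainingDivergedError(PcleSrError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite loss at training step {step}")
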