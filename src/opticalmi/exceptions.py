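"""Exception types raised by the opticalmi pipeline."""


class OpticalError(Exception):
    """Base class for all opticalmi errors."""


class ParameterError(OpticalError, ValueError):
    """An argument or configuration value is outside its valid domain."""


class BoundaryError(OpticalError, ValueError):
    """An epoch or window would extend beyond the available samples."""


class DimensionError(OpticalError, ValueError):
    """Array shapes of two pipeline objects do not agree."""


class DegenerateSeparationError(OpticalError, ValueError):
    """Class means coincide; a discriminant direction is undefined."""


class TrainingDivergenceError(OpticalError, RuntimeError):
    """Network training produced a non-finite loss (learn rate too large)."""


class OptimizationFailureError(OpticalError, RuntimeError):
    """Every hyper-parameter evaluation failed; no incumbent exists."""
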