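"""Exception hierarchy shared across the package."""


class PerfvizError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PerfvizError, ValueError):
    """A scalar parameter violates its precondition."""


class InvalidLayoutError(PerfvizError, ValueError):
    """Scene masks overlap or fall outside the image bounds."""


class DegenerateReferenceError(PerfvizError, ValueError):
    """Reference-card signal is zero or negative in at least one frame."""


class EmptyROIError(PerfvizError, ValueError):
    """An ROI has no valid pixels to aggregate over."""


class ClassificationError(PerfvizError, ValueError):
    """Threshold-based zone classification produced an empty class."""

    def __init__(self, zone: str):
        self.zone = zone
        super().__init__(f"zone classification produced an empty '{zone}' class")


class DegenerateConfigurationError(PerfvizError, ValueError):
    """Landmark configuration does not constrain an affine map."""


class FitError(PerfvizError, RuntimeError):
    """Nonlinear least squares failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DimensionError(PerfvizError, ValueError):
    """Array shapes are incompatible."""
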