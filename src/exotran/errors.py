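"""Exception hierarchy shared by all solver and I/O modules."""


class ExotranError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExotranError):
    """Invalid run configuration: bad counts, sizes, unknown scheme ids, ..."""


class GeometryError(ExotranError):
    """Layout outside the domain, no inlet-outlet connectivity, ..."""


class PlacementError(GeometryError):
    """Random cell placement failed after the retry budget."""


class SegmentationError(ExotranError):
    """Image segmentation found no usable contours."""


class SolverError(ExotranError):
    """Iterative or linear solve failed to converge."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class NumericalError(ExotranError):
    """NaN/Inf detected during time integration."""
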