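"""Exception hierarchy for the morphometry pipeline.

Every stage raises a subclass of :class:`TubemorphError` so callers (and the
command-line driver) can map failure classes to exit codes.
"""


class TubemorphError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ParameterError(TubemorphError, ValueError):
    """Invalid user-supplied parameter (sizes, probabilities, thresholds)."""

    exit_code = 2


class EmptyInputError(TubemorphError, ValueError):
    """An input volume or mesh contains no usable data."""

    exit_code = 3


class TopologyError(TubemorphError):
    """A mesh does not have the topology a stage requires."""

    exit_code = 4

    def __init__(self, message, euler=None, boundary_loops=None):
        super().__init__(message)
        self.euler = euler
        self.boundary_loops = boundary_loops


class AmbiguityError(TubemorphError):
    """Geometric moments too isotropic to define a unique principal axis."""

    exit_code = 5


class NumericalError(TubemorphError):
    """A linear system or matrix function failed to evaluate soundly."""

    exit_code = 6


class QualityError(TubemorphError):
    """A stage finished but violated its quality contract."""

    exit_code = 7

    def __init__(self, message, metrics=None):
        super().__init__(message)
        self.metrics = metrics or {}


class ConvergenceError(TubemorphError):
    """Iterative solver exhausted its budget without meeting tolerance."""

    exit_code = 8

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SingularityError(NumericalError):
    """A degenerate element (zero-area triangle) made a map singular."""

    exit_code = 9


class DiffeomorphismError(TubemorphError):
    """A registration or feature map contains folds (non-positive Jacobian)."""

    exit_code = 10
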