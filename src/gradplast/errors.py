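"""Exception hierarchy shared across the pipeline stages."""


class GradplastError(Exception):
    """Base class for all package errors."""


class InputShapeError(GradplastError):
    """An array or table has the wrong shape or length."""


class InputValueError(GradplastError):
    """An input value violates a precondition (NaN, out of range, zero norm...)."""


class DesignError(GradplastError):
    """A longitudinal design table violates its invariants."""


class ConfigError(GradplastError):
    """A run configuration is malformed or out of bounds."""


class MeshError(GradplastError):
    """A surface mesh is degenerate or inconsistent."""


class GraphError(GradplastError):
    """An affinity graph is disconnected."""


class NumericalError(GradplastError):
    """A numerical degeneracy (zero variance, eigenvalue at 1, collinearity)."""


class TieError(GradplastError):
    """Row thresholding hit unresolvable ties under the strict tie policy."""


class SamplingError(GradplastError):
    """Too many surface vertices fall outside the sampled field."""


class ParcellationError(GradplastError):
    """A parcellation does not cover the mesh."""


class PipelineError(GradplastError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
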