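"""Exception hierarchy for the stmort package."""


class StmortError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StmortError):
    """An input file or table is missing a required field."""


class GeometryError(StmortError):
    """A geometry is degenerate, non-polygonal or otherwise unusable."""


class ParameterError(StmortError):
    """An argument is outside its valid domain."""


class EstimationError(StmortError):
    """A heuristic estimator cannot be computed from the available data."""


class ModelError(StmortError):
    """A space-time covariance model is structurally inconsistent."""


class KrigingError(StmortError):
    """The kriging system is singular beyond the ridge retry."""


class FitError(StmortError):
    """An iterative fit failed to converge or was requested on unfit state."""


class PipelineError(StmortError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str, manifest=None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest or {}
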