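"""Exception hierarchy.

Every error raised by the package derives from :class:`MacromortError`, so
pipeline callers can catch one type and report the failing stage.
"""


class MacromortError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MacromortError):
    """Invalid simulation or pipeline configuration (bad θ, n_years, ...)."""


class SizingError(MacromortError):
    """Sample too short for the requested lags / tests."""


class EstimationError(MacromortError):
    """Estimation failure (rank deficiency, singular design)."""


class DegeneracyError(MacromortError):
    """Degenerate input: no long-run relation, constant series, zero variance."""


class PanelValidationError(MacromortError):
    """A panel file or frame violates the documented schema."""


class NonInvertibleError(MacromortError):
    """Long-run slope too close to zero to solve for the regressor."""


class AlignmentError(MacromortError):
    """Year coverage of a regressor path does not match the forecast window."""


class PipelineStageError(MacromortError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
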