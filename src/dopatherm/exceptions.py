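"""Exception hierarchy.

Every error raised by the package derives from :class:`DopathermError`
so callers can catch pipeline failures with a single except clause.
"""


class DopathermError(Exception):
    """Base class for all package errors."""


class InvalidGridError(DopathermError):
    """Simulation time grid is unusable (e.g. step ≥ duration)."""


class InsufficientDataError(DopathermError):
    """Too few points for the requested estimate."""


class UnidentifiableFitError(DopathermError):
    """The design cannot identify the model parameters (e.g. flat rates)."""


class FitFailureError(DopathermError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDataError(DopathermError):
    """Input is degenerate for the operation (e.g. all-zero signal)."""


class SchemaError(DopathermError):
    """A tabular input violates the expected schema."""


class NotClassifiableError(DopathermError):
    """A docking run lacks the coordinates needed for pose classification."""


class ConfigError(DopathermError):
    """Configuration file invalid: unknown keys or out-of-range values."""


class PipelineStageError(DopathermError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
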