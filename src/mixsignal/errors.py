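"""Exception hierarchy shared across the pipeline stages."""


class MixsignalError(Exception):
    """Base class for all package-specific errors."""


class InvalidScenarioError(MixsignalError, ValueError):
    """A simulation scenario violates its invariants."""


class SchemaError(MixsignalError, ValueError):
    """An input table fails schema or row-level validation."""


class MissingCellError(MixsignalError, KeyError):
    """A requested (emitter, receiver) cell is absent from a fitted model."""


class InvalidPairError(MixsignalError, ValueError):
    """Two directional tests do not describe the same unordered pair."""


class IncompleteDesignError(MixsignalError, ValueError):
    """A layout lacks the monoculture source plots an expected mixture needs."""


class ModelInputError(MixsignalError, ValueError):
    """Model input is structurally unusable (missing levels, aliased terms)."""


class NotConvergedError(MixsignalError, RuntimeError):
    """An optimiser failed to converge; downstream use is refused."""


class StandardizationError(MixsignalError, ValueError):
    """The response has zero variance, so standardized effects are undefined."""


class InvalidIntervalError(MixsignalError, ValueError):
    """A confidence interval has its bounds in the wrong order."""


class PipelineStageError(MixsignalError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
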