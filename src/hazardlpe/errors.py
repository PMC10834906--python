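"""Exception hierarchy used across the package."""


class HazardLpeError(Exception):
    """Base class for all package errors."""


class ParameterError(HazardLpeError, ValueError):
    """Invalid parameter values (e.g. a distribution supported outside [0, 1])."""


class InputError(HazardLpeError, ValueError):
    """Invalid or empty input data."""


class CapacityError(HazardLpeError, ValueError):
    """A session asks for more movies than the stimulus pool holds."""


class SchemaError(HazardLpeError, ValueError):
    """A required column is missing from an input file."""


class MergeError(HazardLpeError, ValueError):
    """Trials and ratings share no movie identifiers."""


class RankError(HazardLpeError, ValueError):
    """Design matrix is rank deficient (e.g. all-constant predictor)."""


class ConvergenceError(HazardLpeError, RuntimeError):
    """A model fit failed to converge."""


class UndefinedThresholdError(HazardLpeError, ValueError):
    """A 50% threshold is undefined because the fitted slope is not positive."""


class ConfigError(HazardLpeError, ValueError):
    """Invalid pipeline configuration."""


class PipelineStageError(HazardLpeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
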