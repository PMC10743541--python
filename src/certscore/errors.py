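"""Exception hierarchy for certscore."""


class CertscoreError(Exception):
    """Base class for all certscore errors."""


class ConfigurationError(CertscoreError):
    """Invalid configuration value (bad correlation matrix, inverted range, ...)."""


class SchemaError(ConfigurationError):
    """Input table does not match the expected cohort schema."""


class DataError(CertscoreError):
    """Invalid data value at run time (non-positive denominator, exit <= entry, ...)."""


class InsufficientDataError(DataError):
    """Too few observations to perform the requested computation."""


class DegeneratePredictorError(DataError):
    """Predictor is constant or otherwise unusable."""


class ConvergenceError(CertscoreError):
    """Model fit failed to converge (e.g. complete separation in logistic regression)."""


class PipelineError(CertscoreError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
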