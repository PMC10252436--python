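"""Exception types shared across the pipeline."""


class OilRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OilRiskError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(OilRiskError, ValueError):
    """Input data violate a contract (negative concentration, empty input, ...)."""


class ZeroExposureError(OilRiskError, ZeroDivisionError):
    """MOE requested for zero exposure: the margin of exposure is undefined,
    not infinite, when no intake of the contaminant occurs."""


class DegenerateScaleError(OilRiskError, ValueError):
    """Min-max normalization requested for an indicator with a single
    distinct value."""


class MissingConsumptionError(OilRiskError, KeyError):
    """A city present in the sampling summaries has no consumption record."""


class StageError(OilRiskError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
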