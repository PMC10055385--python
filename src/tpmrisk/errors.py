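"""Exception hierarchy for the tpmrisk pipeline."""


class TpmriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TpmriskError):
    """A configuration field is missing or out of range."""


class DataError(TpmriskError):
    """Input tables are malformed or incomplete."""


class CohortError(TpmriskError):
    """Cohort construction failed (e.g. control pool too small)."""


class MappingError(TpmriskError):
    """A diagnosis or drug code cannot be mapped to the vocabulary."""


class ConstructionError(TpmriskError):
    """Network architecture cannot be built for the given input shape."""


class TrainingError(TpmriskError):
    """Model training received unusable data."""


class InferenceError(TpmriskError):
    """Prediction inputs do not match the trained model."""


class SplitError(TpmriskError):
    """Data cannot be partitioned as requested."""


class MetricError(TpmriskError):
    """A metric is undefined for the given inputs."""


class FeatureError(TpmriskError):
    """A feature group refers to rows outside the map."""
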