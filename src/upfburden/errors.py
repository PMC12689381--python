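"""Exception types shared across the pipeline."""


class UpfBurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UpfBurdenError, ValueError):
    """Invalid generative or pipeline configuration (e.g. probabilities not summing to 1)."""


class SchemaError(UpfBurdenError, ValueError):
    """Cohort file does not match its declared schema (missing column, unknown level)."""


class ValidationError(UpfBurdenError, ValueError):
    """Invalid data passed to an operation (rating out of range, empty group, ...)."""
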