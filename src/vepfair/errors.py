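"""Exception types shared across the pipeline."""


class VepfairError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VepfairError, ValueError):
    """A spec, calibration table, or pipeline config is invalid.

    Raised at load/validation time, before any computation starts, and the
    message names the offending field.
    """


class DataError(VepfairError, ValueError):
    """Input data violates a contract (AF out of range, malformed row, ...)."""


class DimensionError(DataError):
    """A genotype matrix does not align with its variant subset."""
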