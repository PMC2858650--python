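"""Typed exceptions shared across the package."""


class AepError(Exception):
    """Base class for all package errors."""


class ConfigError(AepError):
    """Invalid configuration value (windows, orders, counts, sessions...)."""


class DesignError(AepError):
    """Analysis design is inconsistent with the data (mixed stimuli,
    contrast not zero-sum, fewer rows than conditions...)."""


class MissingDesignError(DesignError):
    """A balanced design cell is absent; no imputation is attempted."""


class DimensionError(AepError):
    """Array/montage shape mismatch."""


class EmptyAverageError(AepError):
    """All trials were rejected; there is nothing to average."""


class ProvenanceError(AepError):
    """A preprocessing step was applied out of order or twice."""


class IOFormatError(AepError):
    """Container/version/label mismatch while reading or writing files."""
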