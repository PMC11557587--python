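"""Exception hierarchy shared across the pipeline."""


class DeltaPetError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DeltaPetError):
    """Invalid phantom/trace/run configuration."""


class InputError(DeltaPetError):
    """Invalid or empty input data."""


class GenerationError(DeltaPetError):
    """Synthetic data could not be generated under the given constraints."""


class NormalizationError(DeltaPetError):
    """Volume normalization is undefined (zero or negative in-mask mean)."""


class MaskError(DeltaPetError):
    """A region mask object is empty or inconsistent with the grid."""


class PairingError(DeltaPetError):
    """Session records could not be matched one-to-one."""


class FitError(DeltaPetError):
    """A statistical or pattern fit could not be computed."""
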