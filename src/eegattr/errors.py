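"""Exception hierarchy shared across the package."""


class EegAttrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EegAttrError):
    """Invalid configuration: bad layer ordering, unknown method tag, ..."""


class InputError(EegAttrError):
    """Invalid runtime input: shape mismatch, out-of-range patch, ..."""


class CapabilityError(EegAttrError):
    """The model contains a layer the requested operation cannot handle."""


class NumericalError(EegAttrError):
    """A computation produced non-finite values."""


class FormatError(EegAttrError):
    """Malformed on-disk sample/map file or sidecar."""


class PipelineOrderError(EegAttrError):
    """Map-processing steps applied out of their fixed order."""
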