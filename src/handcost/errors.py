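"""Exception hierarchy shared across the package."""


class HandcostError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HandcostError):
    """Invalid configuration: bad distribution parameters, probabilities, sizes."""


class DataError(HandcostError):
    """Malformed input data: bad CSV rows, unknown labels, negative amounts."""


class ConversionLookupError(DataError):
    """FX rate or CPI index missing for a requested year or period."""
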