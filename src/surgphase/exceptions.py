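"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A config value or weight shape is inconsistent with the architecture."""


class DimensionError(ValueError):
    """An array dimension violates a structural precondition."""


class DegenerateInputError(ValueError):
    """An input (e.g. a zero vector) makes the requested quantity undefined."""


class FormatError(ValueError):
    """An on-disk table violates the documented file format."""
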