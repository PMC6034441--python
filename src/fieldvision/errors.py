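"""Exception types shared across the toolkit."""


class FieldVisionError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(FieldVisionError):
    """A run configuration or light geometry is invalid."""


class ImageFormatError(FieldVisionError):
    """An image file could not be read or written in a supported format."""
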