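"""Exception hierarchy shared across the package."""


class FnirsKitError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(FnirsKitError):
    """A required HDR metadata field is missing or malformed."""


class StreamError(FnirsKitError):
    """A required recorded stream is absent or unusable."""


class ConfigurationError(FnirsKitError):
    """An analysis or conversion configuration is invalid."""


class ProcessingError(FnirsKitError):
    """A signal-processing step received input it cannot handle."""
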