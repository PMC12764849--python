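"""Exception hierarchy shared across the package."""


class ArchetrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ArchetrackError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ArchetrackError, ValueError):
    """In-memory data violates a container invariant."""


class ConfigError(ArchetrackError, ValueError):
    """A configuration object is internally inconsistent."""
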