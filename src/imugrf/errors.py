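"""Exception hierarchy shared across the package."""


class ImuGrfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImuGrfError, ValueError):
    """A domain object violates one of its invariants."""


class SchemaError(ValidationError):
    """A file does not conform to the documented schema (names the offender)."""


class FormatError(ValidationError):
    """A file parses but its contents are malformed (e.g. non-monotone time)."""


class IntegrityError(ImuGrfError, RuntimeError):
    """A stored artifact is corrupt or inconsistent with its metadata."""


class ConfigError(ValidationError):
    """A configuration value is out of range or internally inconsistent."""


class LengthError(ValidationError):
    """A sequence is too short (or too long) for the requested operation."""


class AnnotationError(ValidationError):
    """Required annotations (e.g. stance onsets, GRF labels) are missing."""
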