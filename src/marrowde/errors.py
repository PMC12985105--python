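"""Exception hierarchy shared across the pipeline stages."""


class MarrowDEError(Exception):
    """Base class for all package errors."""


class SchemaError(MarrowDEError):
    """A required column or field is missing from an input table."""


class ValidationError(MarrowDEError):
    """An input value violates a declared invariant (e.g. non-binary outcome)."""


class DegenerateContrastError(MarrowDEError):
    """A contrast group has too few subjects to test."""


class ConfigError(MarrowDEError):
    """A simulation or pipeline configuration is internally inconsistent."""


class FormatError(MarrowDEError):
    """A file does not conform to its declared on-disk format."""


class DesignError(MarrowDEError):
    """A model design matrix is singular or otherwise unusable."""
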