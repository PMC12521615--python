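"""Exception hierarchy shared across the package."""


class PepferError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(PepferError):
    """Raised for structurally invalid inputs (bad letters, length mismatches)."""


class FormatError(PepferError):
    """Raised for invalid on-disk file contents; message names the offending line."""


class EmptyTableError(PepferError):
    """Raised when read processing yields no usable reads in a column."""


class ConfigurationError(PepferError):
    """Raised for inconsistent configuration (e.g. table/model misalignment)."""


class NotNormalizedError(PepferError):
    """Raised when an operation requires a gauge-normalized model."""
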