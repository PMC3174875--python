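"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2, everything
else derived from LpsmonoError -> 3.
"""


class LpsmonoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LpsmonoError):
    """Invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class FormatError(LpsmonoError):
    """Malformed input file (missing column, non-numeric cell, ...)."""


class IntegrityError(LpsmonoError):
    """Packaged fixture does not match its recorded checksum."""


class DataError(LpsmonoError):
    """Input data violates a contract (missing purity, empty table, ...)."""


class NamespaceError(LpsmonoError):
    """Gene identifiers from mixed namespaces in one set operation."""


class ModelError(LpsmonoError):
    """Statistical model cannot be fit under the current settings."""
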