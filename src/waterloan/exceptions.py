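"""Exception hierarchy.

``DataError`` covers everything caused by bad input data (unreadable
files, schema mismatches, missing chains); callers that need a process
exit code can map it to a data-error status distinct from usage errors.
"""


class WaterloanError(Exception):
    """Base class for all package errors."""


class DataError(WaterloanError):
    """Input data is malformed, missing, or inconsistent."""


class PDBParseError(DataError):
    """A coordinate file could not be parsed into a usable model."""


class SchemaVersionError(DataError):
    """A reference-database file has an unsupported schema version."""


class ChainNotFoundError(DataError):
    """A requested chain is absent from the structure."""
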