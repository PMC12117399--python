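"""Exception hierarchy.

``SchemaError`` and ``ConfigError`` map to CLI exit code 2 (the user gave us
something malformed); every other :class:`IeivfError` maps to exit code 1.
"""


class IeivfError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(IeivfError):
    """An input file does not conform to the expected tabular layout."""


class RowParseError(SchemaError):
    """A single data row could not be parsed; carries the 1-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class AssemblyMismatchError(SchemaError):
    """Tables annotated against different genome assemblies were co-loaded.

    Only variant tables from the same human genome assembly can be merged
    into one filtering analysis.
    """


class ConfigError(IeivfError):
    """The filter configuration is internally inconsistent."""
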