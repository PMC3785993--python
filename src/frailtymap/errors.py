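"""Exception hierarchy.

Data-integrity problems (bad stacks, unparseable cells, incomparable
pairs) raise subclasses of :class:`FrailtyMapError` so callers — in
particular the CLI — can map them onto distinct exit codes.
"""


class FrailtyMapError(Exception):
    """Base class for all frailtymap errors."""


class SchemaError(FrailtyMapError):
    """A variable name, kind, or category violates the schema."""


class StackIntegrityError(FrailtyMapError):
    """Duplicate instance ids or cross-instance inconsistencies."""


class StackParseError(FrailtyMapError):
    """A stack file cell could not be parsed; names row and column."""

    def __init__(self, message: str, row: object = None, column: str | None = None):
        loc = ""
        if row is not None or column is not None:
            loc = f" (row={row!r}, column={column!r})"
        super().__init__(message + loc)
        self.row = row
        self.column = column


class UnitConversionError(FrailtyMapError):
    """A value's unit cannot be converted to the schema's canonical unit."""


class RecordingFormatError(FrailtyMapError):
    """A gait recording violates the expected format (e.g. non-monotone time)."""


class InsufficientDataError(FrailtyMapError):
    """Too few samples/values to proceed."""


class IncomparablePairError(FrailtyMapError):
    """Two instances share no weighted, mutually present variable."""


class InstanceLookupError(FrailtyMapError):
    """An instance id is not present in the stack."""
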