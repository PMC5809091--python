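"""Exception hierarchy.

Every error raised by the library derives from :class:`GenotabError`, so
callers (and the CLI) can distinguish engine failures from programming
errors. Subclasses mirror the kinds of failure a tabular-genomics pipeline
can hit: malformed file structure, unknown format, a reference to a column
or schema that does not exist, an invalid operation specification, and
export-time constraint violations.
"""


class GenotabError(Exception):
    """Base class for all genotab errors."""


class StructuralError(GenotabError):
    """A file or row grid violates rectangular structure (e.g. ragged rows)."""


class FormatError(GenotabError):
    """Input does not conform to the expected file format."""


class SchemaError(GenotabError):
    """A required column or location schema is absent."""


class SpecificationError(GenotabError):
    """An operation was specified incorrectly (bad key count, empty list...)."""


class ColumnTypeError(GenotabError):
    """An operation needs a numeric column but the column is text-typed."""


class ExportError(GenotabError):
    """A table cannot be rendered in the requested output format."""


class DataError(GenotabError):
    """The data itself makes the requested operation meaningless."""


class ReadError(GenotabError):
    """An input file could not be read."""
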