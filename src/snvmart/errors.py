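"""Exception hierarchy with stable CLI exit codes.

Exit-code families: usage errors are handled by click (2); input-format
errors exit 3; query/selection errors exit 4.
"""


class SnvmartError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputFormatError(SnvmartError):
    """A source file (VCF, panel, BED, rs-list, ancestral table) is malformed."""

    exit_code = 3


class QueryError(SnvmartError):
    """A query cannot be answered (missing mart, bad region, nothing to export)."""

    exit_code = 4


class SelectionError(QueryError):
    """The population/group selection is empty or names unknown codes."""
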