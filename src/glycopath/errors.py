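"""Exception hierarchy for the glycopath toolkit.

Every failure mode surfaced to callers derives from :class:`GlycopathError`
so CLI entry points can catch one type and exit non-zero with a message.
"""

from __future__ import annotations


class GlycopathError(Exception):
    """Base class for all glycopath errors."""


class WurcsParseError(GlycopathError):
    """A WURCS string could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description naming the offending field.
    field:
        Which header field failed: ``"prefix"``, ``"version"``,
        ``"counts"``, or ``"input"``.
    """

    def __init__(self, message: str, field: str = "input") -> None:
        super().__init__(message)
        self.field = field


class InvalidAccessionError(GlycopathError):
    """A GlyTouCan accession did not match the configured pattern."""

    def __init__(self, accession: str) -> None:
        super().__init__(
            f"invalid GlyTouCan accession: {accession!r} "
            "(expected 'G' + 5 digits + 2 uppercase letters)"
        )
        self.accession = accession


class UnknownClassError(GlycopathError):
    """An instance IRI was requested for a class outside the model."""


class SerialOverflowError(GlycopathError):
    """A serial number exceeded the 5-digit instance IRI scheme."""


class ChainError(GlycopathError):
    """Consecutive pathway steps do not share product/acceptor glycans."""


class StepIndexError(GlycopathError):
    """Step indices are duplicated or leave gaps."""


class ConfigurationError(GlycopathError):
    """A vocabulary or prefix required by the run is missing."""


class TableError(GlycopathError):
    """Base class for instance-table errors."""


class DuplicateSubjectError(TableError):
    """Two rows of an instance table share a subject identifier."""


class TableArityError(TableError):
    """A data row's cell count disagrees with the header row."""


class EmptyTableError(TableError):
    """The table source contains no header row."""


class TurtleParseError(GlycopathError):
    """Turtle input could not be parsed.

    Carries the 1-based line number where the syntax error (or unknown
    prefix) was detected, when the underlying parser reports one.
    """

    def __init__(self, message: str, line: int | None = None) -> None:
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class PrefixConflictError(GlycopathError):
    """Two graphs bind the same prefix to different namespaces."""

    def __init__(self, prefix: str, first: str, second: str) -> None:
        super().__init__(
            f"conflicting bindings for prefix {prefix!r}: {first} vs {second}"
        )
        self.prefix = prefix


class QueryError(GlycopathError):
    """A query specification is malformed (e.g. unbound projection)."""


class ArityError(GlycopathError):
    """A reaction's participant arity violates the model shape."""


class UnknownRuleError(GlycopathError):
    """A validation rule id is not registered."""


class MutationError(GlycopathError):
    """A requested fixture mutation cannot be applied."""
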