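"""Spreadsheet-style instance tables and their RDFization.

The table convention mirrors how a bench scientist arranges pathway
data for conversion to RDF: one CSV file per class, subjects of that
class in the leftmost column, property names (CURIEs or absolute IRIs)
in the header row, and object values in the cells.  A cell may hold
several values separated by ``|`` (configurable); the separator can be
escaped with a backslash inside a value so round-trips are exact.

RDFization of a table emits one ``rdf:type`` statement per row plus one
statement per cell value.  A cell value becomes a resource when it is
an absolute IRI, a CURIE under a declared prefix, or a bare GlyTouCan
accession (resolved to the repository IRI); anything else is a plain
literal.  Properties whose objects are always literals even when they
look like identifiers (BioPAX ``bp:id`` being the canonical case) can
be listed in ``literal_properties``.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .errors import (
    ConfigurationError,
    DuplicateSubjectError,
    EmptyTableError,
    TableArityError,
)
from .model_builder import ACCESSION_RE, VocabularyMap, glytoucan_iri
from .rdf_graph import Literal, RDF_TYPE, TripleGraph

__all__ = [
    "InstanceTable",
    "TableRow",
    "read_instance_table",
    "write_instance_table",
    "table_to_triples",
    "DEFAULT_SEPARATOR",
    "DEFAULT_LITERAL_PROPERTIES",
]

DEFAULT_SEPARATOR = "|"
# bp:id objects are literal identifiers by definition; without this, an
# accession in an xref id cell would be promoted to a glycan IRI.
DEFAULT_LITERAL_PROPERTIES = frozenset({"bp:id"})

_ABSOLUTE_IRI_RE = re.compile(r"[a-zA-Z][a-zA-Z0-9+.\-]*://\S+$")


@dataclass
class TableRow:
    subject_id: str
    values: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class InstanceTable:
    """All instances of one class, with their property values."""

    class_name: str
    property_names: list[str]
    rows: list[TableRow] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.subject_id in seen:
                raise DuplicateSubjectError(
                    f"duplicate subject {row.subject_id!r} in table "
                    f"{self.class_name!r}"
                )
            seen.add(row.subject_id)
            for key in row.values:
                if key not in self.property_names:
                    raise TableArityError(
                        f"value for undeclared property {key!r} on subject "
                        f"{row.subject_id!r}"
                    )


def _split_cell(cell: str, separator: str) -> list[str]:
    """Split a multi-value cell on unescaped separators and unescape."""
    values: list[str] = []
    current: list[str] = []
    i = 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell) and cell[i + 1] in ("\\", separator):
            current.append(cell[i + 1])
            i += 2
            continue
        if ch == separator:
            values.append("".join(current))
            current = []
        else:
            current.append(ch)
        i += 1
    values.append("".join(current))
    return values


def _join_cell(values: list[str], separator: str) -> str:
    escaped = [
        v.replace("\\", "\\\\").replace(separator, "\\" + separator) for v in values
    ]
    return separator.join(escaped)


def read_instance_table(
    source: TextIO | str,
    class_name: str,
    *,
    separator: str = DEFAULT_SEPARATOR,
) -> InstanceTable:
    """Read one class table from a CSV stream (or CSV text).

    The first row is the header; its first cell names the subject
    column and the remaining cells are property names.  Empty cells
    contribute no value (not an empty string).
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise EmptyTableError(f"table {class_name!r} has no header row") from None
    if not header:
        raise EmptyTableError(f"table {class_name!r} has an empty header row")
    property_names = header[1:]
    table = InstanceTable(class_name=class_name, property_names=list(property_names))
    seen: set[str] = set()
    for line_no, raw in enumerate(reader, start=2):
        if not raw:
            continue
        if len(raw) != len(header):
            raise TableArityError(
                f"table {class_name!r} line {line_no}: {len(raw)} cells "
                f"but header declares {len(header)}"
            )
        subject = raw[0]
        if subject in seen:
            raise DuplicateSubjectError(
                f"table {class_name!r} line {line_no}: duplicate subject "
                f"{subject!r}"
            )
        seen.add(subject)
        values: dict[str, list[str]] = {}
        for prop, cell in zip(property_names, raw[1:]):
            if cell == "":
                continue
            values[prop] = _split_cell(cell, separator)
        table.rows.append(TableRow(subject_id=subject, values=values))
    return table


def write_instance_table(
    table: InstanceTable,
    sink: TextIO,
    *,
    subject_column: str = "subject",
    separator: str = DEFAULT_SEPARATOR,
) -> None:
    """Write a table as RFC 4180 CSV; inverse of :func:`read_instance_table`."""
    table.validate()
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow([subject_column, *table.property_names])
    for row in table.rows:
        cells = [row.subject_id]
        for prop in table.property_names:
            values = row.values.get(prop)
            cells.append(_join_cell(values, separator) if values else "")
        writer.writerow(cells)


def _resolve_term(term: str, vocab: VocabularyMap, base_namespace: str) -> str:
    """Resolve a subject/predicate token to an absolute IRI."""
    if _ABSOLUTE_IRI_RE.fullmatch(term):
        return term
    if ":" in term:
        return vocab.expand_curie(term)
    return base_namespace + term


def _cell_to_node(
    value: str,
    vocab: VocabularyMap,
    *,
    force_literal: bool,
) -> str | Literal:
    if force_literal:
        return Literal(value)
    if _ABSOLUTE_IRI_RE.fullmatch(value):
        return value
    if ACCESSION_RE.fullmatch(value):
        return glytoucan_iri(value)
    prefix, sep, local = value.partition(":")
    if sep and " " not in value and prefix in vocab.prefix_to_namespace:
        return vocab.prefix_to_namespace[prefix] + local
    return Literal(value)


def table_to_triples(
    table: InstanceTable,
    vocab: VocabularyMap | None = None,
    base_namespace: str | None = None,
    *,
    literal_properties: Iterable[str] = DEFAULT_LITERAL_PROPERTIES,
) -> TripleGraph:
    """RDFize one instance table.

    Per row: one ``rdf:type`` statement assigning the table's class,
    plus one statement per cell value.  The triple count is therefore
    exactly ``rows + sum of cell value multiplicities``.
    """
    vocab = vocab or VocabularyMap.default()
    base = base_namespace or vocab.prefix_to_namespace.get("", "")
    if not base:
        raise ConfigurationError("a base namespace is required to resolve local ids")
    table.validate()

    if table.class_name in vocab.class_iris:
        class_iri = vocab.class_iris[table.class_name]
    else:
        class_iri = _resolve_term(table.class_name, vocab, base)
    forced = frozenset(literal_properties)

    g = TripleGraph(prefixes=vocab.prefix_to_namespace)
    for row in table.rows:
        subject = _resolve_term(row.subject_id, vocab, base)
        g.add(subject, RDF_TYPE, class_iri)
        for prop in table.property_names:
            values = row.values.get(prop)
            if not values:
                continue
            predicate = _resolve_term(prop, vocab, base)
            force_literal = prop in forced
            for value in values:
                if predicate == RDF_TYPE:
                    node: str | Literal = _resolve_term(value, vocab, base)
                else:
                    node = _cell_to_node(value, vocab, force_literal=force_literal)
                g.add(subject, predicate, node)
    return g
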