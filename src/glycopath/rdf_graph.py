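"""Triple-graph container and deterministic Turtle serialization.

The exchange structure of the whole toolkit is :class:`TripleGraph`: a
set of (subject, predicate, object) statements plus a prefix map.  The
Turtle writer is deliberately deterministic — prefixes, subjects,
predicates and objects are emitted in sorted order, with ``rdf:type``
first and abbreviated as ``a`` — so that two runs over the same input
produce byte-identical documents and diffs stay meaningful.

Parsing reuses rdflib's Turtle parser and converts the result back into
a :class:`TripleGraph`; only the subset this package emits is supported
(no blank nodes, collections or numeric shorthand — the pathway model
uses none of them).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

import rdflib
from rdflib.plugins.parsers.notation3 import BadSyntax

from .errors import PrefixConflictError, TurtleParseError

__all__ = [
    "Literal",
    "Statement",
    "TripleGraph",
    "RDF_TYPE",
    "serialize_turtle",
    "parse_turtle",
    "serialize_ntriples",
    "merge",
]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDF_TYPE = RDF_NS + "type"
_XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"

# PN_LOCAL subset safe for unescaped prefixed names: the instance ids this
# package mints ("GC-Pathway-00301"), ontology terms and accessions all fit.
_LOCAL_RE = re.compile(r"(?:[A-Za-z0-9_](?:[A-Za-z0-9_.\-]*[A-Za-z0-9_\-])?)?$")


@dataclass(frozen=True)
class Literal:
    """An RDF literal: lexical form plus optional datatype or language tag.

    A datatype of ``xsd:string`` is normalized to ``None`` (RDF 1.1 makes
    the two indistinguishable), which keeps Turtle round-trips exact.
    """

    lexical_form: str
    datatype: str | None = None
    language_tag: str | None = None

    def __post_init__(self) -> None:
        if self.datatype is not None and self.language_tag is not None:
            raise ValueError("a literal cannot carry both a datatype and a language tag")
        if self.datatype == _XSD_STRING:
            object.__setattr__(self, "datatype", None)


Node = Union[str, Literal]  # str = absolute IRI


@dataclass(frozen=True)
class Statement:
    """A single RDF statement; subject and predicate are absolute IRIs."""

    subject: str
    predicate: str
    object: Node


class TripleGraph:
    """A set of statements with a prefix map.

    Statement storage has set semantics: adding a duplicate is a no-op.
    Equality between graphs compares the statement sets only; the prefix
    map is presentation metadata and does not affect identity.
    """

    def __init__(
        self,
        statements: Iterable[Statement] = (),
        prefixes: dict[str, str] | None = None,
    ) -> None:
        self._statements: set[Statement] = set()
        self._by_subject: dict[str, dict[str, list[Node]]] = {}
        self.prefixes: dict[str, str] = dict(prefixes or {})
        for st in statements:
            self.add_statement(st)

    # -- collection protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._statements)

    def __iter__(self) -> Iterator[Statement]:
        return iter(self._statements)

    def __contains__(self, statement: Statement) -> bool:
        return statement in self._statements

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripleGraph):
            return NotImplemented
        return self._statements == other._statements

    def __hash__(self):  # graphs are mutable
        raise TypeError("TripleGraph is unhashable")

    @property
    def statements(self) -> frozenset[Statement]:
        return frozenset(self._statements)

    # -- mutation ------------------------------------------------------------
    def add(self, subject: str, predicate: str, obj: Node) -> None:
        self.add_statement(Statement(subject, predicate, obj))

    def add_statement(self, statement: Statement) -> None:
        if statement in self._statements:
            return
        self._statements.add(statement)
        self._by_subject.setdefault(statement.subject, {}).setdefault(
            statement.predicate, []
        ).append(statement.object)

    def discard(self, statement: Statement) -> None:
        if statement not in self._statements:
            return
        self._statements.discard(statement)
        preds = self._by_subject[statement.subject]
        preds[statement.predicate].remove(statement.object)
        if not preds[statement.predicate]:
            del preds[statement.predicate]
        if not preds:
            del self._by_subject[statement.subject]

    def bind(self, prefix: str, namespace: str) -> None:
        existing = self.prefixes.get(prefix)
        if existing is not None and existing != namespace:
            raise PrefixConflictError(prefix, existing, namespace)
        self.prefixes[prefix] = namespace

    # -- queries used throughout the package ---------------------------------
    def objects(self, subject: str, predicate: str) -> list[Node]:
        """All objects of statements with this subject and predicate, sorted."""
        found = self._by_subject.get(subject, {}).get(predicate, [])
        return sorted(found, key=_node_sort_key)

    def subjects(self, predicate: str | None = None, obj: Node | None = None) -> list[str]:
        """Distinct subjects, optionally restricted by predicate/object, sorted."""
        if predicate is None and obj is None:
            return sorted(self._by_subject)
        found = {
            s.subject
            for s in self._statements
            if (predicate is None or s.predicate == predicate)
            and (obj is None or s.object == obj)
        }
        return sorted(found)

    def subjects_of_type(self, class_iri: str) -> list[str]:
        return self.subjects(RDF_TYPE, class_iri)

    def types_of(self, subject: str) -> set[str]:
        return {
            o
            for o in self._by_subject.get(subject, {}).get(RDF_TYPE, [])
            if isinstance(o, str)
        }


def _node_sort_key(node: Node) -> tuple:
    if isinstance(node, Literal):
        return (1, node.lexical_form, node.datatype or "", node.language_tag or "")
    return (0, node)


# ---------------------------------------------------------------------------
# Turtle writer
# ---------------------------------------------------------------------------

def _compact(iri: str, prefixes: dict[str, str]) -> str:
    """Compact an IRI to a prefixed name where possible, else ``<iri>``.

    The longest declared namespace that prefixes the IRI wins; the local
    part must stay within the unescaped PN_LOCAL subset this writer emits.
    """
    best: tuple[str, str] | None = None
    for prefix, ns in prefixes.items():
        if ns and iri.startswith(ns) and (best is None or len(ns) > len(best[1])):
            best = (prefix, ns)
    if best is not None:
        local = iri[len(best[1]):]
        if _LOCAL_RE.fullmatch(local):
            return f"{best[0]}:{local}"
    return f"<{iri}>"


_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _quote(text: str) -> str:
    return '"' + "".join(_ESCAPES.get(ch, ch) for ch in text) + '"'


def _render_object(node: Node, prefixes: dict[str, str]) -> str:
    if isinstance(node, Literal):
        rendered = _quote(node.lexical_form)
        if node.language_tag:
            rendered += f"@{node.language_tag}"
        elif node.datatype:
            rendered += f"^^{_compact(node.datatype, prefixes)}"
        return rendered
    return _compact(node, prefixes)


def serialize_turtle(graph: TripleGraph) -> str:
    """Serialize a graph to Turtle, deterministically.

    Ordering contract: prefix declarations sorted by prefix; subjects
    sorted by IRI; per subject, ``rdf:type`` first (written ``a``), then
    the remaining predicates sorted by IRI; objects sorted with IRIs
    before literals.  Statements sharing a subject are grouped with
    ``;`` and multi-object predicates with ``,``.  The output parses
    back to an equal statement set.
    """
    prefixes = dict(graph.prefixes)
    lines = [
        f"@prefix {prefix}: <{ns}> ."
        for prefix, ns in sorted(prefixes.items())
    ]
    by_subject: dict[str, dict[str, list[Node]]] = {}
    for st in graph:
        by_subject.setdefault(st.subject, {}).setdefault(st.predicate, []).append(
            st.object
        )
    if lines and by_subject:
        lines.append("")
    for subject in sorted(by_subject):
        preds = by_subject[subject]
        ordered = sorted(preds, key=lambda p: (p != RDF_TYPE, p))
        blocks = []
        for predicate in ordered:
            token = "a" if predicate == RDF_TYPE else _compact(predicate, prefixes)
            objects = sorted(preds[predicate], key=_node_sort_key)
            rendered = ", ".join(_render_object(o, prefixes) for o in objects)
            blocks.append(f"{token} {rendered}")
        subject_token = _compact(subject, prefixes)
        lines.append(f"{subject_token} " + " ;\n    ".join(blocks) + " .")
    return "\n".join(lines) + ("\n" if lines else "")


def serialize_ntriples(graph: TripleGraph) -> str:
    """Serialize to N-Triples (sorted lines) for triple-store bulk loads.

    Byte-exact stability across library versions is not promised for
    this secondary writer; the Turtle writer is the canonical output.
    """
    rendered = []
    for st in graph:
        obj = st.object
        if isinstance(obj, Literal):
            token = _quote(obj.lexical_form)
            if obj.language_tag:
                token += f"@{obj.language_tag}"
            elif obj.datatype:
                token += f"^^<{obj.datatype}>"
        else:
            token = f"<{obj}>"
        rendered.append(f"<{st.subject}> <{st.predicate}> {token} .")
    return "\n".join(sorted(rendered)) + ("\n" if rendered else "")


# ---------------------------------------------------------------------------
# Turtle reader (rdflib-backed)
# ---------------------------------------------------------------------------

def parse_turtle(text: str) -> TripleGraph:
    """Parse Turtle text into a :class:`TripleGraph`.

    Only the subset this package emits is supported; in particular a
    document containing blank nodes is rejected.  Syntax errors (which
    include references to undeclared prefixes) raise
    :class:`TurtleParseError` carrying a line number.
    """
    rg = rdflib.Graph()
    try:
        rg.parse(data=text, format="turtle")
    except BadSyntax as exc:
        line = getattr(exc, "lines", None)
        line = line + 1 if isinstance(line, int) else None
        raise TurtleParseError(getattr(exc, "_why", str(exc)), line=line) from exc
    graph = TripleGraph()
    for prefix, ns in rg.namespaces():
        graph.prefixes[str(prefix)] = str(ns)
    for s, p, o in rg:
        if isinstance(s, rdflib.BNode) or isinstance(o, rdflib.BNode):
            raise TurtleParseError("blank nodes are outside the supported subset")
        if isinstance(o, rdflib.Literal):
            obj: Node = Literal(
                lexical_form=str(o),
                datatype=str(o.datatype) if o.datatype else None,
                language_tag=o.language or None,
            )
        else:
            obj = str(o)
        graph.add(str(s), str(p), obj)
    return graph


def merge(graphs: list[TripleGraph]) -> TripleGraph:
    """Union of statement sets and prefix maps.

    Raises
    ------
    PrefixConflictError
        If two inputs bind the same prefix to different namespaces.
    """
    merged = TripleGraph()
    for g in graphs:
        for prefix, ns in g.prefixes.items():
            merged.bind(prefix, ns)
        for st in g:
            merged.add_statement(st)
    return merged


def to_rdflib(graph: TripleGraph) -> rdflib.Graph:
    """Convert to an rdflib Graph (used for SPARQL cross-checks)."""
    rg = rdflib.Graph()
    for prefix, ns in graph.prefixes.items():
        rg.bind(prefix, rdflib.Namespace(ns), replace=True)
    for st in graph:
        obj = st.object
        if isinstance(obj, Literal):
            node = rdflib.Literal(
                obj.lexical_form, datatype=obj.datatype, lang=obj.language_tag
            )
        else:
            node = rdflib.URIRef(obj)
        rg.add((rdflib.URIRef(st.subject), rdflib.URIRef(st.predicate), node))
    return rg
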