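"""Basic-graph-pattern evaluation and the canned verification queries.

The verification workflow for an RDFized pathway dataset asks four
questions: how many O-antigens are there, what are they called, is each
reaction composed of a donor / acceptor / product with the expected
one-residue deficit, and which glycans and glycosyltransferases make up
a named pathway.  Those are exposed here as :func:`q1_count_antigens`,
:func:`q2_antigen_names`, :func:`q3_reaction_components` and
:func:`q4_pathway_members` on top of a small query evaluator
(:func:`evaluate`) that supports conjunctive triple patterns with
``equals``/``regex`` filters, DISTINCT, projection and COUNT — the
SPARQL subset the verification queries need.

Variables are written ``?name``.  Regular expressions use Python's
:mod:`re` dialect (``re.search`` semantics, as SPARQL's ``regex``).
Result rows are always sorted, so query output is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Union

from .errors import ArityError, QueryError
from .model_builder import VocabularyMap
from .rdf_graph import Literal, RDF_TYPE, TripleGraph

__all__ = [
    "TriplePattern",
    "Filter",
    "QuerySpec",
    "BindingTable",
    "evaluate",
    "q1_count_antigens",
    "q2_antigen_names",
    "q3_reaction_components",
    "q4_pathway_members",
    "ReactionComponents",
]

Term = Union[str, Literal]  # "?x" marks a variable in the str case


def is_variable(term: Term) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass(frozen=True)
class TriplePattern:
    subject: Term
    predicate: Term
    object: Term

    def variables(self) -> set[str]:
        return {t for t in (self.subject, self.predicate, self.object) if is_variable(t)}


@dataclass(frozen=True)
class Filter:
    variable: str
    operator: str  # "equals" | "regex"
    operand: str

    def __post_init__(self) -> None:
        if self.operator not in ("equals", "regex"):
            raise QueryError(f"unknown filter operator {self.operator!r}")


@dataclass(frozen=True)
class QuerySpec:
    patterns: tuple[TriplePattern, ...]
    filters: tuple[Filter, ...] = ()
    projection: tuple[str, ...] = ()
    distinct: bool = False
    count: bool = False


@dataclass
class BindingTable:
    """Query result: variable names plus sorted rows of bound values."""

    variables: list[str]
    rows: list[tuple[Term, ...]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self) -> str:
        def render(value: Term) -> str:
            return value.lexical_form if isinstance(value, Literal) else str(value)

        lines = ["\t".join(self.variables)]
        lines.extend("\t".join(render(v) for v in row) for row in self.rows)
        return "\n".join(lines)


def _render_key(value: Term) -> tuple:
    if isinstance(value, Literal):
        return (1, value.lexical_form, value.datatype or "", value.language_tag or "")
    return (0, str(value), "", "")


def _match(pattern: TriplePattern, statement, binding: dict[str, Term]):
    """Extend a binding with one statement, or None on mismatch."""
    extended = dict(binding)
    for term, actual in (
        (pattern.subject, statement.subject),
        (pattern.predicate, statement.predicate),
        (pattern.object, statement.object),
    ):
        if is_variable(term):
            bound = extended.get(term)
            if bound is None:
                extended[term] = actual
            elif bound != actual:
                return None
        elif term != actual:
            return None
    return extended


def _filter_value(value: Term) -> str:
    return value.lexical_form if isinstance(value, Literal) else str(value)


def evaluate(graph: TripleGraph, query: QuerySpec) -> BindingTable:
    """Evaluate a conjunctive query as the natural join of its patterns.

    Filters are applied after the join; projection, DISTINCT and COUNT
    after filtering.  Rows are sorted by their rendered values, so the
    result is a pure function of the graph.

    Raises
    ------
    QueryError
        If a projected or filtered variable is bound by no pattern, or
        a regex operand fails to compile.
    """
    pattern_vars: set[str] = set()
    for p in query.patterns:
        pattern_vars |= p.variables()
    for name in query.projection:
        if name not in pattern_vars:
            raise QueryError(f"projected variable {name} appears in no pattern")
    for flt in query.filters:
        if flt.variable not in pattern_vars:
            raise QueryError(f"filtered variable {flt.variable} appears in no pattern")

    compiled: list[tuple[Filter, re.Pattern | None]] = []
    for flt in query.filters:
        if flt.operator == "regex":
            try:
                compiled.append((flt, re.compile(flt.operand)))
            except re.error as exc:
                raise QueryError(f"invalid regex {flt.operand!r}: {exc}") from exc
        else:
            compiled.append((flt, None))

    bindings: list[dict[str, Term]] = [{}]
    for pattern in query.patterns:
        extended: list[dict[str, Term]] = []
        for binding in bindings:
            for statement in graph:
                result = _match(pattern, statement, binding)
                if result is not None:
                    extended.append(result)
        bindings = extended
        if not bindings:
            break

    kept = []
    for binding in bindings:
        ok = True
        for flt, regex in compiled:
            value = _filter_value(binding[flt.variable])
            if flt.operator == "equals":
                ok = value == flt.operand
            else:
                ok = regex.search(value) is not None
            if not ok:
                break
        if ok:
            kept.append(binding)

    projection = list(query.projection) or sorted(pattern_vars)
    rows = [tuple(b[name] for name in projection) for b in kept]
    if query.distinct:
        rows = list(set(rows))
    rows.sort(key=lambda row: tuple(_render_key(v) for v in row))
    if query.count:
        return BindingTable(variables=["count"], rows=[(Literal(str(len(rows))),)])
    return BindingTable(variables=projection, rows=rows)


# ---------------------------------------------------------------------------
# Canned verification queries
# ---------------------------------------------------------------------------

def q1_count_antigens(graph: TripleGraph, vocab: VocabularyMap | None = None) -> int:
    """Number of distinct O-antigens: instances typed ``bp:Pathway``."""
    vocab = vocab or VocabularyMap.default()
    return len(graph.subjects_of_type(vocab.class_iri("Pathway")))


def q2_antigen_names(graph: TripleGraph, vocab: VocabularyMap | None = None) -> BindingTable:
    """One row per pathway with its display name.

    A pathway without a name still contributes a row (empty name), so
    the row count always equals :func:`q1_count_antigens`.
    """
    vocab = vocab or VocabularyMap.default()
    name_prop = vocab.prop("displayName")
    rows: list[tuple[Term, ...]] = []
    for pathway in graph.subjects_of_type(vocab.class_iri("Pathway")):
        names = [o for o in graph.objects(pathway, name_prop) if isinstance(o, Literal)]
        rows.append((pathway, names[0] if names else Literal("")))
    rows.sort(key=lambda row: tuple(_render_key(v) for v in row))
    return BindingTable(variables=["?antigen", "?name"], rows=rows)


@dataclass(frozen=True)
class ReactionComponents:
    acceptor: str
    donor: str
    product: str


def q3_reaction_components(
    graph: TripleGraph,
    reaction_iri: str,
    vocab: VocabularyMap | None = None,
) -> ReactionComponents:
    """The donor / acceptor / product of one biochemical reaction.

    The donor is the ``bp:left`` participant typed as a sugar
    nucleotide; the other ``bp:left`` is the acceptor; the single
    ``bp:right`` is the product.

    Raises
    ------
    ArityError
        If the reaction's participant counts or typing do not fit that
        shape (mirrors validator rule R2).
    """
    vocab = vocab or VocabularyMap.default()
    if vocab.class_iri("BiochemicalReaction") not in graph.types_of(reaction_iri):
        raise ArityError(f"{reaction_iri} is not typed BiochemicalReaction")
    lefts = [o for o in graph.objects(reaction_iri, vocab.prop("left")) if isinstance(o, str)]
    rights = [o for o in graph.objects(reaction_iri, vocab.prop("right")) if isinstance(o, str)]
    if len(lefts) != 2 or len(rights) != 1:
        raise ArityError(
            f"{reaction_iri}: expected 2 bp:left and 1 bp:right, "
            f"found {len(lefts)} and {len(rights)}"
        )
    sn_iri = vocab.class_iri("SugarNucleotide")
    donors = [o for o in lefts if sn_iri in graph.types_of(o)]
    if len(donors) != 1:
        raise ArityError(
            f"{reaction_iri}: expected exactly 1 sugar-nucleotide left "
            f"participant, found {len(donors)}"
        )
    acceptor = next(o for o in lefts if o != donors[0])
    return ReactionComponents(acceptor=acceptor, donor=donors[0], product=rights[0])


def q4_pathway_members(
    graph: TripleGraph,
    name_regex: str,
    vocab: VocabularyMap | None = None,
) -> BindingTable:
    """Glycans and glycosyltransferases of pathways whose name matches.

    For each matching pathway, follows ``bp:pathwayOrder`` to its steps,
    each step's ``bp:stepConversion`` to the reaction, takes the
    reaction product (``bp:right``) as the glycan, and resolves the
    enzyme through the ``bp:Catalysis`` controlling the reaction.
    Returns distinct sorted (glycan, enzyme) rows; donors are available
    per reaction through :func:`q3_reaction_components`.
    """
    vocab = vocab or VocabularyMap.default()
    try:
        regex = re.compile(name_regex)
    except re.error as exc:
        raise QueryError(f"invalid regex {name_regex!r}: {exc}") from exc

    name_prop = vocab.prop("displayName")
    rows: set[tuple[Term, ...]] = set()
    for pathway in graph.subjects_of_type(vocab.class_iri("Pathway")):
        names = [o for o in graph.objects(pathway, name_prop) if isinstance(o, Literal)]
        if not any(regex.search(n.lexical_form) for n in names):
            continue
        for step in graph.objects(pathway, vocab.prop("pathwayOrder")):
            if not isinstance(step, str):
                continue
            for reaction in graph.objects(step, vocab.prop("stepConversion")):
                if not isinstance(reaction, str):
                    continue
                products = [
                    o for o in graph.objects(reaction, vocab.prop("right"))
                    if isinstance(o, str)
                ]
                enzymes = [
                    enzyme
                    for catalysis in graph.subjects(vocab.prop("controlled"), reaction)
                    for enzyme in graph.objects(catalysis, vocab.prop("controller"))
                    if isinstance(enzyme, str)
                ]
                for product in products:
                    for enzyme in enzymes:
                        rows.add((product, enzyme))
    ordered = sorted(rows, key=lambda row: tuple(_render_key(v) for v in row))
    return BindingTable(variables=["?glycan", "?glycosyltransferase"], rows=ordered)
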