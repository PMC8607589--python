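"""Structural validation of O-antigen pathway graphs.

The pathway model makes strong structural promises — every reaction is
a single-residue extension, every catalysis names its enzyme, step
order forms a simple chain — and this module turns each promise into a
named, individually toggleable rule over a :class:`TripleGraph`:

=====  ======================================================================
R1     single extension: product WURCS residue count = acceptor's + 1
R2     reaction arity: two ``bp:left`` (one sugar nucleotide, one
       saccharide) and exactly one ``bp:right``
R3     catalysis shape: exactly one ``bp:controlled`` reaction, at least
       one ``bp:controller``
R4     step chain: ``bp:nextStep`` forms a single simple path over a
       pathway's steps (no cycles, no branching)
R5     dual typing: acceptor/product glycans are both Saccharide and
       SmallMolecule
R6     xref presence: every glycan has a ``bp:xref`` to a UnificationXref
       whose id matches the GlyTouCan accession pattern
R7     typed subjects: every subject carries at least one ``rdf:type``
=====  ======================================================================

Validation never fails fast: all violations are collected into a
:class:`ValidationReport`.  R1 needs WURCS strings; they are looked up
in a caller-supplied index (or harvested from the graph's WURCS
literals), and glycans missing from the index downgrade R1 to a warning
for those nodes rather than failing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import UnknownRuleError, WurcsParseError
from .model_builder import ACCESSION_RE, VocabularyMap
from .rdf_graph import Literal, RDF_TYPE, TripleGraph
from .wurcs import residue_count

__all__ = [
    "ValidationRule",
    "Violation",
    "ValidationReport",
    "RULES",
    "validate_graph",
    "check_rule",
    "build_wurcs_index",
]


@dataclass(frozen=True)
class ValidationRule:
    rule_id: str
    description: str
    severity: str = "error"


@dataclass(frozen=True)
class Violation:
    rule_id: str
    subject: str
    message: str
    severity: str = "error"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    checked_statement_count: int = 0

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    @property
    def ok(self) -> bool:
        """True iff the graph conforms (no error-level violations)."""
        return not self.errors

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps(
                {
                    "rule_id": v.rule_id,
                    "subject": v.subject,
                    "severity": v.severity,
                    "message": v.message,
                }
            )
            for v in self.violations
        )

    def summary(self) -> str:
        lines = [
            f"checked {self.checked_statement_count} statements: "
            f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"
        ]
        for v in self.violations:
            lines.append(f"  [{v.severity}] {v.rule_id} {v.subject}: {v.message}")
        return "\n".join(lines)


RULES: dict[str, ValidationRule] = {
    rule.rule_id: rule
    for rule in (
        ValidationRule("R1", "product residue count exceeds acceptor's by exactly 1"),
        ValidationRule("R2", "reaction has two left participants (donor + acceptor) and one right"),
        ValidationRule("R3", "catalysis has one controlled reaction and a controller"),
        ValidationRule("R4", "nextStep links form a single simple path per pathway"),
        ValidationRule("R5", "acceptor/product glycans typed Saccharide and SmallMolecule"),
        ValidationRule("R6", "every glycan has a UnificationXref with a valid accession"),
        ValidationRule("R7", "every subject has at least one rdf:type"),
    )
}


def build_wurcs_index(graph: TripleGraph, vocab: VocabularyMap | None = None) -> dict[str, str]:
    """Harvest WURCS literals attached to glycan nodes in the graph."""
    vocab = vocab or VocabularyMap.default()
    pred = vocab.prop("has_wurcs")
    index: dict[str, str] = {}
    for st in graph:
        if st.predicate == pred and isinstance(st.object, Literal):
            index[st.subject] = st.object.lexical_form
    return index


def _classify_reaction(graph: TripleGraph, reaction: str, vocab: VocabularyMap):
    """Identify (donor, acceptor, product) of a reaction, or None if R2 fails."""
    lefts = [o for o in graph.objects(reaction, vocab.prop("left")) if isinstance(o, str)]
    rights = [o for o in graph.objects(reaction, vocab.prop("right")) if isinstance(o, str)]
    if len(lefts) != 2 or len(rights) != 1:
        return None
    sn_iri = vocab.class_iri("SugarNucleotide")
    donors = [o for o in lefts if sn_iri in graph.types_of(o)]
    if len(donors) != 1:
        return None
    acceptor = next(o for o in lefts if o != donors[0])
    sac_iri = vocab.class_iri("Saccharide")
    if sac_iri not in graph.types_of(acceptor):
        return None
    return donors[0], acceptor, rights[0]


def _check_r1(graph, vocab, wurcs_index):
    violations = []
    for reaction in graph.subjects_of_type(vocab.class_iri("BiochemicalReaction")):
        parts = _classify_reaction(graph, reaction, vocab)
        if parts is None:
            continue  # R2 reports malformed participant sets
        _, acceptor, product = parts
        missing = [g for g in (acceptor, product) if g not in wurcs_index]
        if missing:
            violations.append(
                Violation(
                    "R1",
                    reaction,
                    f"no WURCS available for {', '.join(missing)}; "
                    "single-extension rule not checkable",
                    severity="warning",
                )
            )
            continue
        try:
            delta = residue_count(wurcs_index[product]) - residue_count(
                wurcs_index[acceptor]
            )
        except WurcsParseError as exc:
            violations.append(Violation("R1", reaction, f"unparseable WURCS: {exc}"))
            continue
        if delta != 1:
            violations.append(
                Violation(
                    "R1",
                    reaction,
                    f"product residue count differs from acceptor's by {delta}, "
                    "expected +1",
                )
            )
    return violations


def _check_r2(graph, vocab, wurcs_index):
    violations = []
    sn_iri = vocab.class_iri("SugarNucleotide")
    sac_iri = vocab.class_iri("Saccharide")
    for reaction in graph.subjects_of_type(vocab.class_iri("BiochemicalReaction")):
        lefts = [o for o in graph.objects(reaction, vocab.prop("left")) if isinstance(o, str)]
        rights = graph.objects(reaction, vocab.prop("right"))
        if len(lefts) != 2:
            violations.append(
                Violation("R2", reaction, f"expected 2 bp:left participants, found {len(lefts)}")
            )
            continue
        if len(rights) != 1:
            violations.append(
                Violation("R2", reaction, f"expected 1 bp:right participant, found {len(rights)}")
            )
            continue
        n_donors = sum(1 for o in lefts if sn_iri in graph.types_of(o))
        if n_donors != 1:
            violations.append(
                Violation(
                    "R2",
                    reaction,
                    f"expected exactly 1 sugar-nucleotide bp:left, found {n_donors}",
                )
            )
            continue
        acceptor = next(o for o in lefts if sn_iri not in graph.types_of(o))
        if sac_iri not in graph.types_of(acceptor):
            violations.append(
                Violation("R2", reaction, f"acceptor {acceptor} is not typed Saccharide")
            )
    return violations


def _check_r3(graph, vocab, wurcs_index):
    violations = []
    reaction_iri = vocab.class_iri("BiochemicalReaction")
    for catalysis in graph.subjects_of_type(vocab.class_iri("Catalysis")):
        controlled = graph.objects(catalysis, vocab.prop("controlled"))
        controllers = graph.objects(catalysis, vocab.prop("controller"))
        if len(controlled) != 1:
            violations.append(
                Violation("R3", catalysis, f"expected 1 bp:controlled, found {len(controlled)}")
            )
        elif not (
            isinstance(controlled[0], str)
            and reaction_iri in graph.types_of(controlled[0])
        ):
            violations.append(
                Violation("R3", catalysis, "bp:controlled is not a BiochemicalReaction")
            )
        if not controllers:
            violations.append(Violation("R3", catalysis, "no bp:controller"))
    return violations


def _check_r4(graph, vocab, wurcs_index):
    violations = []
    next_step = vocab.prop("nextStep")
    for pathway in graph.subjects_of_type(vocab.class_iri("Pathway")):
        steps = [o for o in graph.objects(pathway, vocab.prop("pathwayOrder")) if isinstance(o, str)]
        step_set = set(steps)
        if not steps:
            violations.append(Violation("R4", pathway, "pathway has no steps"))
            continue
        edges = {}
        indegree = {s: 0 for s in steps}
        broken = False
        for s in steps:
            nxts = [o for o in graph.objects(s, next_step) if isinstance(o, str)]
            if len(nxts) > 1:
                violations.append(
                    Violation("R4", s, f"step has {len(nxts)} nextStep links (branching)")
                )
                broken = True
                continue
            if nxts:
                if nxts[0] not in step_set:
                    violations.append(
                        Violation("R4", s, "nextStep points outside the pathway's steps")
                    )
                    broken = True
                    continue
                edges[s] = nxts[0]
                indegree[nxts[0]] += 1
        if broken:
            continue
        heads = [s for s in steps if indegree[s] == 0]
        if len(heads) != 1 or any(d > 1 for d in indegree.values()):
            violations.append(
                Violation(
                    "R4",
                    pathway,
                    "nextStep links do not form a single simple chain "
                    f"({len(heads)} head step(s))",
                )
            )
            continue
        visited = []
        cursor: str | None = heads[0]
        while cursor is not None and cursor not in visited:
            visited.append(cursor)
            cursor = edges.get(cursor)
        if len(visited) != len(steps):
            violations.append(
                Violation(
                    "R4",
                    pathway,
                    f"chain visits {len(visited)} of {len(steps)} steps "
                    "(cycle or disconnected segment)",
                )
            )
    return violations


def _glycan_nodes(graph: TripleGraph, vocab: VocabularyMap) -> tuple[set[str], set[str]]:
    """(acceptor/product glycans, donor glycans) over all reactions."""
    sn_iri = vocab.class_iri("SugarNucleotide")
    saccharides: set[str] = set()
    donors: set[str] = set()
    for reaction in graph.subjects_of_type(vocab.class_iri("BiochemicalReaction")):
        for prop in ("left", "right"):
            for o in graph.objects(reaction, vocab.prop(prop)):
                if not isinstance(o, str):
                    continue
                if sn_iri in graph.types_of(o):
                    donors.add(o)
                else:
                    saccharides.add(o)
    return saccharides, donors


def _check_r5(graph, vocab, wurcs_index):
    violations = []
    sac_iri = vocab.class_iri("Saccharide")
    sm_iri = vocab.class_iri("SmallMolecule")
    saccharides, _ = _glycan_nodes(graph, vocab)
    for glycan in sorted(saccharides):
        types = graph.types_of(glycan)
        missing = [
            name
            for name, iri in (("Saccharide", sac_iri), ("SmallMolecule", sm_iri))
            if iri not in types
        ]
        if missing:
            violations.append(
                Violation("R5", glycan, f"glycan lacks type(s): {', '.join(missing)}")
            )
    return violations


def _check_r6(graph, vocab, wurcs_index):
    violations = []
    ux_iri = vocab.class_iri("UnificationXref")
    saccharides, donors = _glycan_nodes(graph, vocab)
    for glycan in sorted(saccharides | donors):
        ok = False
        for xref in graph.objects(glycan, vocab.prop("xref")):
            if not (isinstance(xref, str) and ux_iri in graph.types_of(xref)):
                continue
            for ident in graph.objects(xref, vocab.prop("id")):
                if isinstance(ident, Literal) and ACCESSION_RE.fullmatch(
                    ident.lexical_form
                ):
                    ok = True
        if not ok:
            violations.append(
                Violation(
                    "R6",
                    glycan,
                    "no bp:xref to a UnificationXref with a valid GlyTouCan accession",
                )
            )
    return violations


def _check_r7(graph, vocab, wurcs_index):
    violations = []
    for subject in graph.subjects():
        if not graph.types_of(subject):
            violations.append(Violation("R7", subject, "subject has no rdf:type"))
    return violations


_CHECKS = {
    "R1": _check_r1,
    "R2": _check_r2,
    "R3": _check_r3,
    "R4": _check_r4,
    "R5": _check_r5,
    "R6": _check_r6,
    "R7": _check_r7,
}


def check_rule(
    graph: TripleGraph,
    rule_id: str,
    wurcs_index: dict[str, str] | None = None,
    vocab: VocabularyMap | None = None,
) -> list[Violation]:
    """Run a single rule; equals the corresponding slice of the full report."""
    if rule_id not in _CHECKS:
        raise UnknownRuleError(f"unknown validation rule {rule_id!r}")
    vocab = vocab or VocabularyMap.default()
    if wurcs_index is None:
        wurcs_index = build_wurcs_index(graph, vocab)
    return _CHECKS[rule_id](graph, vocab, wurcs_index)


def validate_graph(
    graph: TripleGraph,
    wurcs_index: dict[str, str] | None = None,
    vocab: VocabularyMap | None = None,
    rules: list[str] | None = None,
) -> ValidationReport:
    """Run every registered rule (or the given subset) over the graph.

    The WURCS index defaults to the literals embedded in the graph; an
    explicit index overrides them (e.g. a sidecar for graphs produced
    elsewhere).  The report collects all violations; it never fails fast.
    """
    vocab = vocab or VocabularyMap.default()
    if wurcs_index is None:
        wurcs_index = build_wurcs_index(graph, vocab)
    report = ValidationReport(checked_statement_count=len(graph))
    for rule_id in rules or sorted(_CHECKS):
        report.violations.extend(check_rule(graph, rule_id, wurcs_index, vocab))
    return report
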