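"""ECODAB-style synthetic fixtures with known ground truth.

Real O-antigen pathway data is scraped from curated web databases
(per-serogroup repeat-unit structures, glycosyltransferase names,
literature references) and registered with GlyTouCan; none of that is
reachable from an offline test suite.  This module generates content
with the same shape instead: per pathway, a k-residue repeat unit built
by k-1 single-residue extensions from one priming residue, with
header-consistent synthetic WURCS strings (residue counts 1..k along
the chain, donors always 1), GlyTouCan-pattern accessions, WbbX-like
enzyme names and PubMed-like citation ids.  Every quantity a test might
want to check is recorded in a :class:`FixtureTruth` alongside the
emitted class tables, and all randomness flows from one seed, so a
fixture is reproducible byte for byte.

:func:`mutate_fixture` plants exactly one targeted defect into a clean
fixture (a broken reaction arity, an inflated product, a dropped
controller, a step cycle, or a corrupt accession) to drive validator
sensitivity tests.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MutationError
from .model_builder import (
    GLYTOUCAN_PREFIX,
    EnzymeEntity,
    GlycanEntity,
    PathwayModel,
    PathwayStepSpec,
    VocabularyMap,
    XrefSpec,
    build_pathway,
    pathway_to_triples,
)
from .rdf_graph import Literal, RDF_TYPE, TripleGraph, merge
from .tables_io import InstanceTable, TableRow, write_instance_table

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "MutationRecord",
    "MUTATION_KINDS",
    "generate_fixture",
    "fixture_models",
    "fixture_graph",
    "graph_to_tables",
    "mutate_fixture",
    "write_fixture",
]

_GC_IRI_RE = re.compile(r".*GC-([A-Za-z]+)-\d{5}$")

MUTATION_KINDS = (
    "break_chain",
    "inflate_product",
    "drop_controller",
    "cycle_steps",
    "bad_accession",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset.

    ``residues_per_repeat`` is the repeat-unit length k (>= 2), either
    one value for all pathways or a per-pathway list.  The defaults
    (five pathways of five residues) keep a full generate/RDFize/
    validate/query cycle well under a second.
    """

    n_pathways: int = 5
    residues_per_repeat: int | tuple[int, ...] = 5
    seed: int = 0
    name_prefix: str = "O-antigen "
    names: tuple[str, ...] | None = None
    serial_start: int = 301  # first minted serial; instance ids look like GC-Pathway-00301

    def repeat_lengths(self) -> list[int]:
        if isinstance(self.residues_per_repeat, int):
            lengths = [self.residues_per_repeat] * self.n_pathways
        else:
            lengths = list(self.residues_per_repeat)
            if len(lengths) != self.n_pathways:
                raise ValueError(
                    f"residues_per_repeat lists {len(lengths)} lengths for "
                    f"{self.n_pathways} pathways"
                )
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be positive")
        if any(k < 2 for k in lengths):
            raise ValueError("each repeat unit needs at least 2 residues")
        return lengths


@dataclass
class FixtureTruth:
    """Ground truth recorded while generating a fixture."""

    n_pathways: int
    pathway_names: list[str]
    reactions_per_pathway: list[int]
    accessions: list[str]
    wurcs_by_iri: dict[str, str]
    enzyme_names: list[str]
    citation_ids: list[str]

    @property
    def total_reactions(self) -> int:
        return sum(self.reactions_per_pathway)

    @property
    def total_next_steps(self) -> int:
        return sum(n - 1 for n in self.reactions_per_pathway)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass(frozen=True)
class MutationRecord:
    mutation: str
    subject: str  # IRI (or subject id) of the mutated instance
    detail: str = ""


def _accession(rng: random.Random, used: set[str]) -> str:
    while True:
        acc = "G{:05d}{}{}".format(
            rng.randrange(100_000),
            chr(rng.randrange(65, 91)),
            chr(rng.randrange(65, 91)),
        )
        if acc not in used:
            used.add(acc)
            return acc


def _enzyme_name(rng: random.Random, used: set[str]) -> str:
    while True:
        name = "Wb{}{}".format(
            chr(rng.randrange(97, 123)), chr(rng.randrange(65, 91))
        )
        if name not in used:
            used.add(name)
            return name


def _wurcs(m: int, rng: random.Random) -> str:
    """A header-consistent synthetic WURCS for a linear m-residue chain.

    Only the header is semantically meaningful; the residue/linkage body
    is a placeholder (real chemistry is out of scope).
    """
    residues = "".join(f"[x{j}h{rng.randrange(10)}]" for j in range(1, m + 1))
    order = "-".join(str(j) for j in range(1, m + 1))
    links = "_".join(f"a{j}-b{j + 1}" for j in range(1, m))
    return f"WURCS=2.0/{m},{m},{m - 1}/{residues}/{order}/{links}"


def _pathway_names(spec: FixtureSpec, rng: random.Random) -> list[str]:
    if spec.names is not None:
        if len(spec.names) != spec.n_pathways:
            raise ValueError("names list length must equal n_pathways")
        return list(spec.names)
    names = []
    for j in range(1, spec.n_pathways + 1):
        subtype = rng.choice(["", "", "A", "B"])  # occasional serogroup subtype
        names.append(f"{spec.name_prefix}{j}{subtype}")
    return names


def fixture_models(
    spec: FixtureSpec,
    vocab: VocabularyMap | None = None,
) -> tuple[list[PathwayModel], FixtureTruth]:
    """Build the pathway models (and truth) for a fixture specification."""
    vocab = vocab or VocabularyMap.default()
    base = vocab.prefix_to_namespace[""]
    rng = random.Random(spec.seed)
    lengths = spec.repeat_lengths()
    names = _pathway_names(spec, rng)

    used_accessions: set[str] = set()
    used_enzymes: set[str] = set()
    truth = FixtureTruth(
        n_pathways=spec.n_pathways,
        pathway_names=list(names),
        reactions_per_pathway=[k - 1 for k in lengths],
        accessions=[],
        wurcs_by_iri={},
        enzyme_names=[],
        citation_ids=[],
    )

    models: list[PathwayModel] = []
    serial = spec.serial_start
    for name, k in zip(names, lengths):
        saccharides: list[GlycanEntity] = []
        for m in range(1, k + 1):
            acc = _accession(rng, used_accessions)
            roles = {"acceptor"} if m == 1 else (
                {"product", "complete_antigen"} if m == k else {"acceptor", "product"}
            )
            saccharides.append(
                GlycanEntity(
                    local_id=f"{name}/S{m}",
                    glytoucan_accession=acc,
                    display_name=f"{name} intermediate {m}" if m < k else f"{name} repeat unit",
                    wurcs=_wurcs(m, rng),
                    roles=frozenset(roles),
                )
            )
        steps: list[PathwayStepSpec] = []
        for i in range(1, k):
            donor = GlycanEntity(
                local_id=f"{name}/D{i}",
                glytoucan_accession=_accession(rng, used_accessions),
                display_name=f"{name} donor {i}",
                wurcs=_wurcs(1, rng),
                roles=frozenset({"sugar_nucleotide"}),
            )
            enzyme = EnzymeEntity(
                local_id=f"{name}/E{i}",
                display_name=_enzyme_name(rng, used_enzymes),
            )
            citation = XrefSpec("publication", "PubMed", str(rng.randrange(10_000_000, 40_000_000)))
            steps.append(
                PathwayStepSpec(
                    step_index=i,
                    acceptor=saccharides[i - 1],
                    donor=donor,
                    product=saccharides[i],
                    enzyme=enzyme,
                    citations=(citation,),
                )
            )
            truth.accessions.append(donor.glytoucan_accession)
            truth.enzyme_names.append(enzyme.display_name)
            truth.citation_ids.append(citation.identifier)
            truth.wurcs_by_iri[GLYTOUCAN_PREFIX + donor.glytoucan_accession] = donor.wurcs
        for glycan in saccharides:
            truth.accessions.append(glycan.glytoucan_accession)
            truth.wurcs_by_iri[GLYTOUCAN_PREFIX + glycan.glytoucan_accession] = glycan.wurcs

        model = build_pathway(name, steps, serial_start=serial, base_namespace=base)
        serial = model.serial_end
        models.append(model)
    return models, truth


def fixture_graph(
    spec: FixtureSpec,
    vocab: VocabularyMap | None = None,
) -> tuple[TripleGraph, FixtureTruth]:
    """Generate a fixture and RDFize it directly (model route)."""
    vocab = vocab or VocabularyMap.default()
    models, truth = fixture_models(spec, vocab)
    graph = merge([pathway_to_triples(m, vocab) for m in models])
    return graph, truth


def graph_to_tables(
    graph: TripleGraph,
    vocab: VocabularyMap | None = None,
) -> dict[str, InstanceTable]:
    """Arrange a pathway graph into per-class instance tables.

    Each subject lands in the table of its primary class (read off the
    minted ``GC-<Class>-NNNNN`` id, or Saccharide/SugarNucleotide for
    GlyTouCan glycan IRIs); additional types go into an explicit
    ``rdf:type`` column.  RDFizing the resulting tables reproduces the
    source graph exactly.
    """
    vocab = vocab or VocabularyMap.default()
    iri_to_class = {iri: name for name, iri in vocab.class_iris.items()}
    curie_by_iri: dict[str, str] = {}
    for prefix, ns in vocab.prefix_to_namespace.items():
        if prefix:
            curie_by_iri[ns] = prefix

    def compact_predicate(iri: str) -> str:
        best = max(
            (ns for ns in curie_by_iri if iri.startswith(ns)),
            key=len,
            default=None,
        )
        if best is None:
            return iri
        return f"{curie_by_iri[best]}:{iri[len(best):]}"

    def primary_class(subject: str, types: set[str]) -> str | None:
        match = _GC_IRI_RE.match(subject)
        if match and match.group(1) in vocab.class_iris:
            return match.group(1)
        if subject.startswith(GLYTOUCAN_PREFIX):
            if vocab.class_iri("SugarNucleotide") in types:
                return "SugarNucleotide"
            return "Saccharide"
        for t in sorted(types):
            if t in iri_to_class:
                return iri_to_class[t]
        return None

    tables: dict[str, InstanceTable] = {}
    columns: dict[str, set[str]] = {}
    per_subject: dict[str, dict[str, list[str]]] = {}
    subject_class: dict[str, str] = {}

    grouped: dict[str, list] = {}
    for st in graph:
        grouped.setdefault(st.subject, []).append(st)

    for subject in graph.subjects():
        types = graph.types_of(subject)
        cls = primary_class(subject, types)
        if cls is None:
            cls = "Untyped"
        subject_class[subject] = cls
        values: dict[str, list[str]] = {}
        for st in sorted(
            grouped[subject],
            key=lambda s: (s.predicate, str(s.object)),
        ):
            if st.predicate == RDF_TYPE:
                if st.object == vocab.class_iris.get(cls):
                    continue  # implied by the table's class
                column = "rdf:type"
                value = str(st.object)
            else:
                column = compact_predicate(st.predicate)
                obj = st.object
                value = obj.lexical_form if isinstance(obj, Literal) else str(obj)
            values.setdefault(column, []).append(value)
        per_subject[subject] = values
        columns.setdefault(cls, set()).update(values)

    for cls in sorted(columns):
        props = sorted(columns[cls], key=lambda c: (c != "rdf:type", c))
        table = InstanceTable(class_name=cls, property_names=props)
        for subject in sorted(s for s, c in subject_class.items() if c == cls):
            table.rows.append(TableRow(subject_id=subject, values=per_subject[subject]))
        tables[cls] = table
    return tables


def generate_fixture(
    spec: FixtureSpec,
    vocab: VocabularyMap | None = None,
) -> tuple[dict[str, InstanceTable], FixtureTruth]:
    """Generate the per-class instance tables plus their ground truth."""
    vocab = vocab or VocabularyMap.default()
    graph, truth = fixture_graph(spec, vocab)
    return graph_to_tables(graph, vocab), truth


def write_fixture(
    tables: dict[str, InstanceTable],
    truth: FixtureTruth | None,
    directory: str | Path,
) -> None:
    """Write tables as ``<ClassName>.csv`` plus a ``truth.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls, table in sorted(tables.items()):
        with open(directory / f"{cls}.csv", "w", encoding="utf-8", newline="") as fh:
            write_instance_table(table, fh)
    if truth is not None:
        (directory / "truth.json").write_text(truth.to_json(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Targeted mutations
# ---------------------------------------------------------------------------

def _copy_tables(tables: dict[str, InstanceTable]) -> dict[str, InstanceTable]:
    return {
        cls: InstanceTable(
            class_name=t.class_name,
            property_names=list(t.property_names),
            rows=[
                TableRow(r.subject_id, {k: list(v) for k, v in r.values.items()})
                for r in t.rows
            ],
        )
        for cls, t in tables.items()
    }


def _require(tables: dict[str, InstanceTable], cls: str) -> InstanceTable:
    if cls not in tables:
        raise MutationError(f"fixture has no {cls!r} table")
    return tables[cls]


def mutate_fixture(
    tables: dict[str, InstanceTable],
    mutation: str,
    seed: int = 0,
) -> tuple[dict[str, InstanceTable], MutationRecord]:
    """Introduce exactly one targeted defect into a clean fixture.

    Each mutation kind is paired with one validation rule:
    ``break_chain`` -> R2, ``inflate_product`` -> R1,
    ``drop_controller`` -> R3, ``cycle_steps`` -> R4,
    ``bad_accession`` -> R6.  Returns the mutated copy of the tables and
    a record naming the altered instance.
    """
    if mutation not in MUTATION_KINDS:
        raise MutationError(f"unknown mutation {mutation!r}")
    rng = random.Random(seed)
    out = _copy_tables(tables)

    if mutation == "break_chain":
        reactions = _require(out, "BiochemicalReaction")
        donors = {
            r.subject_id for r in _require(out, "SugarNucleotide").rows
        }
        candidates = [
            r for r in reactions.rows
            if len(r.values.get("bp:left", [])) == 2
        ]
        if not candidates:
            raise MutationError("no reaction with two left participants")
        row = rng.choice(candidates)
        acceptors = [v for v in row.values["bp:left"] if v not in donors]
        if not acceptors:
            raise MutationError("reaction has no non-donor left participant")
        row.values["bp:left"] = [v for v in row.values["bp:left"] if v != acceptors[0]]
        return out, MutationRecord(mutation, row.subject_id,
                                   f"removed acceptor {acceptors[0]}")

    if mutation == "inflate_product":
        # Target a terminal product (never an acceptor downstream) so the
        # inflated WURCS breaks exactly one reaction's residue arithmetic.
        reactions = _require(out, "BiochemicalReaction")
        lefts = {v for r in reactions.rows for v in r.values.get("bp:left", [])}
        terminal = sorted(
            {
                v
                for r in reactions.rows
                for v in r.values.get("bp:right", [])
                if v not in lefts
            }
        )
        if not terminal:
            raise MutationError("no terminal product glycan found")
        target = rng.choice(terminal)
        saccharides = _require(out, "Saccharide")
        for row in saccharides.rows:
            if row.subject_id == target and row.values.get("glycan:has_wurcs"):
                wurcs = row.values["glycan:has_wurcs"][0]
                header, _, body = wurcs.partition("/")
                counts, _, rest = body.partition("/")
                u, r_, l_ = (int(c) for c in counts.split(","))
                row.values["glycan:has_wurcs"] = [
                    f"{header}/{u + 2},{r_ + 2},{l_ + 2}/{rest}"
                ]
                return out, MutationRecord(
                    mutation, target, f"residue count {r_} -> {r_ + 2}"
                )
        raise MutationError(f"terminal product {target} carries no WURCS")

    if mutation == "drop_controller":
        catalyses = _require(out, "Catalysis")
        candidates = [r for r in catalyses.rows if r.values.get("bp:controller")]
        if not candidates:
            raise MutationError("no catalysis with a controller")
        row = rng.choice(candidates)
        dropped = row.values.pop("bp:controller")
        return out, MutationRecord(mutation, row.subject_id,
                                   f"removed controller {dropped[0]}")

    if mutation == "cycle_steps":
        steps = _require(out, "BiochemicalPathwayStep")
        pathways = _require(out, "Pathway")
        targets = {
            v for r in steps.rows for v in r.values.get("bp:nextStep", [])
        }
        multi = [
            r for r in pathways.rows
            if len(r.values.get("bp:pathwayOrder", [])) >= 2
        ]
        if not multi:
            raise MutationError("cycle needs a pathway with at least 2 steps")
        pathway = rng.choice(multi)
        members = set(pathway.values["bp:pathwayOrder"])
        tail = next(
            r for r in steps.rows
            if r.subject_id in members and not r.values.get("bp:nextStep")
        )
        head = sorted(members - targets)[0]
        tail.values["bp:nextStep"] = [head]
        if "bp:nextStep" not in steps.property_names:
            steps.property_names.append("bp:nextStep")
        return out, MutationRecord(mutation, tail.subject_id,
                                   f"added nextStep back to {head}")

    # bad_accession
    xrefs = _require(out, "UnificationXref")
    if not xrefs.rows:
        raise MutationError("no unification xrefs to corrupt")
    row = rng.choice(xrefs.rows)
    old = row.values.get("bp:id", ["?"])[0]
    row.values["bp:id"] = ["INVALID01"]
    return out, MutationRecord(mutation, row.subject_id, f"id {old} -> INVALID01")
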