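"""BioPAX Level 3 aligned pathway model for O-antigen biosynthesis.

An O-antigen repeat unit is assembled by stepwise single-residue
extensions: each step is a glycosyl transfer in which a
glycosyltransferase moves one monosaccharide from a sugar-nucleotide
donor onto an acceptor glycan, yielding a product one residue longer.
This module houses the domain entities (glycans, enzymes, cross
references, step specifications), mints instance IRIs in the
``GC-<Class>-NNNNN`` scheme, chains steps into a
:class:`PathwayModel`, and lowers a model to RDF statements:

* each step becomes a ``bp:BiochemicalReaction`` with two ``bp:left``
  participants (donor + acceptor) and one ``bp:right`` (product);
* catalysis by the glycosyltransferase is a ``bp:Catalysis`` with
  ``bp:controlled``/``bp:controller``;
* step order is expressed with ``bp:BiochemicalPathwayStep`` and
  ``bp:nextStep``, tied to the ``bp:Pathway`` via ``bp:pathwayOrder``;
* glycan identity is anchored in GlyTouCan accessions, both as the
  instance IRI (``http://glytoucan.org/Structures/Glycans/<acc>``) and
  as a ``bp:UnificationXref``; literature goes into
  ``bp:PublicationXref`` nodes.

Donors are typed with a sugar-nucleotide class (ChEBI); acceptors and
products are typed as both GlycoRDF ``Saccharide`` and BioPAX
``SmallMolecule`` so the same node serves glycan-centric and
pathway-centric consumers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    ChainError,
    ConfigurationError,
    InvalidAccessionError,
    SerialOverflowError,
    StepIndexError,
    UnknownClassError,
)
from .rdf_graph import Literal, RDF_NS, RDF_TYPE, TripleGraph

__all__ = [
    "BP_NS",
    "GLYCORDF_NS",
    "GLYTOUCAN_PREFIX",
    "DEFAULT_BASE_NAMESPACE",
    "DEFAULT_SUGAR_NUCLEOTIDE_IRI",
    "ACCESSION_RE",
    "VocabularyMap",
    "GlycanEntity",
    "EnzymeEntity",
    "XrefSpec",
    "PathwayStepSpec",
    "BuiltStep",
    "PathwayModel",
    "mint_instance_iri",
    "glytoucan_iri",
    "build_pathway",
    "pathway_to_triples",
]

BP_NS = "http://www.biopax.org/release/biopax-level3.owl#"
GLYCORDF_NS = "http://purl.jp/bio/12/glyco/glycan#"
OBO_NS = "http://purl.obolibrary.org/obo/"
GLYTOUCAN_PREFIX = "http://glytoucan.org/Structures/Glycans/"
DEFAULT_BASE_NAMESPACE = "https://example.org/glycopath/"

# The sugar-nucleotide class lives in ChEBI; the exact identifier is a
# configuration point (override via VocabularyMap / config file), this is
# merely the shipped default binding.
DEFAULT_SUGAR_NUCLEOTIDE_IRI = OBO_NS + "CHEBI_25609"

# GlyTouCan's published accession scheme: "G" + 5 digits + 2 uppercase.
ACCESSION_RE = re.compile(r"G\d{5}[A-Z]{2}")

# Classes for which GC-<Class>-NNNNN instance IRIs may be minted.
KNOWN_MODEL_CLASSES = frozenset(
    {
        "Pathway",
        "BiochemicalReaction",
        "Catalysis",
        "BiochemicalPathwayStep",
        "SmallMolecule",
        "Protein",
        "Saccharide",
        "SugarNucleotide",
        "PublicationXref",
        "UnificationXref",
    }
)

_SERIAL_LIMIT = 100_000


@dataclass
class VocabularyMap:
    """Prefixes plus class- and property-IRI bindings for the model.

    ``default()`` carries the full vocabulary the pathway model uses;
    everything is overridable, and the sugar-nucleotide class IRI in
    particular should be reviewed per deployment (see module docs).
    """

    prefix_to_namespace: dict[str, str]
    class_iris: dict[str, str]
    property_iris: dict[str, str]

    @classmethod
    def default(
        cls,
        base_namespace: str = DEFAULT_BASE_NAMESPACE,
        sugar_nucleotide_class_iri: str = DEFAULT_SUGAR_NUCLEOTIDE_IRI,
    ) -> "VocabularyMap":
        prefixes = {
            "bp": BP_NS,
            "rdf": RDF_NS,
            "glycan": GLYCORDF_NS,
            "obo": OBO_NS,
            "gtc": GLYTOUCAN_PREFIX,
            "": base_namespace,
        }
        class_iris = {
            "Pathway": BP_NS + "Pathway",
            "BiochemicalReaction": BP_NS + "BiochemicalReaction",
            "Catalysis": BP_NS + "Catalysis",
            "BiochemicalPathwayStep": BP_NS + "BiochemicalPathwayStep",
            "SmallMolecule": BP_NS + "SmallMolecule",
            "Protein": BP_NS + "Protein",
            "PublicationXref": BP_NS + "PublicationXref",
            "UnificationXref": BP_NS + "UnificationXref",
            "Saccharide": GLYCORDF_NS + "Saccharide",
            "SugarNucleotide": sugar_nucleotide_class_iri,
        }
        property_iris = {
            "type": RDF_TYPE,
            "left": BP_NS + "left",
            "right": BP_NS + "right",
            "controlled": BP_NS + "controlled",
            "controller": BP_NS + "controller",
            "pathwayOrder": BP_NS + "pathwayOrder",
            "nextStep": BP_NS + "nextStep",
            "stepConversion": BP_NS + "stepConversion",
            "pathwayComponent": BP_NS + "pathwayComponent",
            "xref": BP_NS + "xref",
            "displayName": BP_NS + "displayName",
            "db": BP_NS + "db",
            "id": BP_NS + "id",
            "has_wurcs": GLYCORDF_NS + "has_wurcs",
        }
        vocab = cls(prefixes, class_iris, property_iris)
        vocab.validate()
        return vocab

    def validate(self) -> None:
        for required, ns in (("bp", BP_NS), ("rdf", RDF_NS)):
            if self.prefix_to_namespace.get(required) != ns:
                raise ConfigurationError(
                    f"vocabulary must bind prefix {required!r} to <{ns}>"
                )
        namespaces = tuple(v for v in self.prefix_to_namespace.values() if v)
        for name, iri in {**self.class_iris, **self.property_iris}.items():
            if not iri.startswith(namespaces):
                raise ConfigurationError(
                    f"IRI for {name!r} ({iri}) resolves under no declared prefix"
                )

    def class_iri(self, name: str) -> str:
        try:
            return self.class_iris[name]
        except KeyError:
            raise ConfigurationError(f"no class IRI configured for {name!r}") from None

    def prop(self, name: str) -> str:
        try:
            return self.property_iris[name]
        except KeyError:
            raise ConfigurationError(f"no property IRI configured for {name!r}") from None

    def expand_curie(self, curie: str) -> str:
        """Expand ``prefix:local`` using the declared prefixes."""
        prefix, _, local = curie.partition(":")
        try:
            return self.prefix_to_namespace[prefix] + local
        except KeyError:
            raise ConfigurationError(
                f"undeclared prefix {prefix!r} in CURIE {curie!r}"
            ) from None


@dataclass(frozen=True)
class XrefSpec:
    """An external cross reference; ``kind`` selects the BioPAX class."""

    kind: str  # "unification" | "publication"
    database: str
    identifier: str

    def __post_init__(self) -> None:
        if self.kind not in ("unification", "publication"):
            raise ValueError(f"unknown xref kind {self.kind!r}")
        if not self.identifier:
            raise ValueError("xref identifier must be non-empty")


GLYCAN_ROLES = frozenset({"acceptor", "product", "complete_antigen", "sugar_nucleotide"})


@dataclass(frozen=True)
class GlycanEntity:
    """A saccharide or sugar nucleotide with GlyTouCan identity."""

    local_id: str
    glytoucan_accession: str
    display_name: str
    wurcs: str | None = None
    roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not ACCESSION_RE.fullmatch(self.glytoucan_accession):
            raise InvalidAccessionError(self.glytoucan_accession)
        unknown = set(self.roles) - GLYCAN_ROLES
        if unknown:
            raise ValueError(f"unknown glycan roles: {sorted(unknown)}")
        if "sugar_nucleotide" in self.roles and len(self.roles) > 1:
            raise ValueError("a sugar nucleotide carries no other role")

    @property
    def is_sugar_nucleotide(self) -> bool:
        return "sugar_nucleotide" in self.roles


@dataclass(frozen=True)
class EnzymeEntity:
    """A glycosyltransferase, identified by its protein name (e.g. WbbL)."""

    local_id: str
    display_name: str
    xrefs: tuple[XrefSpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.display_name:
            raise ValueError("enzyme display_name must be non-empty")


@dataclass(frozen=True)
class PathwayStepSpec:
    """One biosynthetic extension: acceptor + donor -> product, catalysed."""

    step_index: int
    acceptor: GlycanEntity
    donor: GlycanEntity
    product: GlycanEntity
    enzyme: EnzymeEntity
    citations: tuple[XrefSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.step_index < 1:
            raise ValueError("step_index is 1-based and must be positive")
        if self.acceptor.local_id == self.product.local_id:
            raise ValueError(
                f"step {self.step_index}: acceptor and product are identical"
            )
        if not self.donor.is_sugar_nucleotide:
            raise ValueError(
                f"step {self.step_index}: donor {self.donor.local_id!r} "
                "must carry the sugar_nucleotide role"
            )


@dataclass(frozen=True)
class BuiltStep:
    """IRIs minted for one step of a built pathway."""

    spec: PathwayStepSpec
    reaction_iri: str
    catalysis_iri: str
    step_iri: str
    acceptor_iri: str
    donor_iri: str
    product_iri: str
    enzyme_iri: str


@dataclass
class PathwayModel:
    """A built pathway: minted IRIs for the pathway and each ordered step."""

    pathway_iri: str
    display_name: str
    steps: list[BuiltStep]
    enzyme_iris: dict[str, str] = field(default_factory=dict)
    glycan_xref_iris: dict[str, str] = field(default_factory=dict)
    citation_xref_iris: dict[tuple[str, str], str] = field(default_factory=dict)
    serial_end: int = 0  # next unused serial, for chaining across pathways


def mint_instance_iri(class_name: str, serial: int, base_namespace: str) -> str:
    """Mint ``<base>GC-<Class>-NNNNN`` with the serial zero-padded to 5 digits."""
    if class_name not in KNOWN_MODEL_CLASSES:
        raise UnknownClassError(f"unknown model class {class_name!r}")
    if not 0 <= serial < _SERIAL_LIMIT:
        raise SerialOverflowError(
            f"serial {serial} outside the 5-digit range [0, {_SERIAL_LIMIT})"
        )
    return f"{base_namespace}GC-{class_name}-{serial:05d}"


def glytoucan_iri(accession: str) -> str:
    """Resolve a GlyTouCan accession to its repository IRI."""
    if not ACCESSION_RE.fullmatch(accession):
        raise InvalidAccessionError(accession)
    return GLYTOUCAN_PREFIX + accession


def build_pathway(
    name: str,
    steps: list[PathwayStepSpec],
    serial_start: int,
    base_namespace: str = DEFAULT_BASE_NAMESPACE,
) -> PathwayModel:
    """Chain step specifications into a :class:`PathwayModel`.

    Steps must carry contiguous 1-based indices and be chained: the
    product of step *i* is the acceptor of step *i+1*.  Serials are
    allocated deterministically in a fixed traversal order starting at
    ``serial_start`` — pathway first, then reaction/catalysis/step per
    step, then enzymes and cross-reference nodes — so one global counter
    shared across pathways yields the mixed per-class serials seen in
    instance ids like ``GC-Pathway-00301`` / ``GC-BiochemicalReaction-00302``.
    """
    if not steps:
        raise ValueError("a pathway needs at least one step")
    ordered = sorted(steps, key=lambda s: s.step_index)
    indices = [s.step_index for s in ordered]
    if len(set(indices)) != len(indices):
        raise StepIndexError(f"duplicate step indices: {indices}")
    if indices != list(range(1, len(indices) + 1)):
        raise StepIndexError(f"step indices must be 1..n without gaps: {indices}")
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.product.local_id != nxt.acceptor.local_id:
            raise ChainError(
                f"product of step {prev.step_index} "
                f"({prev.product.local_id!r}) is not the acceptor of step "
                f"{nxt.step_index} ({nxt.acceptor.local_id!r})"
            )

    serial = serial_start
    def mint(class_name: str) -> str:
        nonlocal serial
        iri = mint_instance_iri(class_name, serial, base_namespace)
        serial += 1
        return iri

    pathway_iri = mint("Pathway")
    built: list[BuiltStep] = []
    pending: list[tuple[PathwayStepSpec, str, str, str]] = []
    for spec in ordered:
        pending.append(
            (spec, mint("BiochemicalReaction"), mint("Catalysis"),
             mint("BiochemicalPathwayStep"))
        )
    enzyme_iris: dict[str, str] = {}
    for spec, *_ in pending:
        if spec.enzyme.local_id not in enzyme_iris:
            enzyme_iris[spec.enzyme.local_id] = mint("Protein")
    glycan_xref_iris: dict[str, str] = {}
    citation_xref_iris: dict[tuple[str, str], str] = {}
    for spec, *_ in pending:
        for glycan in (spec.acceptor, spec.donor, spec.product):
            if glycan.glytoucan_accession not in glycan_xref_iris:
                glycan_xref_iris[glycan.glytoucan_accession] = mint("UnificationXref")
        for citation in spec.citations:
            key = (citation.database, citation.identifier)
            if key not in citation_xref_iris:
                citation_xref_iris[key] = mint("PublicationXref")

    for spec, reaction_iri, catalysis_iri, step_iri in pending:
        built.append(
            BuiltStep(
                spec=spec,
                reaction_iri=reaction_iri,
                catalysis_iri=catalysis_iri,
                step_iri=step_iri,
                acceptor_iri=glytoucan_iri(spec.acceptor.glytoucan_accession),
                donor_iri=glytoucan_iri(spec.donor.glytoucan_accession),
                product_iri=glytoucan_iri(spec.product.glytoucan_accession),
                enzyme_iri=enzyme_iris[spec.enzyme.local_id],
            )
        )
    return PathwayModel(
        pathway_iri=pathway_iri,
        display_name=name,
        steps=built,
        enzyme_iris=enzyme_iris,
        glycan_xref_iris=glycan_xref_iris,
        citation_xref_iris=citation_xref_iris,
        serial_end=serial,
    )


def pathway_to_triples(
    model: PathwayModel,
    vocab: VocabularyMap | None = None,
    *,
    emit_pathway_component: bool = False,
) -> TripleGraph:
    """Lower a :class:`PathwayModel` to RDF statements.

    Emits, per reaction, two ``bp:left`` statements (donor and acceptor)
    and one ``bp:right`` (product); catalysis and step/order wiring; dual
    ``Saccharide`` + ``SmallMolecule`` typing for acceptor/product
    glycans and sugar-nucleotide typing for donors; display names; and
    ``bp:xref`` links to GlyTouCan ``UnificationXref`` and literature
    ``PublicationXref`` nodes.  WURCS strings, when present on a glycan,
    are attached as literals so downstream validation can check the
    single-extension rule directly from the graph.

    ``bp:pathwayComponent`` statements (pathway -> reaction) are emitted
    only when ``emit_pathway_component`` is set; step order alone is the
    default wiring.
    """
    vocab = vocab or VocabularyMap.default()
    g = TripleGraph(prefixes=vocab.prefix_to_namespace)

    def typed(subject: str, class_name: str) -> None:
        g.add(subject, RDF_TYPE, vocab.class_iri(class_name))

    typed(model.pathway_iri, "Pathway")
    g.add(model.pathway_iri, vocab.prop("displayName"), Literal(model.display_name))

    seen_glycans: set[str] = set()

    def emit_glycan(entity: GlycanEntity, iri: str) -> None:
        if iri in seen_glycans:
            return
        seen_glycans.add(iri)
        if entity.is_sugar_nucleotide:
            typed(iri, "SugarNucleotide")
        else:
            typed(iri, "Saccharide")
            typed(iri, "SmallMolecule")
        g.add(iri, vocab.prop("displayName"), Literal(entity.display_name))
        if entity.wurcs:
            g.add(iri, vocab.prop("has_wurcs"), Literal(entity.wurcs))
        xref_iri = model.glycan_xref_iris[entity.glytoucan_accession]
        g.add(iri, vocab.prop("xref"), xref_iri)
        typed(xref_iri, "UnificationXref")
        g.add(xref_iri, vocab.prop("db"), Literal("GlyTouCan"))
        g.add(xref_iri, vocab.prop("id"), Literal(entity.glytoucan_accession))

    for position, step in enumerate(model.steps):
        spec = step.spec
        typed(step.reaction_iri, "BiochemicalReaction")
        g.add(step.reaction_iri, vocab.prop("left"), step.donor_iri)
        g.add(step.reaction_iri, vocab.prop("left"), step.acceptor_iri)
        g.add(step.reaction_iri, vocab.prop("right"), step.product_iri)

        typed(step.catalysis_iri, "Catalysis")
        g.add(step.catalysis_iri, vocab.prop("controlled"), step.reaction_iri)
        g.add(step.catalysis_iri, vocab.prop("controller"), step.enzyme_iri)

        typed(step.step_iri, "BiochemicalPathwayStep")
        g.add(step.step_iri, vocab.prop("stepConversion"), step.reaction_iri)
        if position + 1 < len(model.steps):
            g.add(step.step_iri, vocab.prop("nextStep"),
                  model.steps[position + 1].step_iri)
        g.add(model.pathway_iri, vocab.prop("pathwayOrder"), step.step_iri)
        if emit_pathway_component:
            g.add(model.pathway_iri, vocab.prop("pathwayComponent"), step.reaction_iri)

        typed(step.enzyme_iri, "Protein")
        g.add(step.enzyme_iri, vocab.prop("displayName"),
              Literal(spec.enzyme.display_name))

        emit_glycan(spec.donor, step.donor_iri)
        emit_glycan(spec.acceptor, step.acceptor_iri)
        emit_glycan(spec.product, step.product_iri)

        for citation in spec.citations:
            cite_iri = model.citation_xref_iris[(citation.database, citation.identifier)]
            g.add(step.reaction_iri, vocab.prop("xref"), cite_iri)
            typed(cite_iri, "PublicationXref")
            g.add(cite_iri, vocab.prop("db"), Literal(citation.database))
            g.add(cite_iri, vocab.prop("id"), Literal(citation.identifier))

        for xref in spec.enzyme.xrefs:
            # enzyme-level xrefs reuse the citation pool for publication refs
            if xref.kind == "publication":
                key = (xref.database, xref.identifier)
                if key in model.citation_xref_iris:
                    g.add(step.enzyme_iri, vocab.prop("xref"),
                          model.citation_xref_iris[key])
    return g
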