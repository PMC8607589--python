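# Methods

## The pathway model

`glycopath` describes the biosynthesis of a bacterial O-antigen repeat
unit as an ordered chain of glycosyl-transfer reactions.  The model's
assumptions, which double as its validation rules, are:

* **Linear assembly.** A k-residue repeat unit is built from a single
  priming monosaccharide by k−1 extensions; the product of step *i* is
  the acceptor of step *i+1*.  Branched assembly orders are not
  represented (see Limitations).
* **Single extension.** Each reaction adds exactly one monosaccharide:
  the product's residue count equals the acceptor's plus one.  Residue
  counts are read from the WURCS 2.0 header
  (`WURCS=<version>/<unique>,<residues>,<linkages>/…`); the RES/LIN body
  is carried opaquely because identity and counts are all the model
  needs.  We equate "monosaccharide count" with the header residue
  count — the only count available without full WURCS chemistry.
* **Explicit catalysis.** Every reaction is controlled by a
  glycosyltransferase through a `bp:Catalysis` node.
* **Global identity.** Every glycan is identified by a GlyTouCan
  accession (`G` + 5 digits + 2 uppercase letters; the pattern is
  configurable), used both as the instance IRI
  (`http://glytoucan.org/Structures/Glycans/<acc>`) and as the
  identifier of a `bp:UnificationXref`.

### Vocabulary

BioPAX Level 3 supplies the pathway vocabulary; two terms come from
outside it because BioPAX has no glycan classes: acceptors and products
are typed both GlycoRDF `glycan:Saccharide` and `bp:SmallMolecule`
(each node serves glycan-centric and pathway-centric consumers), and
donors are typed with a ChEBI sugar-nucleotide class.  The exact ChEBI
identifier is a **configuration point**: the shipped default binding is
`obo:CHEBI_25609`, overridable per deployment via `VocabularyMap` or the
TOML config file, and nothing in the package depends on which identifier
is chosen.  Enzymes are typed `bp:Protein`.  A step is tied to its
reaction with `bp:stepConversion` (the BioPAX property for
`BiochemicalPathwayStep`), display names use `bp:displayName`, and
WURCS strings are attached to glycan nodes as literals
(`glycan:has_wurcs`) so validation can run from the graph alone.
`bp:pathwayComponent` links are available behind a flag (default off);
step order alone is the default wiring.

### IRI minting

Instance IRIs are `<base>GC-<Class>-NNNNN` with one global,
monotonically increasing serial shared by all classes, so consecutive
instances of different classes get consecutive serials
(`GC-Pathway-00301`, `GC-BiochemicalReaction-00302`, …).  The base
namespace defaults to `https://example.org/glycopath/` and should be
overridden for real deployments.  Serials are allocated in a fixed
traversal order (pathway; per step reaction/catalysis/step; enzymes;
xrefs), which makes building a pure function of the inputs.

## Tables

The RDFization input is one CSV (RFC 4180, UTF-8) per class: subjects
in the leftmost column, property names (CURIEs or absolute IRIs) in the
header, values in cells.  Multi-valued cells use `|` (configurable);
a literal containing the separator escapes it with a backslash, so
write→read round-trips are exact.  Empty cells contribute no statement.

A cell value becomes a resource when it is an absolute IRI, a CURIE
under a declared prefix, or a bare GlyTouCan accession (resolved to the
repository IRI); otherwise it is a plain string literal.  Properties
listed in `literal_properties` are always literal; the default is
`{"bp:id"}`, because an xref identifier is a literal by definition even
when it looks like an accession.  Subjects are local ids resolved
against the base namespace unless already absolute.

## Turtle

The writer is deterministic by construction: prefixes sorted, subjects
sorted, predicates per subject sorted with `rdf:type` first (written
`a`), objects sorted with IRIs before literals, `;`/`,` grouping.  Two
equal graphs serialize to byte-identical documents, so diffs and
content hashes are meaningful.  Parsing is delegated to rdflib and
covers the emitted subset (prefixed names, angle-bracket IRIs, plain
and typed literals); blank nodes, collections and numeric shorthand are
rejected — the model emits none.  A plain literal and an
`xsd:string`-typed literal are normalized to the same value, matching
RDF 1.1 semantics and keeping round-trips exact.  N-Triples export is
offered for bulk loading; byte-stability is only promised for Turtle.

## Validation rules

| rule | checks | severity |
|------|--------|----------|
| R1 | product WURCS residues = acceptor's + 1, per reaction | error (warning when a WURCS is missing from the index) |
| R2 | two `bp:left` (one sugar nucleotide, one saccharide), one `bp:right` | error |
| R3 | one `bp:controlled` reaction and ≥ 1 `bp:controller` per catalysis | error |
| R4 | `bp:nextStep` forms one simple path over each pathway's steps | error |
| R5 | acceptor/product glycans typed Saccharide **and** SmallMolecule | error |
| R6 | every glycan has a UnificationXref with a pattern-valid accession | error |
| R7 | every subject has at least one `rdf:type` | error |

Rules run independently and collect all violations (no fail-fast); a
report with only warnings still counts as conforming.  R1 evaluates
only reactions whose participants R2 can identify, so one seeded defect
trips exactly one rule.  The WURCS index defaults to the
`glycan:has_wurcs` literals in the graph; a JSON sidecar can override
it for graphs produced elsewhere.  The priming acceptor of a pathway's
first reaction is an ordinary single-residue saccharide — no special
priming class exists.

## Queries

`evaluate()` computes the natural join of conjunctive triple patterns,
applies `equals`/`regex` filters (Python `re`, `search` semantics —
the verification filters are fixed strings, so dialect differences are
immaterial), then projection, DISTINCT and COUNT.  Row order is sorted,
making results pure functions of the graph.  The four canned queries:

1. **q1** — count of instances typed `bp:Pathway`; one pathway stands
   for one O-antigen.
2. **q2** — (pathway, name) rows; a nameless pathway yields an empty
   binding but is still counted, so `len(q2) == q1` always.
3. **q3** — a reaction's acceptor/donor/product, the donor being the
   `bp:left` typed as a sugar nucleotide; arity faults raise a
   structured error mirroring R2.
4. **q4** — membership of name-matched pathways via
   pathwayOrder → step → stepConversion → reaction: returns distinct
   (product glycan, enzyme) rows.  Donors are deliberately excluded
   from q4 — they are reaction-level detail, available via q3.

In the test suite the engine is cross-checked against an exhaustive
nested-loop matcher on randomized queries and against rdflib's SPARQL
engine on the canned queries; neither oracle is ever the
implementation.

## Synthetic data

The generator emulates a curated O-antigen collection: for each of n
pathways a k-residue repeat unit (defaults n=5, k=5, matching typical
serogroup repeat units and keeping a full pipeline run well under a
second), per-step sugar-nucleotide donors, WbbX-style enzyme names,
unique GlyTouCan-pattern accessions, PubMed-like citation integers and
header-consistent linear WURCS strings (residue counts 1..k along the
chain, donors 1; `linkages = residues − 1`).  All randomness flows from
one seed; identical specs yield byte-identical tables.  Tables are
derived from the built graph, so the table route and the direct model
route produce the same statements — a property the suite asserts.

What the generator does **not** emulate: real serogroup structures and
chemistry (WURCS bodies are placeholder tokens), branched repeat units,
shared intermediates between serogroups, curation noise (typos,
missing citations), and the real dataset's accession assignments.
Passing tests therefore demonstrate pipeline correctness on
structurally faithful data, not agreement with any particular curated
database content.  The study-scale acceptance run uses a synthetic
192-pathway antigen list of the same shape.

`mutate_fixture` plants exactly one defect per call, each paired with
one rule: `break_chain`→R2, `inflate_product`→R1 (it targets a terminal
product so only one reaction's arithmetic breaks),
`drop_controller`→R3, `cycle_steps`→R4 (needs a pathway with ≥ 2
steps), `bad_accession`→R6.

## Numerical and degenerate-input choices

* WURCS versions other than 2.0 are rejected by default; a permissive
  flag accepts any 2.x.  Leading/trailing whitespace is trimmed before
  parsing (CSV cells carry stray spaces); interior whitespace is not.
* A single-residue glycan has linkage count 0; the strict linearity
  check (`linkages = residues − 1`) is opt-in because branched or
  repeating structures legitimately differ.
* Serial numbers are capped at 5 digits (< 100000), matching the
  instance-id scheme; overflow is an error, not a wraparound.
* An empty CSV (no header) is an error; a header-only table is a valid
  empty table.  Duplicate subjects and ragged rows are named errors.
* Graph equality is statement-set equality; the prefix map is
  presentation metadata.  Merging graphs with conflicting bindings for
  the same prefix is an error rather than a silent rebind.

## Limitations

* R4 enforces strictly linear step chains; genuinely branched assembly
  orders would be flagged even if biologically real.
* The query layer is the verification subset only: no OPTIONAL, UNION,
  property paths, aggregation beyond COUNT, or federation.
* Turtle parsing covers the emitted subset, not arbitrary third-party
  documents.
* WURCS handling is header-only; no format conversion, canonicalization
  or residue chemistry.
* No live GlyTouCan registration, triple-store upload, or endpoint
  hosting; outputs are files.
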