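# glycopath

Semantic description of bacterial O-antigen biosynthesis pathways.

O-antigens — the serogroup-defining polysaccharides on the outer
membrane of Gram-negative bacteria such as *E. coli* — are assembled as
repeat units by stepwise glycosyl transfer: each glycosyltransferase
moves one monosaccharide from a sugar-nucleotide donor onto an acceptor
glycan, producing a glycan one residue longer.  Curated descriptions of
these pathways (glycan structures, enzymes, literature) exist mostly as
unstructured web content; `glycopath` is a toolkit for turning such
content, arranged in simple spreadsheet-style tables, into standard
semantic data that can be queried and shared.

It is aimed at glycobiology data curators and at anyone building or
checking BioPAX/RDF pathway datasets offline:

* **Data model** — BioPAX Level 3 classes (`bp:Pathway`,
  `bp:BiochemicalReaction`, `bp:Catalysis`, `bp:BiochemicalPathwayStep`,
  `bp:SmallMolecule`, xref classes) extended with GlycoRDF `Saccharide`
  and a ChEBI sugar-nucleotide class.  Each reaction carries the donor
  and acceptor as `bp:left` and the product as `bp:right`; catalysis is
  `bp:controlled`/`bp:controller`; step order uses `bp:pathwayOrder` and
  `bp:nextStep`.  Glycans are identified by GlyTouCan accessions, minted
  into IRIs under `http://glytoucan.org/Structures/Glycans/` and mirrored
  in `bp:UnificationXref` nodes; instance IRIs follow the
  `GC-<Class>-NNNNN` scheme (e.g. `GC-Pathway-00301`).
* **Tables → triples** — one CSV per class, subjects in the left column,
  property CURIEs in the header row, `|`-separated multi-values.
* **Deterministic Turtle** — sorted prefixes/subjects/predicates,
  `rdf:type` abbreviated to `a`, byte-identical output for equal graphs;
  parsing (rdflib-backed) round-trips exactly.
* **Validation** — seven structural rules (R1–R7), including the WURCS
  residue-count rule: for every reaction,
  `residues(product) = residues(acceptor) + 1`, read from the WURCS 2.0
  header `WURCS=<version>/<unique>,<residues>,<linkages>/…`.
* **Queries** — a conjunctive graph-pattern evaluator with
  `equals`/`regex` filters, plus the four canned verification queries:
  antigen count, antigen names, reaction composition, pathway membership.
* **Synthetic fixtures** — ECODAB-style pathway tables with known ground
  truth (and targeted mutations), so the whole pipeline is testable
  offline.

## Worked example

```sh
python examples/query_pathways.py
```

builds three synthetic pathways and runs the verification queries:

```
q1 — number of O-antigens: 3

q2 — antigen names:
?antigen        ?name
https://example.org/glycopath/GC-Pathway-00301  O-antigen 1A
https://example.org/glycopath/GC-Pathway-00331  O-antigen 2
https://example.org/glycopath/GC-Pathway-00361  O-antigen 3

q3 — components of GC-BiochemicalReaction-00302:
  acceptor: http://glytoucan.org/Structures/Glycans/G83810DA
  donor:    http://glytoucan.org/Structures/Glycans/G36463ZA
  product:  http://glytoucan.org/Structures/Glycans/G32098HE
  product residues - acceptor residues = 1 (single extension)

q4 — members of 'O-antigen 1A': 4 (glycan, enzyme) rows
```

q1/q2 recover the three generated pathways and their names.  q3 shows
one reaction's participants; the product is exactly one residue longer
than the acceptor, as the extension model requires.  q4 walks
pathwayOrder → step → reaction → catalysis for the pathway named
"O-antigen 1A" (a five-residue repeat unit) and returns its four
product glycans with the four distinct glycosyltransferases that make
them.

The same pipeline is available from the shell:

```sh
glycopath gen-fixtures --out tables --pathways 3 --residues 5 --seed 42
glycopath rdfize --in tables --out oantigens.ttl
glycopath validate oantigens.ttl
glycopath query oantigens.ttl q1
glycopath query oantigens.ttl q4 --name "O-antigen 1A"
```

Other examples: `build_o1a_pathway.py` (entity objects → Turtle),
`rdfize_tables.py` (CSV tables → merged graph), `validate_pathways.py`
(rules firing on seeded defects), `parse_wurcs_headers.py` (WURCS
header arithmetic).

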