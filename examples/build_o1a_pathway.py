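"""Build a four-step O-antigen pathway from entity objects and print
its Turtle serialization.

Models the O1A-style worked example: a five-residue repeat unit
assembled from one priming residue by four glycosyltransferases, each
transferring one monosaccharide from a sugar-nucleotide donor.
"""

from glycopath import (
    EnzymeEntity,
    GlycanEntity,
    PathwayStepSpec,
    XrefSpec,
    build_pathway,
    pathway_to_triples,
    serialize_turtle,
)


def saccharide(i: int) -> GlycanEntity:
    return GlycanEntity(
        local_id=f"S{i}",
        glytoucan_accession=f"G0000{i}AA",
        display_name=f"O1A intermediate {i}",
        wurcs=f"WURCS=2.0/{i},{i},{i - 1}/[x]/1/",
        roles=frozenset({"acceptor", "product"}),
    )


chain = [saccharide(i) for i in range(1, 6)]
enzymes = ["WbbL", "WbbJ", "WbbK", "WbbH"]
steps = [
    PathwayStepSpec(
        step_index=i,
        acceptor=chain[i - 1],
        donor=GlycanEntity(
            local_id=f"D{i}",
            glytoucan_accession=f"G1000{i}AA",
            display_name=f"UDP-sugar {i}",
            wurcs="WURCS=2.0/1,1,0/[x]/1/",
            roles=frozenset({"sugar_nucleotide"}),
        ),
        product=chain[i],
        enzyme=EnzymeEntity(local_id=f"E{i}", display_name=enzymes[i - 1]),
        citations=(XrefSpec("publication", "PubMed", str(30000000 + i)),),
    )
    for i in range(1, 5)
]

model = build_pathway("O-antigen 1A", steps, serial_start=301)
graph = pathway_to_triples(model)

print(f"pathway IRI: {model.pathway_iri}")
print(f"steps: {len(model.steps)}, statements: {len(graph)}")
print()
print(serialize_turtle(graph))
# The pathway instance is GC-Pathway-00301; each step contributes one
# BiochemicalReaction (two bp:left participants, one bp:right), one
# Catalysis naming the enzyme, and one BiochemicalPathwayStep chained by
# bp:nextStep (3 links for 4 steps).
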