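"""Run the four verification queries over an RDFized dataset.

q1 counts O-antigens (pathway instances), q2 lists their names, q3
decomposes one reaction into acceptor/donor/product, and q4 retrieves
the glycans and glycosyltransferases of a named pathway.
"""

from glycopath import (
    FixtureSpec,
    VocabularyMap,
    fixture_graph,
    q1_count_antigens,
    q2_antigen_names,
    q3_reaction_components,
    q4_pathway_members,
)
from glycopath.validator import build_wurcs_index
from glycopath.wurcs import residue_count

vocab = VocabularyMap.default()
graph, truth = fixture_graph(
    FixtureSpec(n_pathways=3, residues_per_repeat=5, seed=42,
                names=("O-antigen 1A", "O-antigen 2", "O-antigen 3"))
)

print("q1 — number of O-antigens:", q1_count_antigens(graph))
print("\nq2 — antigen names:")
print(q2_antigen_names(graph).to_tsv())

reaction = graph.subjects_of_type(vocab.class_iri("BiochemicalReaction"))[0]
parts = q3_reaction_components(graph, reaction)
wurcs = build_wurcs_index(graph)
delta = residue_count(wurcs[parts.product]) - residue_count(wurcs[parts.acceptor])
print(f"\nq3 — components of {reaction.rsplit('/', 1)[-1]}:")
print(f"  acceptor: {parts.acceptor}")
print(f"  donor:    {parts.donor}")
print(f"  product:  {parts.product}")
print(f"  product residues - acceptor residues = {delta} (single extension)")

members = q4_pathway_members(graph, "O-antigen 1A")
print(f"\nq4 — members of 'O-antigen 1A': {len(members)} (glycan, enzyme) rows")
print(members.to_tsv())
# Three pathways were generated, so q1 prints 3 and q2 three names; every
# reaction product is one residue longer than its acceptor; the O1A-style
# pathway (5-residue repeat unit) yields 4 rows: 4 intermediate/product
# glycans made by 4 distinct glycosyltransferases.
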