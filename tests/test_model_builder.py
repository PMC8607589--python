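import pytest

from glycopath.errors import (
    ChainError,
    InvalidAccessionError,
    SerialOverflowError,
    StepIndexError,
    UnknownClassError,
)
from glycopath.model_builder import (
    EnzymeEntity,
    GlycanEntity,
    PathwayStepSpec,
    VocabularyMap,
    XrefSpec,
    build_pathway,
    glytoucan_iri,
    mint_instance_iri,
    pathway_to_triples,
)
from glycopath.rdf_graph import RDF_TYPE, Literal
from glycopath.validator import validate_graph

NS = "https://example.org/glycopath/"


def make_glycan(i, m, sugar_nucleotide=False):
    roles = {"sugar_nucleotide"} if sugar_nucleotide else {"acceptor", "product"}
    return GlycanEntity(
        local_id=f"g{i}",
        glytoucan_accession=f"G{i:05d}AB",
        display_name=f"glycan {i}",
        wurcs=f"WURCS=2.0/{m},{m},{m - 1}/[x]/1/",
        roles=frozenset(roles),
    )


def make_steps(n):
    """n chained steps building an (n+1)-residue glycan."""
    chain = [make_glycan(i, i) for i in range(1, n + 2)]
    steps = []
    for i in range(1, n + 1):
        steps.append(
            PathwayStepSpec(
                step_index=i,
                acceptor=chain[i - 1],
                donor=make_glycan(100 + i, 1, sugar_nucleotide=True),
                product=chain[i],
                enzyme=EnzymeEntity(local_id=f"e{i}", display_name=f"Wbb{i}"),
                citations=(XrefSpec("publication", "PubMed", str(30000000 + i)),),
            )
        )
    return steps


class TestIriMinting:
    def test_paper_style_instance_ids(self):
        assert (
            mint_instance_iri("BiochemicalReaction", 302, NS)
            == NS + "GC-BiochemicalReaction-00302"
        )
        assert mint_instance_iri("Pathway", 301, NS) == NS + "GC-Pathway-00301"
        assert mint_instance_iri("Pathway", 0, NS) == NS + "GC-Pathway-00000"

    def test_unknown_class_and_serial_overflow(self):
        with pytest.raises(UnknownClassError):
            mint_instance_iri("Widget", 1, NS)
        with pytest.raises(SerialOverflowError):
            mint_instance_iri("Pathway", 100000, NS)

    def test_glytoucan_iri(self):
        assert (
            glytoucan_iri("G12345AB")
            == "http://glytoucan.org/Structures/Glycans/G12345AB"
        )
        assert glytoucan_iri("G00000AA").endswith("/G00000AA")
        with pytest.raises(InvalidAccessionError):
            glytoucan_iri("12345")


class TestBuildPathway:
    @pytest.mark.parametrize("n_steps", [1, 4])
    def test_one_instance_of_each_class_per_step(self, n_steps):
        model = build_pathway("O-antigen X", make_steps(n_steps), 301, NS)
        assert len(model.steps) == n_steps
        assert model.pathway_iri == NS + "GC-Pathway-00301"
        assert len({s.reaction_iri for s in model.steps}) == n_steps
        assert len({s.catalysis_iri for s in model.steps}) == n_steps
        assert len({s.step_iri for s in model.steps}) == n_steps

    def test_serials_continue_across_pathways(self):
        first = build_pathway("A", make_steps(2), 301, NS)
        second = build_pathway("B", make_steps(2), first.serial_end, NS)
        minted_first = {first.pathway_iri} | {
            iri
            for s in first.steps
            for iri in (s.reaction_iri, s.catalysis_iri, s.step_iri, s.enzyme_iri)
        }
        assert second.pathway_iri not in minted_first

    def test_broken_chain_names_the_steps(self):
        steps = make_steps(3)
        steps[1] = PathwayStepSpec(
            step_index=2,
            acceptor=make_glycan(50, 2),  # not step 1's product
            donor=steps[1].donor,
            product=steps[1].product,
            enzyme=steps[1].enzyme,
        )
        with pytest.raises(ChainError, match="step 1.*step 2"):
            build_pathway("broken", steps, 301, NS)

    def test_duplicate_and_gapped_step_indices_rejected(self):
        steps = make_steps(2)
        dup = [steps[0], steps[0]]
        with pytest.raises(StepIndexError):
            build_pathway("dup", dup, 301, NS)
        gap = [steps[1]]  # starts at index 2
        with pytest.raises(StepIndexError):
            build_pathway("gap", gap, 301, NS)

    def test_donor_must_be_sugar_nucleotide(self):
        with pytest.raises(ValueError, match="sugar_nucleotide"):
            PathwayStepSpec(
                step_index=1,
                acceptor=make_glycan(1, 1),
                donor=make_glycan(2, 1),  # plain saccharide
                product=make_glycan(3, 2),
                enzyme=EnzymeEntity(local_id="e", display_name="WbbA"),
            )


class TestPathwayToTriples:
    def graph(self, n_steps, **kwargs):
        model = build_pathway("O-antigen X", make_steps(n_steps), 301, NS)
        return model, pathway_to_triples(model, **kwargs)

    def test_reaction_has_two_lefts_and_one_right(self, vocab):
        model, g = self.graph(1)
        reaction = model.steps[0].reaction_iri
        assert len(g.objects(reaction, vocab.prop("left"))) == 2
        assert len(g.objects(reaction, vocab.prop("right"))) == 1

    def test_linear_chain_has_n_minus_one_next_steps(self, vocab):
        _, g = self.graph(4)
        next_steps = [s for s in g if s.predicate == vocab.prop("nextStep")]
        assert len(next_steps) == 3

    def test_every_subject_is_typed(self):
        _, g = self.graph(3)
        for subject in g.subjects():
            assert g.types_of(subject), f"{subject} lacks rdf:type"

    def test_glycans_dual_typed_and_xrefed(self, vocab):
        model, g = self.graph(2)
        for step in model.steps:
            for glycan in (step.acceptor_iri, step.product_iri):
                types = g.types_of(glycan)
                assert vocab.class_iri("Saccharide") in types
                assert vocab.class_iri("SmallMolecule") in types
            assert vocab.class_iri("SugarNucleotide") in g.types_of(step.donor_iri)
            xrefs = g.objects(step.product_iri, vocab.prop("xref"))
            assert any(
                vocab.class_iri("UnificationXref") in g.types_of(x)
                for x in xrefs
                if isinstance(x, str)
            )

    def test_determinism(self):
        _, g1 = self.graph(4)
        _, g2 = self.graph(4)
        assert g1 == g2

    def test_counts_conserved(self, vocab):
        n = 4
        _, g = self.graph(n)
        assert len(g.subjects_of_type(vocab.class_iri("BiochemicalReaction"))) == n
        assert len(g.subjects_of_type(vocab.class_iri("Catalysis"))) == n
        assert len(g.subjects_of_type(vocab.class_iri("BiochemicalPathwayStep"))) == n

    def test_pathway_component_flag(self, vocab):
        model, off = self.graph(2)
        assert not [s for s in off if s.predicate == vocab.prop("pathwayComponent")]
        on = pathway_to_triples(model, emit_pathway_component=True)
        assert len([s for s in on if s.predicate == vocab.prop("pathwayComponent")]) == 2

    def test_display_names_emitted_as_literals(self, vocab):
        model, g = self.graph(1)
        names = g.objects(model.pathway_iri, vocab.prop("displayName"))
        assert names == [Literal("O-antigen X")]

    def test_built_graph_passes_validation(self):
        _, g = self.graph(4)
        report = validate_graph(g)
        assert report.ok and not report.violations
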