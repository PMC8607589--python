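import random

import pytest

from _oracles import candidate_product, oracle_evaluate
from glycopath import merge
from glycopath.errors import ArityError, QueryError
from glycopath.model_builder import BP_NS, VocabularyMap
from glycopath.query import (
    Filter,
    QuerySpec,
    TriplePattern,
    evaluate,
    q1_count_antigens,
    q2_antigen_names,
    q3_reaction_components,
    q4_pathway_members,
)
from glycopath.rdf_graph import RDF_TYPE, Literal, TripleGraph, to_rdflib
from glycopath.synthetic import FixtureSpec, fixture_graph
from glycopath.wurcs import residue_count


def random_query(rng: random.Random, graph: TripleGraph) -> QuerySpec:
    """A random conjunctive query whose constants are sampled from the
    graph so joins have a chance of matching.  Every pattern keeps at
    least one constant slot (all-wildcard patterns are unrealistic and
    explode the oracle's search space)."""
    statements = sorted(graph, key=repr)
    n_patterns = rng.randint(1, 4)
    variables = [f"?v{i}" for i in range(rng.randint(1, 3))]
    patterns = []
    for _ in range(n_patterns):
        st = rng.choice(statements)
        slots = []
        constant_slots = 0
        for value in (st.subject, st.predicate, st.object):
            if rng.random() < 0.55:
                slots.append(value)
                constant_slots += 1
            else:
                slots.append(rng.choice(variables))
        if constant_slots == 0:
            slots[1] = st.predicate
        patterns.append(TriplePattern(*slots))
    bound = set()
    for p in patterns:
        bound |= p.variables()
    filters = []
    if bound and rng.random() < 0.4:
        var = rng.choice(sorted(bound))
        if rng.random() < 0.5:
            filters.append(Filter(var, "regex", rng.choice(["O-antigen", "GC-", "a", "zzz"])))
        else:
            st = rng.choice(statements)
            filters.append(Filter(var, "equals", str(st.subject)))
    projection = tuple(sorted(bound)) if bound and rng.random() < 0.7 else ()
    return QuerySpec(
        patterns=tuple(patterns),
        filters=tuple(filters),
        projection=projection,
        distinct=rng.random() < 0.5,
        count=rng.random() < 0.2,
    )


class TestEvaluate:
    def test_type_pattern_counts_pathways(self, small_fixture, vocab):
        _, graph, truth = small_fixture
        spec = QuerySpec(
            patterns=(TriplePattern("?s", RDF_TYPE, vocab.class_iri("Pathway")),),
            projection=("?s",),
        )
        assert len(evaluate(graph, spec)) == truth.n_pathways

    def test_empty_graph_matches_nothing(self):
        spec = QuerySpec(patterns=(TriplePattern("?s", "?p", "?o"),))
        assert len(evaluate(TripleGraph(), spec)) == 0

    def test_join_on_shared_variable_matches_oracle(self, o1a_fixture, vocab):
        _, graph, _ = o1a_fixture
        spec = QuerySpec(
            patterns=(
                TriplePattern("?c", vocab.prop("controlled"), "?r"),
                TriplePattern("?r", vocab.prop("right"), "?g"),
            ),
            projection=("?r", "?g"),
        )
        assert evaluate(graph, spec).rows == oracle_evaluate(graph, spec)

    def test_unbound_projection_rejected(self, small_fixture):
        _, graph, _ = small_fixture
        spec = QuerySpec(
            patterns=(TriplePattern("?s", "?p", "?o"),), projection=("?missing",)
        )
        with pytest.raises(QueryError):
            evaluate(graph, spec)

    def test_invalid_regex_rejected(self, small_fixture):
        _, graph, _ = small_fixture
        spec = QuerySpec(
            patterns=(TriplePattern("?s", RDF_TYPE, "?o"),),
            filters=(Filter("?s", "regex", "("),),
        )
        with pytest.raises(QueryError):
            evaluate(graph, spec)

    def test_oracle_equivalence_on_randomized_queries(self):
        """The join engine agrees with an exhaustive nested-loop matcher
        on randomized conjunctive queries over fixture graphs."""
        rng = random.Random(20240917)
        graphs = [
            fixture_graph(FixtureSpec(n_pathways=n, residues_per_repeat=k, seed=s))[0]
            for n, k, s in [(1, 3, 1), (2, 4, 2), (3, 5, 3)]
        ]
        assert all(len(g) <= 500 for g in graphs)
        checked = 0
        while checked < 210:
            graph = rng.choice(graphs)
            spec = random_query(rng, graph)
            if candidate_product(graph, spec) > 300_000:
                continue
            result = evaluate(graph, spec)
            assert result.rows == oracle_evaluate(graph, spec)
            checked += 1

    def test_monotonicity_of_filter_free_queries(self, small_fixture, vocab):
        _, graph, _ = small_fixture
        spec = QuerySpec(
            patterns=(TriplePattern("?s", RDF_TYPE, "?t"),), projection=("?s", "?t")
        )
        partial = TripleGraph(sorted(graph.statements, key=repr)[: len(graph) // 2],
                              graph.prefixes)
        before = set(evaluate(partial, spec).rows)
        after = set(evaluate(graph, spec).rows)
        assert before <= after


class TestCannedQueries:
    def test_q1_counts_generated_pathways(self, small_fixture):
        _, graph, truth = small_fixture
        assert q1_count_antigens(graph) == truth.n_pathways

    def test_q1_empty_graph(self):
        assert q1_count_antigens(TripleGraph()) == 0

    def test_q2_one_named_row_per_pathway(self, small_fixture):
        _, graph, truth = small_fixture
        table = q2_antigen_names(graph)
        assert len(table) == truth.n_pathways
        names = sorted(row[1].lexical_form for row in table.rows)
        assert names == sorted(truth.pathway_names)

    def test_q2_unnamed_pathway_still_counted(self, vocab):
        g = TripleGraph()
        g.add("https://e.org/p1", RDF_TYPE, vocab.class_iri("Pathway"))
        table = q2_antigen_names(g)
        assert len(table) == 1 == q1_count_antigens(g)
        assert table.rows[0][1] == Literal("")

    def test_q1_equals_q2_rowcount_everywhere(self, small_fixture, o1a_fixture):
        for _, graph, _ in (small_fixture, o1a_fixture):
            assert q1_count_antigens(graph) == len(q2_antigen_names(graph))

    def test_q3_returns_three_distinct_participants(self, o1a_fixture, vocab):
        _, graph, _ = o1a_fixture
        for reaction in graph.subjects_of_type(vocab.class_iri("BiochemicalReaction")):
            parts = q3_reaction_components(graph, reaction)
            assert len({parts.acceptor, parts.donor, parts.product}) == 3

    def test_q3_product_one_residue_beyond_acceptor(self, o1a_fixture, vocab):
        _, graph, truth = o1a_fixture
        for reaction in graph.subjects_of_type(vocab.class_iri("BiochemicalReaction")):
            parts = q3_reaction_components(graph, reaction)
            delta = residue_count(truth.wurcs_by_iri[parts.product]) - residue_count(
                truth.wurcs_by_iri[parts.acceptor]
            )
            assert delta == 1

    def test_q3_arity_error_on_two_donor_lefts(self, vocab):
        g = TripleGraph()
        r = "https://e.org/r1"
        g.add(r, RDF_TYPE, vocab.class_iri("BiochemicalReaction"))
        for d in ("https://e.org/d1", "https://e.org/d2"):
            g.add(r, vocab.prop("left"), d)
            g.add(d, RDF_TYPE, vocab.class_iri("SugarNucleotide"))
        g.add(r, vocab.prop("right"), "https://e.org/p")
        with pytest.raises(ArityError):
            q3_reaction_components(g, r)

    def test_q4_named_pathway_membership(self, o1a_fixture):
        _, graph, truth = o1a_fixture
        table = q4_pathway_members(graph, "O-antigen 1A")
        assert len(table) == 4  # four extension steps
        assert len({row[1] for row in table.rows}) == 4  # four distinct enzymes

    def test_q4_no_match_and_invalid_regex(self, o1a_fixture):
        _, graph, _ = o1a_fixture
        assert len(q4_pathway_members(graph, "no such antigen")) == 0
        with pytest.raises(QueryError):
            q4_pathway_members(graph, "(")

    def test_q4_wildcard_is_union_of_memberships(self):
        graph, truth = fixture_graph(
            FixtureSpec(n_pathways=2, residues_per_repeat=(3, 5), seed=11,
                        names=("O-antigen 7", "O-antigen 8"))
        )
        union = set(q4_pathway_members(graph, ".*").rows)
        by_name = set(q4_pathway_members(graph, "O-antigen 7").rows) | set(
            q4_pathway_members(graph, "O-antigen 8").rows
        )
        assert union == by_name
        assert len(union) == truth.total_reactions


class TestSparqlCrossCheck:
    """rdflib's SPARQL engine as an independent oracle for the canned
    queries (it is never the implementation)."""

    def test_q1_matches_sparql_count(self, small_fixture):
        _, graph, _ = small_fixture
        rg = to_rdflib(graph)
        rows = list(
            rg.query(
                "SELECT (COUNT(DISTINCT ?p) AS ?n) WHERE { ?p a <%sPathway> }" % BP_NS
            )
        )
        assert int(rows[0][0]) == q1_count_antigens(graph)

    def test_q4_matches_sparql_join(self, o1a_fixture):
        _, graph, _ = o1a_fixture
        rg = to_rdflib(graph)
        sparql = (
            "PREFIX bp: <%s>\n"
            "SELECT DISTINCT ?glycan ?enzyme WHERE {\n"
            "  ?p a bp:Pathway ; bp:displayName ?name ; bp:pathwayOrder ?step .\n"
            "  ?step bp:stepConversion ?r .\n"
            "  ?r bp:right ?glycan .\n"
            "  ?cat bp:controlled ?r ; bp:controller ?enzyme .\n"
            '  FILTER regex(?name, "O-antigen 1A")\n'
            "}" % BP_NS
        )
        sparql_rows = {(str(g), str(e)) for g, e in rg.query(sparql)}
        ours = {
            (row[0], row[1]) for row in q4_pathway_members(graph, "O-antigen 1A").rows
        }
        assert sparql_rows == ours
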