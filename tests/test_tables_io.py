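import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopath import merge
from glycopath.errors import (
    ConfigurationError,
    DuplicateSubjectError,
    EmptyTableError,
    TableArityError,
)
from glycopath.rdf_graph import Literal, RDF_TYPE
from glycopath.tables_io import (
    InstanceTable,
    TableRow,
    read_instance_table,
    table_to_triples,
    write_instance_table,
)


def roundtrip(table):
    sink = io.StringIO()
    write_instance_table(table, sink)
    return read_instance_table(sink.getvalue(), table.class_name)


class TestReadWrite:
    def test_structural_read(self):
        csv_text = (
            "subject,bp:left,bp:right\n"
            "R1,a,b\nR2,c,d\nR3,e,f\n"
        )
        table = read_instance_table(csv_text, "BiochemicalReaction")
        assert table.property_names == ["bp:left", "bp:right"]
        assert len(table.rows) == 3
        assert table.rows[0].values == {"bp:left": ["a"], "bp:right": ["b"]}

    def test_multivalue_cell_splits_on_separator(self):
        table = read_instance_table(
            'subject,bp:left\nR1,G12345AB|G54321BA\n', "BiochemicalReaction"
        )
        assert table.rows[0].values["bp:left"] == ["G12345AB", "G54321BA"]

    def test_empty_cells_yield_no_value(self):
        table = read_instance_table("subject,p,q\nR1,,x\n", "C")
        assert "p" not in table.rows[0].values

    def test_duplicate_subject_rejected(self):
        with pytest.raises(DuplicateSubjectError, match="R1"):
            read_instance_table("subject,p\nR1,a\nR1,b\n", "C")

    def test_arity_mismatch_rejected(self):
        with pytest.raises(TableArityError):
            read_instance_table("subject,p,q\nR1,a\n", "C")

    def test_empty_source_rejected(self):
        with pytest.raises(EmptyTableError):
            read_instance_table("", "C")

    def test_header_only_roundtrip(self):
        table = InstanceTable(class_name="C", property_names=["p", "q"])
        assert roundtrip(table) == table

    def test_separator_inside_literal_survives_roundtrip(self):
        table = InstanceTable(
            class_name="C",
            property_names=["p"],
            rows=[TableRow("s1", {"p": ["a|b", "plain", "back\\slash"]})],
        )
        assert roundtrip(table) == table

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.lists(
                st.text(
                    alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
                    min_size=1,
                ),
                min_size=1,
                max_size=3,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_roundtrip_identity_property(self, cells):
        table = InstanceTable(
            class_name="C",
            property_names=[f"p{i}" for i in range(len(cells))],
            rows=[TableRow("s1", {f"p{i}": v for i, v in enumerate(cells)})],
        )
        assert roundtrip(table) == table


class TestTableToTriples:
    def test_type_plus_value_count(self, vocab):
        table = InstanceTable(
            class_name="Pathway",
            property_names=["bp:displayName", "bp:pathwayOrder"],
            rows=[TableRow("P1", {"bp:displayName": ["O-antigen 1"],
                                  "bp:pathwayOrder": ["S1"]})],
        )
        g = table_to_triples(table, vocab)
        assert len(g) == 3  # 1 rdf:type + 2 values

    def test_all_cells_empty_yields_types_only(self, vocab):
        table = InstanceTable(
            class_name="Pathway",
            property_names=["bp:displayName"],
            rows=[TableRow(f"P{i}", {}) for i in range(4)],
        )
        g = table_to_triples(table, vocab)
        assert len(g) == 4
        assert all(s.predicate == RDF_TYPE for s in g)

    def test_multivalued_cell_expands_to_one_statement_each(self, vocab):
        table = InstanceTable(
            class_name="BiochemicalReaction",
            property_names=["bp:left"],
            rows=[TableRow("R1", {"bp:left": ["G12345AB", "G54321BA"]})],
        )
        g = table_to_triples(table, vocab)
        lefts = g.objects(
            vocab.prefix_to_namespace[""] + "R1",
            vocab.prop("left"),
        )
        assert len(lefts) == 2

    def test_triple_count_equals_rows_plus_cell_multiplicities(self, clean_tables):
        tables, _ = clean_tables
        for table in tables.values():
            g = table_to_triples(table)
            expected = len(table.rows) + sum(
                len(v) for row in table.rows for v in row.values.values()
            )
            assert len(g) == expected

    def test_object_vs_literal_discrimination(self, vocab):
        table = InstanceTable(
            class_name="Saccharide",
            property_names=["bp:xref", "bp:displayName", "bp:id"],
            rows=[
                TableRow(
                    "s1",
                    {
                        "bp:xref": ["G12345AB", "https://example.org/x"],
                        "bp:displayName": ["just a name"],
                        "bp:id": ["G12345AB"],  # forced literal
                    },
                )
            ],
        )
        g = table_to_triples(table, vocab)
        subject = vocab.prefix_to_namespace[""] + "s1"
        xrefs = g.objects(subject, vocab.prop("xref"))
        assert "http://glytoucan.org/Structures/Glycans/G12345AB" in xrefs
        assert "https://example.org/x" in xrefs
        assert g.objects(subject, vocab.prop("displayName")) == [Literal("just a name")]
        assert g.objects(subject, vocab.prop("id")) == [Literal("G12345AB")]

    def test_unresolvable_prefix_names_the_prefix(self, vocab):
        table = InstanceTable(
            class_name="Pathway",
            property_names=["xx:whatever"],
            rows=[TableRow("P1", {"xx:whatever": ["v"]})],
        )
        with pytest.raises(ConfigurationError, match="xx"):
            table_to_triples(table, vocab)

    def test_fixture_tables_reproduce_the_model_graph(self, small_fixture):
        """RDFizing the emitted class tables yields exactly the graph
        built directly from the pathway models."""
        from glycopath import graph_to_tables

        _, graph, _ = small_fixture
        tables = graph_to_tables(graph)
        rebuilt = merge([table_to_triples(t) for t in tables.values()])
        assert rebuilt == graph
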