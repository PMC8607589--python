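import pytest

from glycopath import (
    FixtureSpec,
    VocabularyMap,
    fixture_graph,
    generate_fixture,
)


@pytest.fixture(scope="session")
def vocab():
    return VocabularyMap.default()


@pytest.fixture(scope="session")
def small_fixture():
    """3 pathways x 5-residue repeat units: 4 reactions each."""
    spec = FixtureSpec(n_pathways=3, residues_per_repeat=5, seed=42)
    graph, truth = fixture_graph(spec)
    return spec, graph, truth


@pytest.fixture(scope="session")
def o1a_fixture():
    """One pathway shaped like the O1A worked example: a five-residue
    repeat unit assembled in four single-residue extension steps."""
    spec = FixtureSpec(
        n_pathways=1, residues_per_repeat=5, seed=1, names=("O-antigen 1A",)
    )
    graph, truth = fixture_graph(spec)
    return spec, graph, truth


@pytest.fixture()
def clean_tables():
    spec = FixtureSpec(n_pathways=2, residues_per_repeat=4, seed=7)
    return generate_fixture(spec)
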