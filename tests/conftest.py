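import pytest

from ontogda.kg_builder import KGSources
from ontogda.simulate import FixtureSpec, make_fixture_bundle


@pytest.fixture(scope="session")
def tiny_spec() -> FixtureSpec:
    """Small bundle used by most structural tests: fast to generate, large
    enough to have non-trivial branches, links and annotations."""
    return FixtureSpec(
        n_classes=40,
        n_classes_go=30,
        n_branch_roots=3,
        n_branch_roots_go=2,
        n_genes=12,
        n_diseases=8,
        gene_hp_annotations=2,
        gene_go_annotations=4,
        disease_hp_annotations=4,
        n_cross_links=6,
        positive_rate=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle(tiny_spec):
    return make_fixture_bundle(tiny_spec)


@pytest.fixture(scope="session")
def sources(bundle) -> KGSources:
    return KGSources(
        hp_ontology=bundle.hp_ontology,
        go_ontology=bundle.go_ontology,
        gene_hp_annotations=bundle.gene_hp_annotations,
        gene_go_annotations=bundle.gene_go_annotations,
        disease_hp_annotations=bundle.disease_hp_annotations,
        logical_definitions=bundle.logical_definitions,
        mappings=bundle.mappings,
        go_prefix="GOX",
    )
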