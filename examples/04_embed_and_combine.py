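"""Embed a knowledge graph with each method and fuse a gene-disease pair.

All four engines emit 200-dimensional vectors by default; the binary
operators turn a (gene, disease) vector pair into one classifier input —
Hadamard keeps the dimension, concatenation doubles it.
"""

from ontogda import (
    FixtureSpec,
    KGSources,
    KGVariantSpec,
    build_variant,
    combine,
    cosine_similarity,
    embed,
    make_fixture_bundle,
)

bundle = make_fixture_bundle(FixtureSpec(
    n_classes=60, n_classes_go=40, n_genes=20, n_diseases=10,
    gene_go_annotations=6, disease_hp_annotations=6, n_cross_links=12, seed=3,
))
sources = KGSources(
    hp_ontology=bundle.hp_ontology,
    go_ontology=bundle.go_ontology,
    gene_hp_annotations=bundle.gene_hp_annotations,
    gene_go_annotations=bundle.gene_go_annotations,
    disease_hp_annotations=bundle.disease_hp_annotations,
    logical_definitions=bundle.logical_definitions,
    mappings=bundle.mappings,
    go_prefix="GOX",
)
kg = build_variant(KGVariantSpec.named("HPs+GO+LD"), sources)

for method in ("rdf2vec", "axiom-sentence", "transe", "distmult"):
    table = embed(kg, method=method, dim=200, seed=3, n_walks=50, depth=3, epochs=5)
    g, d = table["G0000"], table["D0000"]
    print(f"{method:14s} vectors={len(table.vectors):4d} dim={table.dimension} "
          f"cos(G0000,D0000)={cosine_similarity(g, d):+.3f}")

g, d = table["G0000"], table["D0000"]
for op in ("hadamard", "average", "weighted-L1", "weighted-L2", "concatenation"):
    print(f"{op:14s} pair vector size = {combine(g, d, op).size}")
# Walk-based embeddings cover the walked entities and every token they meet;
# the triple models embed all registered entities.
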