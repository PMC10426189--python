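"""Knowledge-graph assembly: virtual-root merge, logical-definition handling,
mapping filtering, annotation attachment, branch ablation and the variant
algebra."""

import networkx as nx
import pytest

from ontogda.kg_builder import (
    EQUIVALENT_TO,
    IS_A,
    VIRTUAL_ROOT,
    BranchAblation,
    KGBuildError,
    KGSources,
    KGVariantSpec,
    ablate_branch,
    add_full_logical_definitions,
    attach_annotations,
    build_variant,
    filter_mappings,
    kg_statistics,
    merge_with_virtual_root,
    simplify_logical_definitions,
    strip_logical_definitions,
)
from ontogda.ontology_io import (
    AnnotationRecord,
    LogicalDefinition,
    MappingRecord,
    OntologyGraph,
)


def ontology(prefix: str, n: int, roots: int = 1) -> OntologyGraph:
    ids = [f"{prefix}:{i}" for i in range(1, n + 1)]
    g = OntologyGraph(classes=set(ids))
    for i, cls in enumerate(ids):
        if i >= roots:
            g.is_a.add((cls, ids[i - 1]))
    g.validate()
    return g


class TestMerge:
    def test_single_ontology(self):
        kg = merge_with_virtual_root([ontology("A", 3)])
        assert len(kg.entities) == 4  # 3 classes + virtual root
        assert sum(1 for _, p, _ in kg.triples if p == IS_A) == 3

    def test_two_ontologies(self):
        kg = merge_with_virtual_root([ontology("A", 3), ontology("B", 4)])
        assert len(kg.entities) == 8
        into_root = [t for t in kg.triples if t[2] == VIRTUAL_ROOT]
        assert len(into_root) == 2

    def test_five_subontology_roots(self):
        """Five phenotype subontology roots each hang off the virtual root."""
        g = OntologyGraph(classes={f"HP:{i}" for i in range(5)})
        kg = merge_with_virtual_root([g])
        assert sum(1 for t in kg.triples if t[2] == VIRTUAL_ROOT) == 5
        assert all("merge" in kg.provenance[t] for t in kg.triples if t[2] == VIRTUAL_ROOT)

    def test_collision_detected(self):
        with pytest.raises(KGBuildError, match="overlapping"):
            merge_with_virtual_root([ontology("A", 3), ontology("A", 2)])


class TestLogicalDefinitionOps:
    def lds(self):
        return [
            LogicalDefinition("A:1", "x", (("GO:10", "GO"),)),
            LogicalDefinition("A:2", "y", (("PATO:1", "PATO"), ("GO:11", "GO"))),
        ]

    def test_strip_inverts_add(self):
        kg = merge_with_virtual_root([ontology("A", 3)])
        enriched = add_full_logical_definitions(kg, self.lds())
        assert enriched.triples > kg.triples
        stripped = strip_logical_definitions(enriched, self.lds())
        assert stripped.triples == kg.triples
        # class count unchanged by stripping
        assert sum(1 for k in stripped.entities.values() if k == "class") >= 3

    def test_strip_is_idempotent_and_empty_is_identity(self):
        kg = add_full_logical_definitions(
            merge_with_virtual_root([ontology("A", 3)]), self.lds()
        )
        once = strip_logical_definitions(kg, self.lds())
        twice = strip_logical_definitions(once, self.lds())
        assert once.triples == twice.triples
        assert strip_logical_definitions(kg, []).triples == kg.triples

    def test_simplify_hearing_impairment(self):
        """The complex axiom collapses to one direct equivalence between the
        phenotype class and the referenced GO class."""
        ld = LogicalDefinition(
            "HP:0000365",
            "has-part some (decreased-rate and inheres-in some GO:0007605)",
            (("PATO:0000911", "PATO"), ("GO:0007605", "GO"), ("PATO:0000460", "PATO")),
        )
        assert simplify_logical_definitions([ld], "GO") == [
            ("HP:0000365", EQUIVALENT_TO, "GO:0007605")
        ]

    def test_simplify_skips_foreign_only(self):
        ld = LogicalDefinition("HP:1", "x", (("PATO:1", "PATO"),))
        assert simplify_logical_definitions([ld], "GO") == []

    def test_simplify_counts_brute_force(self):
        lds = [
            LogicalDefinition(f"HP:{i}", "x", refs)
            for i, refs in enumerate(
                [
                    (("PATO:1", "PATO"),),
                    (("GO:1", "GO"),),
                    (("GO:2", "GO"), ("GO:3", "GO")),  # two target refs -> two triples
                    (("CHEBI:1", "CHEBI"),),
                    (("GO:4", "GO"), ("PATO:2", "PATO")),
                ]
                + [(("PATO:9", "PATO"),)] * 5
            )
        ]
        expected = sum(
            1 for ld in lds for _, pfx in ld.referenced_classes if pfx == "GO"
        )
        out = simplify_logical_definitions(lds, "GO")
        assert len(out) == expected == 4


class TestFilterMappings:
    def records(self):
        return [
            MappingRecord("HP:1", "GO:1", 0.75),
            MappingRecord("HP:2", "GO:2", 0.80),
            MappingRecord("HP:3", "GO:3", 0.90),
        ]

    def test_inclusive_boundary(self):
        kept = filter_mappings(self.records(), 0.8)
        assert [m.confidence for m in kept] == [0.80, 0.90]

    def test_zero_keeps_all_one_keeps_none(self):
        assert len(filter_mappings(self.records(), 0.0)) == 3
        assert filter_mappings(self.records(), 1.0) == []


class TestAnnotations:
    def test_attach_and_deduplicate(self):
        kg = merge_with_virtual_root([ontology("A", 3)])
        ann = [
            AnnotationRecord("g1", "A:1", "gene"),
            AnnotationRecord("g1", "A:2", "gene"),
            AnnotationRecord("g2", "A:1", "gene"),
            AnnotationRecord("g2", "A:1", "gene"),  # duplicate row
        ]
        out = attach_annotations(kg, ann)
        ann_triples = out.triples_with_tag("annotation")
        assert len(ann_triples) == 3
        assert sum(1 for k in out.entities.values() if k == "gene") == 2

    def test_missing_class_fails(self):
        kg = merge_with_virtual_root([ontology("A", 3)])
        with pytest.raises(KGBuildError, match="absent"):
            attach_annotations(kg, [AnnotationRecord("g1", "B:9", "gene")])


class TestAblation:
    def toy(self):
        # root X:1 -> X:2 -> ... chain; branch root X:3 covers X:3..X:6
        g = ontology("X", 6)
        ann = [AnnotationRecord(f"g{i}", f"X:{cls}", "gene") for i, cls in enumerate([1, 2, 3, 4, 4, 5, 5, 6, 6, 6])]
        return g, ann

    def test_remove_and_keep_only_partition(self):
        g, ann = self.toy()
        branch = g.descendants("X:3")
        in_branch = [a for a in ann if a.class_id in branch]
        removed = ablate_branch(ann, g, "X:3", "remove")
        kept = ablate_branch(ann, g, "X:3", "keep_only")
        assert len(kept) == len(in_branch) == 8
        assert len(removed) == len(ann) - len(in_branch) == 2
        assert {id(a) for a in removed} | {id(a) for a in kept} == {id(a) for a in ann}
        assert {id(a) for a in removed} & {id(a) for a in kept} == set()

    def test_root_removal_empties(self):
        g, ann = self.toy()
        assert ablate_branch(ann, g, "X:1", "remove") == []

    def test_unknown_branch(self):
        g, ann = self.toy()
        with pytest.raises(Exception, match="unknown class"):
            ablate_branch(ann, g, "X:99", "remove")


class TestVariants:
    def test_baseline_has_no_cross_links(self, sources):
        kg = build_variant(KGVariantSpec.named("HPf"), sources)
        assert not kg.triples_with_tag("mapping")
        assert not kg.triples_with_tag("ld_simplified")

    def test_union_identity(self, sources):
        ld = build_variant(KGVariantSpec.named("HPs+GO+LD"), sources)
        mp = build_variant(KGVariantSpec.named("HPs+GO+Map"), sources)
        both = build_variant(KGVariantSpec.named("HPs+GO+LD+Map"), sources)
        assert both.triples == ld.triples | mp.triples

    def test_ld_variant_only_target_prefix_links(self, sources):
        kg = build_variant(KGVariantSpec.named("HPs+GO+LD"), sources)
        for s, _, o in kg.triples_with_tag("ld_simplified"):
            assert s.split(":")[0] != o.split(":")[0]
            assert o.startswith("GOX:")

    def test_builders_preserve_acyclicity(self, sources):
        for name in ("HPf", "HPf+GO", "HPs+GO+LD+Map"):
            kg = build_variant(KGVariantSpec.named(name), sources)
            assert nx.is_directed_acyclic_graph(kg.is_a_digraph())

    def test_ablated_variant_annotations(self, sources, bundle):
        spec = KGVariantSpec.named(
            "HPs+GO+LD",
            ablation=BranchAblation(bundle.signal_branch_root, "remove"),
        )
        kg = build_variant(spec, sources)
        branch = bundle.hp_ontology.descendants(bundle.signal_branch_root)
        for s, p, o in kg.triples_with_tag("annotation"):
            assert o not in branch
        # ontology classes themselves are never removed
        assert sum(1 for k in kg.entities.values() if k == "class") >= len(
            bundle.hp_ontology.classes
        )

    def test_unknown_ablation_root(self, sources):
        spec = KGVariantSpec.named(
            "HPs+GO+LD", ablation=BranchAblation("NOPE:1", "remove")
        )
        with pytest.raises(KGBuildError, match="not found"):
            build_variant(spec, sources)


class TestStatistics:
    def test_empty_graph_zeros(self):
        from ontogda.kg_builder import KnowledgeGraph

        stats = kg_statistics(KnowledgeGraph())["count"]
        assert (stats == 0).all()

    def test_counts_match_brute_force(self, sources):
        kg = build_variant(KGVariantSpec.named("HPs+GO+LD+Map"), sources)
        stats = kg_statistics(kg)["count"]
        gene_ann = sum(
            1
            for s, p, o in kg.triples
            if p == "hasAnnotation" and kg.entities[s] == "gene"
        )
        assert stats["gene_annotations"] == gene_ann
        assert stats["total_triples"] == len(kg.triples)
        assert stats["ld_simplified_triples"] == len(kg.triples_with_tag("ld_simplified"))
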