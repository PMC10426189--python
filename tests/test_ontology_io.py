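"""Parser and validator behaviour for ontologies, annotations, logical
definitions and mappings."""

import re

import networkx as nx
import pytest

from ontogda.ontology_io import (
    MappingRecord,
    OntologyValidationError,
    extract_logical_definitions,
    parse_disease_annotations,
    parse_gene_annotations,
    parse_mappings,
    parse_ontology,
    write_obo,
)

OBO_THREE = """format-version: 1.4

[Term]
id: T:0000001
name: a

[Term]
id: T:0000002
name: b
is_a: T:0000001

[Term]
id: T:0000003
name: c
is_a: T:0000001
"""

OBO_CYCLE = """format-version: 1.4

[Term]
id: T:0000001

[Term]
id: T:0000002
is_a: T:0000003

[Term]
id: T:0000003
is_a: T:0000002
"""

# ten classes, two deprecated, subClassOf chain on the rest
OWL_TEN = (
    "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
    "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
    "@prefix obo: <http://purl.obolibrary.org/obo/> .\n\n"
    + "\n".join(
        f"obo:TT_{i:07d} a owl:Class ." for i in range(1, 11)
    )
    + "\n"
    + "\n".join(
        f"obo:TT_{i:07d} rdfs:subClassOf obo:TT_{i - 1:07d} ."
        for i in range(2, 9)
    )
    + "\nobo:TT_0000009 owl:deprecated true .\nobo:TT_0000010 owl:deprecated true .\n"
)


class TestParseOntology:
    def test_minimal_dag(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_THREE)
        g = parse_ontology(p, format="obo")
        assert g.roots == {"T:0000001"}
        assert len(g.is_a) == 2
        assert g.labels["T:0000002"] == "b"

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "c.obo"
        p.write_text(OBO_CYCLE)
        with pytest.raises(OntologyValidationError, match="cycle"):
            parse_ontology(p, format="obo")

    def test_owl_obsolete_flags(self, tmp_path):
        p = tmp_path / "t.ttl"
        p.write_text(OWL_TEN)
        # independent scan of the source text
        n_declared = len(re.findall(r"a owl:Class", OWL_TEN))
        n_deprecated = len(re.findall(r"owl:deprecated true", OWL_TEN))
        g = parse_ontology(p, format="ttl")
        assert len(g.classes) == n_declared == 10
        assert len(g.classes - g.obsolete) == n_declared - n_deprecated == 8
        assert not (g.roots & g.obsolete)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_ontology(tmp_path / "absent.obo")

    def test_roundtrip_obo(self, bundle, tmp_path):
        p = tmp_path / "round.obo"
        write_obo(bundle.hp_ontology, p)
        again = parse_ontology(p, format="obo")
        assert again.classes == bundle.hp_ontology.classes
        assert again.is_a == bundle.hp_ontology.is_a
        assert again.obsolete == bundle.hp_ontology.obsolete
        assert again.labels == bundle.hp_ontology.labels

    def test_reachability_matches_transitive_closure(self, bundle):
        g = bundle.hp_ontology
        down = nx.DiGraph()
        down.add_nodes_from(g.classes)
        down.add_edges_from((p, c) for c, p in g.is_a)
        closure = nx.transitive_closure(down)
        root = sorted(g.roots)[0]
        assert g.descendants(root, include_self=False) == set(closure.successors(root))


GAF = """!gaf-version: 2.2
DB\tG1\tg1\t\tGO:0000001\tREF\tIEA\t\tP\t\t\t\t\t\t\t\t
DB\tG1\tg1\tNOT\tGO:0000002\tREF\tIEA\t\tP\t\t\t\t\t\t\t\t
DB\tG2\tg2\t\tGO:0000002\tREF\tIDA\t\tF\t\t\t\t\t\t\t\t
DB\tG3\tg3\t\tGO:0000003\tREF\tISS\t\tC\t\t\t\t\t\t\t\t
"""


class TestAnnotationParsers:
    def test_gaf_not_rows_excluded(self, tmp_path):
        p = tmp_path / "x.gaf"
        p.write_text(GAF)
        result = parse_gene_annotations(p, dialect="gaf")
        assert len(result.records) == 3
        assert all(r.entity_kind == "gene" for r in result.records)
        assert any("NOT" in reason for _, reason in result.rejects)

    def test_header_only_gaf(self, tmp_path):
        p = tmp_path / "empty.gaf"
        p.write_text("!gaf-version: 2.2\n")
        assert parse_gene_annotations(p, dialect="gaf").records == []

    def test_generic_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("".join(f"G{i}\tHP:000000{i}\n" for i in range(5)))
        result = parse_gene_annotations(p, dialect="generic-tsv")
        assert len(result.records) == 5
        assert {r.entity_kind for r in result.records} == {"gene"}

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("G1\tHP:0000001\n")
        with pytest.raises(ValueError, match="dialect"):
            parse_gene_annotations(p, dialect="weird")

    def test_hpoa_records_are_diseases(self, tmp_path):
        p = tmp_path / "d.hpoa"
        p.write_text(
            "#comment\ndatabase_id\tdisease_name\tqualifier\thpo_id\n"
            "OMIM:1\tx\t\tHP:0000001\n"
            "OMIM:2\ty\t\tHP:0000002\n"
            "OMIM:3\tz\t\tHP:0000003\n"
        )
        result = parse_disease_annotations(p)
        assert len(result.records) == 3
        assert {r.entity_kind for r in result.records} == {"disease"}

    def test_obsolete_class_routed_to_rejects(self, tmp_path, bundle):
        ont = bundle.hp_ontology
        cls = sorted(ont.classes)[5]
        ont2 = type(ont)(
            classes=set(ont.classes),
            labels=dict(ont.labels),
            is_a=set(ont.is_a),
            obsolete={cls},
        )
        p = tmp_path / "d.tsv"
        p.write_text(f"D1\t{cls}\nD2\tMISSING:1\n")
        result = parse_disease_annotations(p, ontology=ont2, dialect="generic-tsv")
        assert result.records == []
        reasons = [r for _, r in result.rejects]
        assert any("obsolete" in r for r in reasons)
        assert any("unknown" in r for r in reasons)

    def test_duplicate_disease_rows_collapse(self, tmp_path):
        p = tmp_path / "d.tsv"
        rows = ["D1\tHP:0000001"] * 3 + ["D1\tHP:0000002"]
        p.write_text("\n".join(rows) + "\n")
        result = parse_disease_annotations(p, dialect="generic-tsv")
        # brute-force unique count over the raw rows
        assert len(result.records) == len(set(rows))
        assert len(result.records) + len(result.rejects) == len(rows)

    def test_accounting_identity(self, tmp_path, bundle):
        """accepted + rejected = data rows, for a file with mixed validity."""
        ont = bundle.hp_ontology
        good = sorted(ont.classes)[:4]
        rows = [f"G{i}\t{c}" for i, c in enumerate(good)] + ["G9\tNOPE:1", "G10\tNOPE:2"]
        p = tmp_path / "mix.tsv"
        p.write_text("\n".join(rows) + "\n")
        result = parse_gene_annotations(p, dialect="generic-tsv", ontology=ont)
        assert len(result.records) + len(result.rejects) == len(rows)


FIG3_TTL = """@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix obo: <http://purl.obolibrary.org/obo/> .

obo:HP_0000365 a owl:Class ;
  owl:equivalentClass [
    a owl:Restriction ;
    owl:onProperty obo:BFO_0000051 ;
    owl:someValuesFrom [
      a owl:Class ;
      owl:intersectionOf (
        obo:PATO_0000911
        [ a owl:Restriction ;
          owl:onProperty obo:RO_0000052 ;
          owl:someValuesFrom obo:GO_0007605 ]
        [ a owl:Restriction ;
          owl:onProperty obo:RO_0002573 ;
          owl:someValuesFrom obo:PATO_0000460 ]
      )
    ]
  ] .
"""


class TestLogicalDefinitions:
    def test_hearing_impairment_axiom(self, tmp_path):
        """The hearing-impairment class is defined through the GO class for
        sensory perception of sound."""
        p = tmp_path / "ld.ttl"
        p.write_text(FIG3_TTL)
        lds = extract_logical_definitions(p)
        assert len(lds) == 1
        ld = lds[0]
        assert ld.defined_class == "HP:0000365"
        curies = {c for c, _ in ld.referenced_classes}
        assert "GO:0007605" in curies
        assert "PATO:0000911" in curies
        # properties are not referenced classes
        assert not any(c.startswith("RO:") or c.startswith("BFO:") for c in curies)

    def test_no_axioms_yields_empty(self, tmp_path):
        p = tmp_path / "none.ttl"
        p.write_text("@prefix owl: <http://www.w3.org/2002/07/owl#> .\n")
        assert extract_logical_definitions(p) == []

    def test_counts_match_regex_scan(self, bundle, tmp_path):
        from ontogda.simulate import write_bundle

        paths = write_bundle(bundle, tmp_path / "b")
        text = paths["lds"].read_text()
        lds = extract_logical_definitions(paths["lds"])
        assert len(lds) == len(re.findall(r"owl:equivalentClass", text))
        n_go_refs = len(re.findall(r"someValuesFrom obo:GOX_", text))
        assert sum(
            1 for ld in lds for _, pfx in ld.referenced_classes if pfx == "GOX"
        ) == n_go_refs


class TestMappings:
    def test_parse_three_rows(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "source\ttarget\tconfidence\n"
            "HP:1\tGO:1\t0.75\nHP:2\tGO:2\t0.80\nHP:3\tGO:3\t0.90\n"
        )
        records = parse_mappings(p)
        assert [m.confidence for m in records] == [0.75, 0.80, 0.90]

    def test_out_of_range_confidence(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("HP:1\tGO:1\t1.2\n")
        with pytest.raises(OntologyValidationError, match="row 1"):
            parse_mappings(p)

    def test_same_prefix_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("HP:1\tHP:2\t0.9\n")
        with pytest.raises(OntologyValidationError, match="prefix"):
            parse_mappings(p)

    def test_record_validation_direct(self):
        with pytest.raises(OntologyValidationError):
            MappingRecord("HP:1", "GO:1", confidence=-0.1)
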