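"""Assemble knowledge-graph variants from ontologies, annotations, logical
definitions and mappings.

The graphs mix three kinds of content: the ontology class hierarchies merged
under a single virtual root; annotation edges connecting gene and disease
instance entities to the classes that describe them (the entities are *not*
instances of those classes); and cross-ontology links, either simplified
logical definitions or alignment mappings above a confidence threshold.

Five standard variants mirror increasing semantic richness over a phenotype
ontology ("HP-like") and a function ontology ("GO-like"):

=================  =============================================================
``HPf``            full phenotype ontology (with its logical-definition
                   structure) + gene/disease phenotype annotations
``HPf+GO``         the above merged with the function ontology under a virtual
                   root, plus gene function annotations
``HPs+GO+LD``      logical definitions stripped, then re-added as one direct
                   equivalence triple per referenced function class
``HPs+GO+Map``     stripped, with threshold-filtered alignment mappings instead
``HPs+GO+LD+Map``  the union of the previous two
=================  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .ontology_io import (
    AnnotationRecord,
    LogicalDefinition,
    MappingRecord,
    OntologyGraph,
    curie_prefix,
)

__all__ = [
    "KnowledgeGraph",
    "KGVariantSpec",
    "KGSources",
    "BranchAblation",
    "VIRTUAL_ROOT",
    "IS_A",
    "HAS_ANNOTATION",
    "EQUIVALENT_TO",
    "VARIANT_NAMES",
    "merge_with_virtual_root",
    "strip_logical_definitions",
    "simplify_logical_definitions",
    "filter_mappings",
    "attach_annotations",
    "ablate_branch",
    "build_variant",
    "kg_statistics",
]

VIRTUAL_ROOT = "VIRTUAL:ROOT"
IS_A = "subClassOf"
HAS_ANNOTATION = "hasAnnotation"
EQUIVALENT_TO = "equivalentTo"
RESTRICTION_ON = "restrictionOn"

Triple = tuple[str, str, str]


class KGBuildError(ValueError):
    pass


@dataclass
class KnowledgeGraph:
    """A set of triples over ontology classes, instance entities and one
    virtual root, with per-triple provenance tags.

    Provenance tags: ``ontology`` (class hierarchy, relations, full
    logical-definition structure), ``annotation``, ``ld_simplified``,
    ``mapping``, ``merge`` (virtual-root edges).  A triple asserted by both a
    logical definition and a mapping keeps both tags.
    """

    triples: set[Triple] = field(default_factory=set)
    entities: dict[str, str] = field(default_factory=dict)  # id -> kind
    provenance: dict[Triple, frozenset[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def add(self, triple: Triple, tag: str) -> None:
        self.triples.add(triple)
        prev = self.provenance.get(triple, frozenset())
        self.provenance[triple] = prev | {tag}

    def register(self, entity: str, kind: str) -> None:
        prev = self.entities.get(entity)
        if prev is not None and prev != kind:
            raise KGBuildError(f"entity {entity!r} registered as both {prev} and {kind}")
        self.entities[entity] = kind

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            triples=set(self.triples),
            entities=dict(self.entities),
            provenance=dict(self.provenance),
            labels=dict(self.labels),
        )

    def triples_with_tag(self, tag: str) -> set[Triple]:
        return {t for t in self.triples if tag in self.provenance.get(t, frozenset())}

    def is_a_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from((s, o) for s, p, o in self.triples if p == IS_A)
        return g

    def validate(self) -> None:
        for s, p, o in self.triples:
            for endpoint in (s, o):
                if endpoint not in self.entities:
                    raise KGBuildError(f"triple references unregistered entity {endpoint!r}")
        if not nx.is_directed_acyclic_graph(self.is_a_digraph()):
            raise KGBuildError("is_a subgraph is cyclic")
        for t in self.triples_with_tag("ld_simplified") | self.triples_with_tag("mapping"):
            if curie_prefix(t[0]) == curie_prefix(t[2]):
                raise KGBuildError(f"cross-ontology triple with equal prefixes: {t}")


@dataclass(frozen=True)
class BranchAblation:
    branch_root: str
    mode: str  # "remove" | "keep_only"

    def __post_init__(self):
        if self.mode not in ("remove", "keep_only"):
            raise ValueError(f"ablation mode must be remove or keep_only, got {self.mode!r}")


VARIANT_NAMES = ("HPf", "HPf+GO", "HPs+GO+LD", "HPs+GO+Map", "HPs+GO+LD+Map")


@dataclass(frozen=True)
class KGVariantSpec:
    """Flag bundle selecting one of the five standard graph variants.

    ``mapping_threshold`` defaults to 0.8 (records at or above it are kept).
    ``ablation`` optionally removes (or keeps only) annotations under one
    ontology branch; the class hierarchy itself is never ablated.
    """

    name: str = "custom"
    include_go: bool = True
    strip_lds: bool = True
    add_simplified_lds: bool = True
    add_mappings: bool = False
    mapping_threshold: float = 0.8
    ablation: Optional[BranchAblation] = None

    @classmethod
    def named(
        cls,
        name: str,
        mapping_threshold: float = 0.8,
        ablation: Optional[BranchAblation] = None,
    ) -> "KGVariantSpec":
        flags = {
            "HPf": dict(include_go=False, strip_lds=False, add_simplified_lds=False, add_mappings=False),
            "HPf+GO": dict(include_go=True, strip_lds=False, add_simplified_lds=False, add_mappings=False),
            "HPs+GO+LD": dict(include_go=True, strip_lds=True, add_simplified_lds=True, add_mappings=False),
            "HPs+GO+Map": dict(include_go=True, strip_lds=True, add_simplified_lds=False, add_mappings=True),
            "HPs+GO+LD+Map": dict(include_go=True, strip_lds=True, add_simplified_lds=True, add_mappings=True),
        }
        if name not in flags:
            raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
        return cls(name=name, mapping_threshold=mapping_threshold, ablation=ablation, **flags[name])


@dataclass
class KGSources:
    """Parsed inputs a variant build draws from."""

    hp_ontology: OntologyGraph
    go_ontology: Optional[OntologyGraph] = None
    gene_hp_annotations: Sequence[AnnotationRecord] = ()
    gene_go_annotations: Sequence[AnnotationRecord] = ()
    disease_hp_annotations: Sequence[AnnotationRecord] = ()
    logical_definitions: Sequence[LogicalDefinition] = ()
    mappings: Sequence[MappingRecord] = ()
    go_prefix: str = "GO"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def merge_with_virtual_root(ontologies: Sequence[OntologyGraph]) -> KnowledgeGraph:
    """Merge one or more ontologies into a single connected graph by making
    every ontology root a subclass of a synthetic virtual root."""
    if not ontologies:
        raise KGBuildError("need at least one ontology")
    seen: set[str] = set()
    for ont in ontologies:
        clash = seen & ont.classes
        if clash:
            raise KGBuildError(f"overlapping class ids across ontologies: {sorted(clash)[:5]}")
        seen |= ont.classes

    kg = KnowledgeGraph()
    kg.register(VIRTUAL_ROOT, "root")
    for ont in ontologies:
        for cls in ont.classes:
            kg.register(cls, "class")
        kg.labels.update(ont.labels)
        for child, parent in ont.is_a:
            kg.add((child, IS_A, parent), "ontology")
        for s, r, o in ont.relations:
            kg.add((s, r, o), "ontology")
        for root in sorted(ont.roots):
            kg.add((root, IS_A, VIRTUAL_ROOT), "merge")
    return kg


def _ld_node(ld: LogicalDefinition) -> str:
    return f"LDNODE:{ld.defined_class}"


def add_full_logical_definitions(
    kg: KnowledgeGraph, lds: Sequence[LogicalDefinition]
) -> KnowledgeGraph:
    """Materialize each equivalence axiom as a small triple structure: the
    defined class is equivalent to an expression node which restricts over
    every referenced class.  Walks can thus traverse defined class →
    expression node → referenced class, mimicking how the axiom sits in the
    serialized ontology graph."""
    out = kg.copy()
    for ld in lds:
        if ld.defined_class not in out.entities:
            continue
        node = _ld_node(ld)
        out.register(node, "class")
        out.add((ld.defined_class, EQUIVALENT_TO, node), "ontology")
        for curie, _prefix in ld.referenced_classes:
            if curie not in out.entities:
                out.register(curie, "class")
            out.add((node, RESTRICTION_ON, curie), "ontology")
    return out


def strip_logical_definitions(
    kg: KnowledgeGraph, lds: Sequence[LogicalDefinition]
) -> KnowledgeGraph:
    """Remove every triple originating from the listed equivalence axioms,
    leaving all other triples untouched.  Idempotent."""
    out = kg.copy()
    for ld in lds:
        node = _ld_node(ld)
        doomed = {t for t in out.triples if t[0] == node or t[2] == node}
        for t in doomed:
            out.triples.discard(t)
            out.provenance.pop(t, None)
        out.entities.pop(node, None)
    return out


def simplify_logical_definitions(
    lds: Sequence[LogicalDefinition], target_prefix: str
) -> list[Triple]:
    """Collapse each axiom to direct equivalence triples: one
    ``(defined_class, equivalentTo, C)`` per referenced class C carrying the
    target prefix.  Axioms that reference no such class emit nothing."""
    if not target_prefix:
        raise ValueError("target_prefix must be non-empty")
    out: list[Triple] = []
    for ld in lds:
        for curie, prefix in ld.referenced_classes:
            if prefix == target_prefix:
                out.append((ld.defined_class, EQUIVALENT_TO, curie))
    return out


def filter_mappings(
    mappings: Sequence[MappingRecord], threshold: float = 0.8
) -> list[MappingRecord]:
    """Keep exactly the mappings with confidence >= threshold (inclusive
    boundary), preserving input order."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [m for m in mappings if m.confidence >= threshold]


def attach_annotations(
    kg: KnowledgeGraph, annotations: Sequence[AnnotationRecord]
) -> KnowledgeGraph:
    """Connect gene/disease entities to the classes that describe them with
    one ``hasAnnotation`` triple per unique (entity, class) pair."""
    missing = sorted({a.class_id for a in annotations if a.class_id not in kg.entities})
    if missing:
        raise KGBuildError(f"annotation classes absent from graph: {missing[:10]}")
    out = kg.copy()
    for a in annotations:
        out.register(a.entity_id, a.entity_kind)
        out.add((a.entity_id, HAS_ANNOTATION, a.class_id), "annotation")
    return out


def ablate_branch(
    annotations: Sequence[AnnotationRecord],
    ontology: OntologyGraph,
    branch_root: str,
    mode: str = "remove",
) -> list[AnnotationRecord]:
    """Drop (or keep only) annotations whose class lies under ``branch_root``.

    Branch membership follows ``is_a`` subsumption only, including the branch
    root itself.  Ontology classes are never removed — only annotations.
    """
    if mode not in ("remove", "keep_only"):
        raise ValueError(f"mode must be remove or keep_only, got {mode!r}")
    branch = ontology.descendants(branch_root, include_self=True)
    if mode == "remove":
        return [a for a in annotations if a.class_id not in branch]
    return [a for a in annotations if a.class_id in branch]


def build_variant(spec: KGVariantSpec, sources: KGSources) -> KnowledgeGraph:
    """Build one knowledge-graph variant from parsed sources.

    The union identity holds exactly: the LD+Map variant's triple set equals
    the union of the LD-only and Map-only variants' triple sets.
    """
    if spec.include_go and sources.go_ontology is None:
        raise KGBuildError(f"variant {spec.name!r} requires a function ontology")

    ontologies = [sources.hp_ontology]
    if spec.include_go:
        ontologies.append(sources.go_ontology)
    kg = merge_with_virtual_root(ontologies)

    if not spec.strip_lds:
        kg = add_full_logical_definitions(kg, sources.logical_definitions)

    gene_hp = list(sources.gene_hp_annotations)
    disease_hp = list(sources.disease_hp_annotations)
    gene_go = list(sources.gene_go_annotations) if spec.include_go else []

    if spec.ablation is not None:
        root = spec.ablation.branch_root
        mode = spec.ablation.mode
        if root in sources.hp_ontology.classes:
            ont = sources.hp_ontology
            gene_hp = ablate_branch(gene_hp, ont, root, mode)
            disease_hp = ablate_branch(disease_hp, ont, root, mode)
        elif sources.go_ontology is not None and root in sources.go_ontology.classes:
            gene_go = ablate_branch(gene_go, sources.go_ontology, root, mode)
        else:
            raise KGBuildError(f"ablation branch root {root!r} not found in any ontology")

    kg = attach_annotations(kg, gene_hp + disease_hp + gene_go)

    if spec.add_simplified_lds:
        for t in simplify_logical_definitions(sources.logical_definitions, sources.go_prefix):
            if t[2] in kg.entities:
                kg.add(t, "ld_simplified")
    if spec.add_mappings:
        for m in filter_mappings(sources.mappings, spec.mapping_threshold):
            if m.source_class in kg.entities and m.target_class in kg.entities:
                kg.add((m.source_class, EQUIVALENT_TO, m.target_class), "mapping")
    kg.validate()
    return kg


def kg_statistics(kg: KnowledgeGraph) -> pd.DataFrame:
    """Tabulate class, annotation and cross-link counts for a graph."""
    kinds = kg.entities
    gene_ann = sum(
        1
        for s, p, o in kg.triples
        if p == HAS_ANNOTATION and kinds.get(s) == "gene"
    )
    disease_ann = sum(
        1
        for s, p, o in kg.triples
        if p == HAS_ANNOTATION and kinds.get(s) == "disease"
    )
    rows = {
        "classes": sum(1 for k in kinds.values() if k == "class"),
        "genes": sum(1 for k in kinds.values() if k == "gene"),
        "diseases": sum(1 for k in kinds.values() if k == "disease"),
        "gene_annotations": gene_ann,
        "disease_annotations": disease_ann,
        "ld_simplified_triples": len(kg.triples_with_tag("ld_simplified")),
        "mapping_triples": len(kg.triples_with_tag("mapping")),
        "total_triples": len(kg.triples),
    }
    return pd.DataFrame({"count": rows})


def write_ntriples(kg: KnowledgeGraph, path, base: str = "urn:ontogda:") -> None:
    """Serialize the triple set as N-Triples plus no side effects; entity
    kinds and provenance go in a TSV sidecar written by the pipeline."""
    def uri(token: str) -> str:
        return f"<{base}{token.replace(' ', '_')}>"

    with open(path, "w") as fh:
        for s, p, o in sorted(kg.triples):
            fh.write(f"{uri(s)} {uri(p)} {uri(o)} .\n")
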