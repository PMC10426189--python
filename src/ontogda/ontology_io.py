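"""Readers and validators for ontologies, annotations, logical definitions,
mappings, and gene-disease association tables.

Everything downstream (knowledge-graph assembly, embedding, prediction) works
on the in-memory types defined here: :class:`OntologyGraph` for a rooted DAG of
ontology classes, :class:`AnnotationRecord` for a gene/disease-to-class edge,
:class:`LogicalDefinition` for a cross-ontology equivalence axiom,
:class:`MappingRecord` for an alignment-produced correspondence, and
:class:`AssociationRecord` for a labelled gene-disease pair.

OBO files are parsed with :mod:`obonet`; OWL serializations (RDF/XML, Turtle)
with :mod:`rdflib`.  Identifiers are canonicalized to ``PREFIX:LOCAL`` CURIEs
with the prefix uppercased.  Annotation rows that reference unknown or obsolete
classes are never silently dropped: every parser returns a
:class:`ParseResult` whose ``rejects`` list accounts for them row by row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet
import pandas as pd
import rdflib
from rdflib import OWL, RDF, RDFS

__all__ = [
    "OntologyGraph",
    "AnnotationRecord",
    "LogicalDefinition",
    "MappingRecord",
    "AssociationRecord",
    "ParseResult",
    "OntologyValidationError",
    "parse_ontology",
    "parse_gene_annotations",
    "parse_disease_annotations",
    "parse_associations",
    "extract_logical_definitions",
    "parse_mappings",
    "write_obo",
]


class OntologyValidationError(ValueError):
    """Raised when a parsed artefact violates a structural invariant."""


_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9._-]*):(\S+)$")


def normalize_curie(identifier: str) -> str:
    """Canonicalize a class identifier to ``PREFIX:LOCAL`` with the prefix
    uppercased.  OBO-style URIs (``.../obo/HP_0000365``) are compacted."""
    identifier = identifier.strip()
    if identifier.startswith("http://") or identifier.startswith("https://"):
        tail = identifier.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        identifier = tail.replace("_", ":", 1) if "_" in tail else tail
    m = _CURIE_RE.match(identifier)
    if not m:
        return identifier
    return f"{m.group(1).upper()}:{m.group(2)}"


def curie_prefix(curie: str) -> str:
    return curie.split(":", 1)[0] if ":" in curie else ""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OntologyGraph:
    """A rooted DAG of ontology classes.

    ``is_a`` edges are (child, parent) pairs; ``relations`` holds typed
    non-subsumption edges as (subject, relation, object).  ``roots`` is
    exactly the set of non-obsolete classes with no ``is_a`` parent — the
    Human Phenotype Ontology, for instance, has five such subontology roots.
    """

    classes: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    is_a: set[tuple[str, str]] = field(default_factory=set)
    relations: set[tuple[str, str, str]] = field(default_factory=set)
    obsolete: set[str] = field(default_factory=set)

    @property
    def roots(self) -> set[str]:
        has_parent = {c for c, _ in self.is_a}
        return {c for c in self.classes if c not in has_parent and c not in self.obsolete}

    def prefix_of(self, cls: str) -> str:
        return curie_prefix(cls)

    @property
    def prefixes(self) -> set[str]:
        return {curie_prefix(c) for c in self.classes}

    def parents(self, cls: str) -> set[str]:
        return {p for c, p in self.is_a if c == cls}

    def subsumption_digraph(self) -> nx.DiGraph:
        """Parent -> child digraph over ``is_a`` (edges point down the tree)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from((p, c) for c, p in self.is_a)
        return g

    def descendants(self, cls: str, include_self: bool = True) -> set[str]:
        """All classes reachable from ``cls`` by following ``is_a`` downward."""
        if cls not in self.classes:
            raise OntologyValidationError(f"unknown class {cls!r}")
        out = set(nx.descendants(self.subsumption_digraph(), cls))
        if include_self:
            out.add(cls)
        return out

    def validate(self) -> None:
        for child, parent in self.is_a:
            for endpoint in (child, parent):
                if endpoint not in self.classes:
                    raise OntologyValidationError(
                        f"is_a edge endpoint {endpoint!r} is not a declared class"
                    )
        dag = nx.DiGraph(list(self.is_a))
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyValidationError(
                f"is_a cycle detected involving {cycle[0][0]!r}"
            )
        for s, _, o in self.relations:
            if s not in self.classes or o not in self.classes:
                raise OntologyValidationError(
                    f"relation edge references undeclared class: ({s}, {o})"
                )


@dataclass(frozen=True)
class AnnotationRecord:
    """One statement that a gene or disease is described by an ontology class."""

    entity_id: str
    class_id: str
    entity_kind: str  # "gene" | "disease"
    aspect: str = ""
    evidence: str = ""
    source: str = ""

    def __post_init__(self):
        if self.entity_kind not in ("gene", "disease"):
            raise ValueError(f"entity_kind must be gene or disease, got {self.entity_kind!r}")


@dataclass(frozen=True)
class LogicalDefinition:
    """An equivalence axiom defining a class in terms of foreign classes.

    ``referenced_classes`` lists every named class mentioned on the right-hand
    side together with its CURIE prefix, e.g. the definition of
    HP:0000365 (hearing impairment) references GO:0007605 (sensory perception
    of sound).
    """

    defined_class: str
    raw_axiom: str
    referenced_classes: tuple[tuple[str, str], ...]  # (curie, prefix)


@dataclass(frozen=True)
class MappingRecord:
    """A cross-ontology correspondence with an alignment confidence."""

    source_class: str
    target_class: str
    confidence: float
    relation: str = "equivalence"

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise OntologyValidationError(
                f"mapping confidence {self.confidence} outside [0, 1] "
                f"({self.source_class} -> {self.target_class})"
            )
        if curie_prefix(self.source_class) == curie_prefix(self.target_class):
            raise OntologyValidationError(
                "mapping endpoints share a prefix: "
                f"{self.source_class} -> {self.target_class}"
            )


@dataclass(frozen=True)
class AssociationRecord:
    """A gene-disease pair with provenance sources and an optional label."""

    gene_id: str
    disease_id: str
    sources: frozenset[str] = frozenset()
    label: Optional[int] = None  # 1 positive, 0 negative, None unset

    def __post_init__(self):
        if not self.gene_id or not self.disease_id:
            raise ValueError("gene_id and disease_id must be non-empty")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class ParseResult:
    """Accepted records plus a row-level rejects report.

    Invariant: ``len(records) + len(rejects)`` equals the number of data rows
    in the input (excluded qualifier rows are counted as rejects).
    """

    records: list
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejects, columns=["row", "reason"])


# ---------------------------------------------------------------------------
# Ontology parsing
# ---------------------------------------------------------------------------


def parse_ontology(path: str | Path, format: str = "obo") -> OntologyGraph:
    """Read an ontology from OBO or an OWL/RDF serialization.

    Obsolete classes are kept (flagged) but never count as roots, and
    annotations to them are later routed to the rejects report.  A cycle in
    the ``is_a`` hierarchy is a validation failure naming one cycle member.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "obo":
        graph = _parse_obo(path)
    elif format in ("owl-rdf", "owl", "xml", "turtle", "ttl"):
        graph = _parse_owl(path, format)
    else:
        raise ValueError(f"unknown ontology format {format!r}")
    graph.validate()
    return graph


def _parse_obo(path: Path) -> OntologyGraph:
    net = obonet.read_obo(str(path), ignore_obsolete=False)
    g = OntologyGraph()
    for node, data in net.nodes(data=True):
        cls = normalize_curie(node)
        g.classes.add(cls)
        if data.get("name"):
            g.labels[cls] = data["name"]
        syns = []
        for raw in data.get("synonym", []):
            m = re.match(r'"([^"]*)"', raw)
            syns.append(m.group(1) if m else raw)
        if syns:
            g.synonyms[cls] = syns
        if str(data.get("is_obsolete", "")).lower() == "true":
            g.obsolete.add(cls)
    # obonet edges run child -> parent, keyed by the relationship type
    for child, parent, key in net.edges(keys=True):
        c, p = normalize_curie(child), normalize_curie(parent)
        if key == "is_a":
            g.is_a.add((c, p))
        else:
            g.relations.add((c, normalize_curie(key), p))
    return g


def _parse_owl(path: Path, format: str) -> OntologyGraph:
    rdf_format = {"owl-rdf": None, "owl": None, "xml": "xml", "turtle": "turtle", "ttl": "turtle"}[format]
    rg = rdflib.Graph()
    if rdf_format is None:
        try:
            rg.parse(str(path), format="xml")
        except Exception:
            rg = rdflib.Graph()
            rg.parse(str(path), format="turtle")
    else:
        rg.parse(str(path), format=rdf_format)

    g = OntologyGraph()
    for s in rg.subjects(RDF.type, OWL.Class):
        if isinstance(s, rdflib.URIRef):
            g.classes.add(normalize_curie(str(s)))
    for s, o in rg.subject_objects(RDFS.subClassOf):
        if isinstance(s, rdflib.URIRef) and isinstance(o, rdflib.URIRef):
            c, p = normalize_curie(str(s)), normalize_curie(str(o))
            g.classes.add(c)
            g.classes.add(p)
            g.is_a.add((c, p))
    for s, o in rg.subject_objects(RDFS.label):
        if isinstance(s, rdflib.URIRef):
            cls = normalize_curie(str(s))
            if cls in g.classes:
                g.labels[cls] = str(o)
    for s, o in rg.subject_objects(OWL.deprecated):
        if isinstance(s, rdflib.URIRef) and str(o).lower() == "true":
            cls = normalize_curie(str(s))
            if cls in g.classes:
                g.obsolete.add(cls)
    return g


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize an :class:`OntologyGraph` to a minimal OBO 1.4 document.

    Round-trips through :func:`parse_ontology`: class, label, is_a,
    relationship and obsolete information are preserved.
    """
    lines = ["format-version: 1.4", ""]
    rel_by_subject: dict[str, list[tuple[str, str]]] = {}
    for s, r, o in sorted(graph.relations):
        rel_by_subject.setdefault(s, []).append((r, o))
    for cls in sorted(graph.classes):
        lines.append("[Term]")
        lines.append(f"id: {cls}")
        if cls in graph.labels:
            lines.append(f"name: {graph.labels[cls]}")
        for syn in graph.synonyms.get(cls, []):
            lines.append(f'synonym: "{syn}" EXACT []')
        for child, parent in sorted(graph.is_a):
            if child == cls:
                lines.append(f"is_a: {parent}")
        for r, o in rel_by_subject.get(cls, []):
            lines.append(f"relationship: {r} {o}")
        if cls in graph.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


def _validate_class(
    class_id: str, ontology: Optional[OntologyGraph]
) -> Optional[str]:
    """Return a reject reason, or None if the class is acceptable."""
    if ontology is None:
        return None
    if class_id not in ontology.classes:
        return f"unknown class {class_id}"
    if class_id in ontology.obsolete:
        return f"obsolete class {class_id}"
    return None


def parse_gene_annotations(
    path: str | Path,
    dialect: str = "gaf",
    ontology: Optional[OntologyGraph] = None,
    evidence_include: Optional[set[str]] = None,
) -> ParseResult:
    """Parse gene annotations from GAF 2.x, the HPO gene-to-phenotype TSV, or
    a generic two/three-column TSV.

    GAF comment lines (``!``) are skipped and rows carrying a ``NOT``
    qualifier are excluded (standard GO practice).  All evidence codes are
    accepted unless ``evidence_include`` names an allow-list.  If ``ontology``
    is given, rows referencing unknown or obsolete classes land in the
    rejects report.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    rejects: list[tuple[int, str]] = []

    def consider(row_no: int, rec: AnnotationRecord) -> None:
        reason = _validate_class(rec.class_id, ontology)
        if reason is not None:
            rejects.append((row_no, reason))
        elif evidence_include is not None and rec.evidence not in evidence_include:
            rejects.append((row_no, f"evidence {rec.evidence!r} not in include list"))
        else:
            records.append(rec)

    if dialect == "gaf":
        for row_no, fields in _tsv_rows(path, comment="!"):
            if len(fields) < 9:
                rejects.append((row_no, "short GAF row"))
                continue
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                rejects.append((row_no, "NOT-qualified"))
                continue
            consider(
                row_no,
                AnnotationRecord(
                    entity_id=fields[1],
                    class_id=normalize_curie(fields[4]),
                    entity_kind="gene",
                    aspect=fields[8] if len(fields) > 8 else "",
                    evidence=fields[6] if len(fields) > 6 else "",
                    source=fields[0],
                ),
            )
    elif dialect == "hp-gene-tsv":
        # ncbi_gene_id <tab> gene_symbol <tab> hpo_id <tab> hpo_name
        for row_no, fields in _tsv_rows(path, comment="#", skip_header_startswith="ncbi"):
            if len(fields) < 3:
                rejects.append((row_no, "short row"))
                continue
            consider(
                row_no,
                AnnotationRecord(
                    entity_id=fields[0],
                    class_id=normalize_curie(fields[2]),
                    entity_kind="gene",
                ),
            )
    elif dialect == "generic-tsv":
        for row_no, fields in _tsv_rows(path, comment="#"):
            if len(fields) < 2:
                rejects.append((row_no, "short row"))
                continue
            consider(
                row_no,
                AnnotationRecord(
                    entity_id=fields[0],
                    class_id=normalize_curie(fields[1]),
                    entity_kind="gene",
                    aspect=fields[2] if len(fields) > 2 else "",
                ),
            )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return ParseResult(records, rejects)


def parse_disease_annotations(
    path: str | Path,
    ontology: Optional[OntologyGraph] = None,
    dialect: str = "hpoa",
) -> ParseResult:
    """Parse disease-to-phenotype annotations (HPOA-style TSV, or a generic
    disease/class TSV).  Duplicate (disease, class) rows collapse to one
    record; the duplicates are accounted for in the rejects report."""
    path = Path(path)
    records: list[AnnotationRecord] = []
    rejects: list[tuple[int, str]] = []
    seen: set[tuple[str, str]] = set()

    def consider(row_no: int, disease: str, cls: str, evidence: str = "") -> None:
        reason = _validate_class(cls, ontology)
        if reason is not None:
            rejects.append((row_no, reason))
            return
        key = (disease, cls)
        if key in seen:
            rejects.append((row_no, "duplicate (disease, class) row"))
            return
        seen.add(key)
        records.append(
            AnnotationRecord(entity_id=disease, class_id=cls, entity_kind="disease", evidence=evidence)
        )

    if dialect == "hpoa":
        # database_id, disease_name, qualifier, hpo_id, ...
        for row_no, fields in _tsv_rows(path, comment="#", skip_header_startswith="database_id"):
            if len(fields) < 4:
                rejects.append((row_no, "short HPOA row"))
                continue
            if fields[2].strip() == "NOT":
                rejects.append((row_no, "NOT-qualified"))
                continue
            consider(row_no, fields[0], normalize_curie(fields[3]))
    elif dialect == "generic-tsv":
        for row_no, fields in _tsv_rows(path, comment="#"):
            if len(fields) < 2:
                rejects.append((row_no, "short row"))
                continue
            consider(row_no, fields[0], normalize_curie(fields[1]))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return ParseResult(records, rejects)


def _tsv_rows(
    path: Path, comment: str = "#", skip_header_startswith: str | None = None
) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(comment):
                continue
            if skip_header_startswith and line.lower().startswith(skip_header_startswith):
                continue
            yield row_no, line.split("\t")


# ---------------------------------------------------------------------------
# Logical definitions
# ---------------------------------------------------------------------------

_VOCAB_NAMESPACES = (str(OWL), str(RDF), str(RDFS))


def extract_logical_definitions(ontology_source: str | Path) -> list[LogicalDefinition]:
    """Extract equivalent-class axioms from an OWL source.

    One :class:`LogicalDefinition` is produced per ``owl:equivalentClass``
    axiom whose right-hand side references at least one named class.  Classes
    reached through ``owl:someValuesFrom`` fillers, ``owl:intersectionOf`` /
    ``owl:unionOf`` members, or direct naming are collected as referenced
    classes; ``owl:onProperty`` objects are properties, not classes, and are
    excluded.  An ontology without such axioms yields an empty list.
    """
    path = Path(ontology_source)
    rg = rdflib.Graph()
    try:
        rg.parse(str(path), format="turtle")
    except Exception:
        rg = rdflib.Graph()
        rg.parse(str(path), format="xml")

    lds: list[LogicalDefinition] = []
    for s, o in rg.subject_objects(OWL.equivalentClass):
        if not isinstance(s, rdflib.URIRef):
            continue
        refs: list[str] = []
        parts: list[str] = []
        _collect_expression(rg, o, refs, parts)
        if not refs:
            continue
        seen: list[tuple[str, str]] = []
        for curie in refs:
            pair = (curie, curie_prefix(curie))
            if pair not in seen:
                seen.append(pair)
        lds.append(
            LogicalDefinition(
                defined_class=normalize_curie(str(s)),
                raw_axiom=" ".join(parts),
                referenced_classes=tuple(seen),
            )
        )
    lds.sort(key=lambda ld: ld.defined_class)
    return lds


def _collect_expression(rg: rdflib.Graph, node, refs: list[str], parts: list[str]) -> None:
    if isinstance(node, rdflib.URIRef):
        uri = str(node)
        if any(uri.startswith(ns) for ns in _VOCAB_NAMESPACES):
            return
        curie = normalize_curie(uri)
        refs.append(curie)
        parts.append(curie)
        return
    if not isinstance(node, rdflib.BNode):
        return
    for member in rg.objects(node, OWL.intersectionOf):
        parts.append("and(")
        for item in rg.items(member):
            _collect_expression(rg, item, refs, parts)
        parts.append(")")
    for member in rg.objects(node, OWL.unionOf):
        parts.append("or(")
        for item in rg.items(member):
            _collect_expression(rg, item, refs, parts)
        parts.append(")")
    for prop in rg.objects(node, OWL.onProperty):
        parts.append(normalize_curie(str(prop)) + " some")
    for filler in rg.objects(node, OWL.someValuesFrom):
        _collect_expression(rg, filler, refs, parts)
    for filler in rg.objects(node, OWL.allValuesFrom):
        _collect_expression(rg, filler, refs, parts)


# ---------------------------------------------------------------------------
# Mappings and associations
# ---------------------------------------------------------------------------


def parse_mappings(path: str | Path) -> list[MappingRecord]:
    """Parse a TSV of cross-ontology mappings (source, target, confidence
    [, relation]).  Confidences outside [0, 1] and same-prefix endpoints are
    validation failures citing the row; values are never clamped."""
    out: list[MappingRecord] = []
    for row_no, fields in _tsv_rows(Path(path), comment="#", skip_header_startswith="source"):
        if len(fields) < 3:
            raise OntologyValidationError(f"mapping row {row_no}: expected ≥3 columns")
        try:
            confidence = float(fields[2])
        except ValueError as exc:
            raise OntologyValidationError(f"mapping row {row_no}: bad confidence {fields[2]!r}") from exc
        try:
            out.append(
                MappingRecord(
                    source_class=normalize_curie(fields[0]),
                    target_class=normalize_curie(fields[1]),
                    confidence=confidence,
                    relation=fields[3] if len(fields) > 3 else "equivalence",
                )
            )
        except OntologyValidationError as exc:
            raise OntologyValidationError(f"mapping row {row_no}: {exc}") from exc
    return out


def parse_associations(
    path: str | Path,
    gene_col: str = "geneId",
    disease_col: str = "diseaseId",
    source_col: str = "source",
) -> list[AssociationRecord]:
    """Read a DisGeNET-style gene-disease association TSV.

    Column names are configurable because export layouts vary; the source
    column may hold multiple provenance tags separated by ``;`` or ``,``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (gene_col, disease_col):
        if col not in df.columns:
            raise ValueError(f"association table lacks column {col!r}")
    out: list[AssociationRecord] = []
    for _, row in df.iterrows():
        raw = row.get(source_col, "") if source_col in df.columns else ""
        sources = frozenset(
            s.strip() for s in re.split(r"[;,]", str(raw)) if s.strip() and str(raw) != "nan"
        )
        out.append(
            AssociationRecord(
                gene_id=str(row[gene_col]),
                disease_id=str(row[disease_col]),
                sources=sources,
                label=1,
            )
        )
    return out
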