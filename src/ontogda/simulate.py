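"""Synthetic fixture generator: toy ontology pairs with controllable
cross-ontology signal.

The generator emulates the data model of the real task: a phenotype-like
ontology (prefix ``HPX``) with several subontology branch roots, a
function-like ontology (prefix ``GOX``), genes annotated to both, diseases
annotated to the phenotype ontology only, and a set of planted cross-ontology
equivalences emitted both as logical definitions and as alignment mappings.

Gene-disease labels are drawn by thresholding a per-pair score

    s(g, d) = w_direct · |shared phenotype annotations of g and d|
            + w_cross  · |disease phenotype classes cross-linked to gene
                          function classes|
            + logistic noise

at the (1 − positive_rate) quantile.  With ``w_direct = 0`` the association
signal is reachable *only* through the cross-ontology links, which makes the
benefit of link-enriched knowledge graphs directly testable: the planted
links live under one designated phenotype branch, so ablating that branch
destroys the signal.

Everything is seeded; the same spec and seed reproduce a byte-identical
bundle, and the bundle can be written to disk in the standard formats (OBO,
TSV, Turtle) so the I/O parsers are exercised rather than bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ontology_io import (
    AnnotationRecord,
    AssociationRecord,
    LogicalDefinition,
    MappingRecord,
    OntologyGraph,
    write_obo,
)

__all__ = ["FixtureSpec", "FixtureBundle", "make_fixture_bundle", "fixture_truth_table", "write_bundle"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    Defaults give a small but non-trivial benchmark: a 150-class phenotype
    ontology and an 80-class function ontology, 200 genes × 100 diseases,
    80 planted cross-links confined to the dominant phenotype branch, and
    pure cross-ontology signal available by setting ``w_direct`` to 0.
    """

    n_classes: int = 150           # phenotype ontology
    n_classes_go: int = 80         # function ontology
    n_branch_roots: int = 5        # phenotype subontology roots
    n_branch_roots_go: int = 3     # function ontology branches
    multi_parent_prob: float = 0.1  # extra is_a parent → DAG, not a tree
    # the first phenotype branch dominates, as the phenotypic-abnormality
    # branch does in the real ontology (it holds most classes and the vast
    # majority of disease annotations)
    dominant_branch_weight: float = 0.6   # share of classes grown under it
    annotation_branch_bias: float = 0.9   # share of HP annotations drawn from it
    n_genes: int = 200
    n_diseases: int = 100
    gene_hp_annotations: int = 2
    gene_go_annotations: int = 12
    disease_hp_annotations: int = 10
    n_cross_links: int = 80
    w_direct: float = 1.0
    w_cross: float = 1.0
    noise_scale: float = 0.15      # logistic noise on the pair score
    positive_rate: float = 0.04
    # "per_disease": each disease is associated with its top-scoring genes
    # (curated catalogues list a handful of genes per disease); "global":
    # threshold the score distribution over all pairs at one quantile
    label_scheme: str = "per_disease"
    seed: int = 0
    hp_prefix: str = "HPX"
    go_prefix: str = "GOX"

    def validate(self) -> None:
        counts = {
            "n_classes": self.n_classes,
            "n_branch_roots": self.n_branch_roots,
            "n_genes": self.n_genes,
            "n_diseases": self.n_diseases,
            "gene_go_annotations": self.gene_go_annotations,
            "disease_hp_annotations": self.disease_hp_annotations,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_cross_links < 0:
            raise ValueError("n_cross_links must be >= 0")
        if self.w_direct < 0 or self.w_cross < 0:
            raise ValueError("signal weights must be >= 0")
        if not (0 < self.positive_rate < 1):
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.n_branch_roots > self.n_classes:
            raise ValueError("more branch roots than classes")


@dataclass
class FixtureBundle:
    """Everything one end-to-end run needs, plus the generating truth."""

    spec: FixtureSpec
    hp_ontology: OntologyGraph
    go_ontology: OntologyGraph
    gene_hp_annotations: list[AnnotationRecord]
    gene_go_annotations: list[AnnotationRecord]
    disease_hp_annotations: list[AnnotationRecord]
    logical_definitions: list[LogicalDefinition]
    mappings: list[MappingRecord]
    associations: list[AssociationRecord]
    cross_links: list[tuple[str, str]]           # (HPX class, GOX class)
    signal_branch_root: str
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def positives(self) -> list[AssociationRecord]:
        return [a for a in self.associations if a.label == 1]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _make_ontology(
    prefix: str,
    n_classes: int,
    n_branch_roots: int,
    multi_parent_prob: float,
    rng: np.random.Generator,
    dominant_branch_weight: float = 0.0,
) -> OntologyGraph:
    """Rooted DAG with ``n_branch_roots`` independent subontology roots (as
    the phenotype ontology has five); remaining classes attach to uniformly
    chosen earlier classes, occasionally with a second parent so the result
    is a DAG rather than a forest of trees.  With a positive
    ``dominant_branch_weight`` that share of new classes grows under the
    first branch, skewing the size distribution the way the
    phenotypic-abnormality branch dominates the real phenotype ontology."""
    g = OntologyGraph()
    ids = [f"{prefix}:{i:07d}" for i in range(1, n_classes + 1)]
    in_dominant = {ids[0]}
    for i, cls in enumerate(ids):
        g.classes.add(cls)
        g.labels[cls] = f"{prefix.lower()} class {i + 1}"
        if i >= n_branch_roots:
            pool = ids[:i]
            if dominant_branch_weight > 0 and rng.random() < dominant_branch_weight:
                dom_pool = [c for c in pool if c in in_dominant]
                parent = dom_pool[int(rng.integers(len(dom_pool)))]
            else:
                parent = pool[int(rng.integers(len(pool)))]
            g.is_a.add((cls, parent))
            if parent in in_dominant:
                in_dominant.add(cls)
            if rng.random() < multi_parent_prob and i > 1:
                second = pool[int(rng.integers(len(pool)))]
                if second != parent and second != cls:
                    g.is_a.add((cls, second))
                    if second in in_dominant:
                        in_dominant.add(cls)
    g.validate()
    return g


def _annotate(
    entities: list[str],
    kind: str,
    classes: list[str],
    per_entity: int,
    rng: np.random.Generator,
    weights: Optional[np.ndarray] = None,
) -> list[AnnotationRecord]:
    out = []
    for e in entities:
        picks = rng.choice(
            len(classes), size=min(per_entity, len(classes)), replace=False, p=weights
        )
        for i in sorted(picks):
            out.append(AnnotationRecord(entity_id=e, class_id=classes[int(i)], entity_kind=kind))
    return out


def make_fixture_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete, internally consistent synthetic bundle."""
    spec.validate()
    # independent streams per stage: removing cross links (or changing their
    # number) must not perturb the ontologies, annotations or noise draws
    ss = np.random.SeedSequence(spec.seed)
    rng, rng_links, rng_annot, rng_score = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    hp = _make_ontology(
        spec.hp_prefix, spec.n_classes, spec.n_branch_roots, spec.multi_parent_prob,
        rng, dominant_branch_weight=spec.dominant_branch_weight,
    )
    go = _make_ontology(
        spec.go_prefix, spec.n_classes_go, spec.n_branch_roots_go, spec.multi_parent_prob, rng
    )

    # the planted signal lives under the first phenotype subontology root
    signal_branch_root = sorted(hp.roots)[0]
    signal_branch = sorted(hp.descendants(signal_branch_root) - {signal_branch_root})
    if len(signal_branch) == 0:
        raise ValueError("signal branch has no descendant classes; increase n_classes")

    go_classes = sorted(go.classes - go.roots)
    hp_classes = sorted(hp.classes - hp.roots)

    n_links = min(spec.n_cross_links, len(signal_branch), len(go_classes))
    if spec.n_cross_links > len(signal_branch) * len(go_classes):
        raise ValueError("more cross links requested than available class pairs")
    hp_side = [signal_branch[int(i)] for i in rng_links.choice(len(signal_branch), size=n_links, replace=False)]
    go_side = [go_classes[int(i)] for i in rng_links.choice(len(go_classes), size=n_links, replace=False)]
    cross_links = list(zip(hp_side, go_side))

    lds = [
        LogicalDefinition(
            defined_class=h,
            raw_axiom=f"{h} EquivalentTo inheres_in some {g}",
            referenced_classes=((g, spec.go_prefix),),
        )
        for h, g in cross_links
    ]
    mappings = [
        MappingRecord(
            source_class=h,
            target_class=g,
            confidence=float(np.round(0.5 + 0.5 * rng_links.random(), 3)),
        )
        for h, g in cross_links
    ]

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    diseases = [f"D{i:04d}" for i in range(spec.n_diseases)]
    # phenotype annotations concentrate in the dominant branch, as disease
    # annotations do in the real ontology
    branch_set = set(signal_branch)
    in_branch = np.array([c in branch_set for c in hp_classes], dtype=float)
    n_in = in_branch.sum()
    if 0 < n_in < len(hp_classes):
        bias = spec.annotation_branch_bias
        hp_weights = np.where(
            in_branch > 0, bias / n_in, (1.0 - bias) / (len(hp_classes) - n_in)
        )
        hp_weights /= hp_weights.sum()
    else:
        hp_weights = None
    gene_hp = _annotate(genes, "gene", hp_classes, spec.gene_hp_annotations, rng_annot, hp_weights)
    gene_go = _annotate(genes, "gene", go_classes, spec.gene_go_annotations, rng_annot)
    disease_hp = _annotate(diseases, "disease", hp_classes, spec.disease_hp_annotations, rng_annot, hp_weights)

    # per-pair score decomposition
    gene_hp_sets = {g: set() for g in genes}
    for a in gene_hp:
        gene_hp_sets[a.entity_id].add(a.class_id)
    gene_go_sets = {g: set() for g in genes}
    for a in gene_go:
        gene_go_sets[a.entity_id].add(a.class_id)
    disease_hp_sets = {d: set() for d in diseases}
    for a in disease_hp:
        disease_hp_sets[a.entity_id].add(a.class_id)
    link_partner: dict[str, set[str]] = {}
    for h, g in cross_links:
        link_partner.setdefault(h, set()).add(g)

    rows = []
    for g in genes:
        for d in diseases:
            direct = len(gene_hp_sets[g] & disease_hp_sets[d])
            cross = sum(
                len(link_partner.get(h, set()) & gene_go_sets[g])
                for h in disease_hp_sets[d]
            )
            rows.append((g, d, direct, cross))
    df = pd.DataFrame(rows, columns=["gene", "disease", "direct", "cross"])
    noise = rng_score.logistic(scale=spec.noise_scale, size=len(df))
    df["noise"] = noise
    df["score"] = spec.w_direct * df["direct"] + spec.w_cross * df["cross"] + df["noise"]
    if spec.label_scheme == "per_disease":
        k = max(1, round(spec.positive_rate * spec.n_genes))
        ranks = df.groupby("disease")["score"].rank(ascending=False, method="first")
        df["label"] = (ranks <= k).astype(int)
    elif spec.label_scheme == "global":
        threshold = float(df["score"].quantile(1.0 - spec.positive_rate))
        df["label"] = (df["score"] > threshold).astype(int)
    else:
        raise ValueError(f"unknown label_scheme {spec.label_scheme!r}")

    associations = [
        AssociationRecord(
            gene_id=r.gene,
            disease_id=r.disease,
            sources=frozenset({"SYNTH"}),
            label=int(r.label),
        )
        for r in df.itertuples()
    ]

    return FixtureBundle(
        spec=spec,
        hp_ontology=hp,
        go_ontology=go,
        gene_hp_annotations=gene_hp,
        gene_go_annotations=gene_go,
        disease_hp_annotations=disease_hp,
        logical_definitions=lds,
        mappings=mappings,
        associations=associations,
        cross_links=cross_links,
        signal_branch_root=signal_branch_root,
        scores=df,
    )


def fixture_truth_table(bundle: FixtureBundle) -> pd.DataFrame:
    """Per-pair score decomposition: direct and cross components, noise,
    total score and label — the oracle for downstream recovery tests."""
    return bundle.scores.copy()


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in standard formats: OBO ontologies, TSV annotation
    and mapping tables, a Turtle snippet for the logical definitions, a
    DisGeNET-style association TSV and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hp_obo": out / "hpx.obo",
        "go_obo": out / "gox.obo",
        "gene_hp": out / "gene_hpx_annotations.tsv",
        "gene_go": out / "gene_gox_annotations.tsv",
        "disease_hp": out / "disease_hpx_annotations.tsv",
        "lds": out / "logical_definitions.ttl",
        "mappings": out / "mappings.tsv",
        "associations": out / "associations.tsv",
        "truth": out / "truth_table.tsv",
    }
    write_obo(bundle.hp_ontology, paths["hp_obo"])
    write_obo(bundle.go_ontology, paths["go_obo"])
    _write_annotation_tsv(bundle.gene_hp_annotations, paths["gene_hp"])
    _write_annotation_tsv(bundle.gene_go_annotations, paths["gene_go"])
    _write_annotation_tsv(bundle.disease_hp_annotations, paths["disease_hp"])
    _write_ld_turtle(bundle, paths["lds"])
    with open(paths["mappings"], "w") as fh:
        fh.write("source\ttarget\tconfidence\trelation\n")
        for m in bundle.mappings:
            fh.write(f"{m.source_class}\t{m.target_class}\t{m.confidence}\t{m.relation}\n")
    with open(paths["associations"], "w") as fh:
        fh.write("geneId\tdiseaseId\tsource\tscore\n")
        for a in bundle.associations:
            if a.label == 1:
                fh.write(f"{a.gene_id}\t{a.disease_id}\t{';'.join(sorted(a.sources))}\t1.0\n")
    bundle.scores.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _write_annotation_tsv(annotations, path: Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.entity_id}\t{a.class_id}\n")


def _write_ld_turtle(bundle: FixtureBundle, path: Path) -> None:
    base = "http://purl.obolibrary.org/obo/"
    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix obo: <http://purl.obolibrary.org/obo/> .",
        "",
    ]
    for ld in bundle.logical_definitions:
        defined = ld.defined_class.replace(":", "_")
        for curie, _prefix in ld.referenced_classes:
            ref = curie.replace(":", "_")
            lines.append(f"obo:{defined} a owl:Class ;")
            lines.append("  owl:equivalentClass [")
            lines.append("    a owl:Restriction ;")
            lines.append("    owl:onProperty obo:RO_0000052 ;")
            lines.append(f"    owl:someValuesFrom obo:{ref}")
            lines.append("  ] .")
            lines.append(f"obo:{ref} a owl:Class .")
            lines.append("")
    Path(path).write_text("\n".join(lines))
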