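"""Build the supervised gene-disease pair dataset.

The pipeline is: drop association records whose only provenance is a source
also used to build the ontology annotations (leakage control); keep only
genes with both phenotype and function annotations and diseases with
phenotype annotations (coverage control); balance the positives with an equal
number of uniformly sampled negative pairs drawn from the positive entities'
grid; and assign stratified cross-validation folds that are reused across
every experimental condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ontology_io import AnnotationRecord, AssociationRecord

__all__ = [
    "PairDataset",
    "FoldPlan",
    "DEFAULT_BANNED_SOURCES",
    "filter_leakage",
    "filter_by_coverage",
    "sample_negatives",
    "make_folds",
]

# Sources shared between the association catalogue and the ontology
# annotation pipelines; pairs known only through them are leakage-prone.
DEFAULT_BANNED_SOURCES = frozenset({"UNIPROT", "OMIM", "ORPHANET"})


@dataclass
class PairDataset:
    """A balanced, labelled set of gene-disease pairs."""

    pairs: list[AssociationRecord]
    seed: int

    @property
    def genes(self) -> set[str]:
        return {p.gene_id for p in self.pairs}

    @property
    def diseases(self) -> set[str]:
        return {p.disease_id for p in self.pairs}

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self) -> None:
        keys = [(p.gene_id, p.disease_id) for p in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (gene, disease) pair in dataset")
        labels = [p.label for p in self.pairs]
        if any(l not in (0, 1) for l in labels):
            raise ValueError("all pairs must carry a 0/1 label")
        n_pos = sum(labels)
        if 2 * n_pos != len(labels):
            raise ValueError(f"dataset unbalanced: {n_pos} positives of {len(labels)}")
        pos_genes = {p.gene_id for p in self.pairs if p.label == 1}
        pos_diseases = {p.disease_id for p in self.pairs if p.label == 1}
        for p in self.pairs:
            if p.label == 0 and (p.gene_id not in pos_genes or p.disease_id not in pos_diseases):
                raise ValueError(f"negative pair outside positive entity universe: {p}")

    def to_frame(self, folds: "FoldPlan | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": [p.gene_id for p in self.pairs],
                "disease": [p.disease_id for p in self.pairs],
                "label": [p.label for p in self.pairs],
            }
        )
        if folds is not None:
            df["fold"] = folds.assignment
        return df

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_pairs": len(self.pairs),
            "n_positive": int(sum(p.label for p in self.pairs)),
            "n_genes": len(self.genes),
            "n_diseases": len(self.diseases),
        }


@dataclass
class FoldPlan:
    """A stratified k-fold partition, fixed once and shared across runs."""

    k: int
    assignment: np.ndarray  # pair index -> fold in [0, k)
    seed: int

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignment != fold)[0]

    def validate(self, labels: Sequence[int]) -> None:
        labels = np.asarray(labels)
        if len(labels) != len(self.assignment):
            raise ValueError("fold plan length does not match dataset")
        sizes = np.bincount(self.assignment, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")
        global_frac = labels.mean()
        for f in range(self.k):
            mask = self.assignment == f
            # stratification: per-fold positive count within 1 of proportional
            if abs(labels[mask].sum() - global_frac * mask.sum()) > 1:
                raise ValueError(f"fold {f} is not stratified")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_leakage(
    records: Sequence[AssociationRecord],
    banned_sources: Iterable[str] = DEFAULT_BANNED_SOURCES,
) -> list[AssociationRecord]:
    """Drop records whose every provenance source is banned.

    A record with at least one non-banned source is retained; records with
    *no* recorded source are retained too (nothing ties them to a banned
    pipeline).  An empty banned set is a usage error.
    """
    banned = {s.upper() for s in banned_sources}
    if not banned:
        raise ValueError("banned_sources must be non-empty")
    out = []
    for r in records:
        srcs = {s.upper() for s in r.sources}
        if srcs and srcs <= banned:
            continue
        out.append(r)
    return out


def filter_by_coverage(
    records: Sequence[AssociationRecord],
    gene_hp_annotations: Sequence[AnnotationRecord],
    gene_go_annotations: Sequence[AnnotationRecord],
    disease_hp_annotations: Sequence[AnnotationRecord],
) -> list[AssociationRecord]:
    """Keep pairs whose gene has ≥1 phenotype AND ≥1 function annotation and
    whose disease has ≥1 phenotype annotation."""
    genes_hp = {a.entity_id for a in gene_hp_annotations}
    genes_go = {a.entity_id for a in gene_go_annotations}
    diseases_hp = {a.entity_id for a in disease_hp_annotations}
    return [
        r
        for r in records
        if r.gene_id in genes_hp and r.gene_id in genes_go and r.disease_id in diseases_hp
    ]


# ---------------------------------------------------------------------------
# Negative sampling and folds
# ---------------------------------------------------------------------------


def sample_negatives(
    positives: Sequence[AssociationRecord], seed: int
) -> PairDataset:
    """Balance the positives with uniformly sampled unassociated pairs.

    Negatives are drawn without replacement, uniformly over the grid
    (positive genes) × (positive diseases) minus the positive cells, so every
    negative's gene and disease each occur in at least one positive pair.
    Deterministic for a fixed seed.
    """
    if not positives:
        raise ValueError("need at least one positive pair")
    genes = sorted({p.gene_id for p in positives})
    diseases = sorted({p.disease_id for p in positives})
    pos_keys = {(p.gene_id, p.disease_id) for p in positives}
    if len(pos_keys) != len(positives):
        raise ValueError("duplicate positive pairs")
    n_cells = len(genes) * len(diseases)
    n_needed = len(positives)
    if n_cells - len(pos_keys) < n_needed:
        raise ValueError(
            f"grid has only {n_cells - len(pos_keys)} non-associated cells, "
            f"need {n_needed}"
        )

    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set(pos_keys)
    # rejection sampling in batches keeps memory flat on large grids while
    # remaining uniform over the eligible cells
    while len(chosen) < n_needed:
        draw = rng.integers(0, n_cells, size=max(1024, 2 * (n_needed - len(chosen))))
        for idx in draw:
            key = (genes[idx // len(diseases)], diseases[idx % len(diseases)])
            if key in seen:
                continue
            seen.add(key)
            chosen.append(key)
            if len(chosen) == n_needed:
                break

    pairs = [
        AssociationRecord(p.gene_id, p.disease_id, p.sources, label=1) for p in positives
    ] + [AssociationRecord(g, d, frozenset(), label=0) for g, d in chosen]
    ds = PairDataset(pairs=pairs, seed=seed)
    ds.validate()
    return ds


def make_folds(dataset: PairDataset, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment over the binary labels, deterministic for
    a fixed seed and reusable across all downstream runs."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} pairs cannot fill {k} folds")
    labels = dataset.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(dataset), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        assignment[test_idx] = fold
    plan = FoldPlan(k=k, assignment=assignment, seed=seed)
    plan.validate(labels)
    return plan


def write_dataset(
    dataset: PairDataset, folds: FoldPlan, out_dir: str | Path, extra_manifest: dict | None = None
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.to_frame(folds).to_csv(out_dir / "dataset.tsv", sep="\t", index=False)
    manifest = dataset.manifest()
    manifest.update({"k": folds.k, "fold_seed": folds.seed})
    if extra_manifest:
        manifest.update(extra_manifest)
    (out_dir / "dataset_manifest.json").write_text(json.dumps(manifest, indent=2))
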