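"""End-to-end orchestration: build graph → make dataset → embed → predict,
plus the branch-ablation suite, driven by one YAML config with a provenance
manifest.

The four stages can run from a synthetic bundle (``fixture:`` section) or
from files on disk (``inputs:`` section, standard formats).  Either way the
inputs pass through the regular parsers.  Every random draw traces to a seed
recorded in the manifest, and re-running with an identical config reproduces
identical dataset and fold artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import gda_dataset, kg_builder, ontology_io, pair_model, simulate
from .embeddings import embed
from .gda_dataset import FoldPlan, PairDataset
from .kg_builder import BranchAblation, KGSources, KGVariantSpec
from .pair_model import EvalReport

__all__ = ["RunManifest", "PipelineConfig", "load_sources", "run_experiment",
           "run_pipeline", "run_ablation_suite"]

log = logging.getLogger("ontogda")


def _jlog(stage: str, **fields) -> None:
    log.info(json.dumps({"stage": stage, **fields}))


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    artifacts: dict = field(default_factory=dict)  # path -> sha256
    started: float = field(default_factory=time.time)
    finished: Optional[float] = None

    def record_input(self, path: Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def record_artifact(self, path: Path) -> None:
        self.artifacts[str(path)] = sha256_file(path)

    def write(self, path: Path) -> None:
        self.finished = time.time()
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "artifacts": self.artifacts,
            "started": self.started,
            "finished": self.finished,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))


_DEFAULTS = {
    "variant": "HPs+GO+LD",
    "mapping_threshold": 0.8,
    "embedding": {"method": "rdf2vec", "dim": 200, "walks": 500, "depth": 4,
                  "window": 5, "epochs": 5},
    "dataset": {"k": 10, "banned_sources": ["UNIPROT", "OMIM", "ORPHANET"]},
    "predict": {"operator": "hadamard", "predictor": "rf"},
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``examples/config.yaml``)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, val in raw.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        cfg = cls(raw=merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if ("fixture" in self.raw) == ("inputs" in self.raw):
            raise ValueError("config must name exactly one of 'fixture' or 'inputs'")
        if self.raw["variant"] not in kg_builder.VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.raw['variant']!r}")
        if self.raw["predict"]["predictor"] not in ("rf", "xgb", "cosine"):
            raise ValueError("predictor must be rf, xgb or cosine")
        if self.raw["predict"]["operator"] not in pair_model.OPERATORS:
            raise ValueError(f"unknown operator {self.raw['predict']['operator']!r}")
        if "inputs" in self.raw:
            required = ("hp_obo", "gene_hp", "gene_go", "disease_hp", "associations")
            missing = [k for k in required if k not in self.raw["inputs"]]
            if missing:
                raise ValueError(f"inputs section lacks: {missing}")
            for key, p in self.raw["inputs"].items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"inputs.{key}: {p}")

    def __getitem__(self, key):
        return self.raw[key]


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------


def load_sources(
    config: PipelineConfig, workdir: Path, manifest: RunManifest
) -> tuple[KGSources, list[ontology_io.AssociationRecord]]:
    """Materialize the graph sources and positive associations, either by
    generating + writing + re-parsing a synthetic bundle, or by parsing the
    files named under ``inputs:``."""
    raw = config.raw
    if "fixture" in raw:
        spec = simulate.FixtureSpec(**{**raw["fixture"], "seed": raw["fixture"].get("seed", raw["seed"])})
        bundle = simulate.make_fixture_bundle(spec)
        paths = simulate.write_bundle(bundle, workdir / "fixture")
        file_cfg = {
            "hp_obo": paths["hp_obo"],
            "go_obo": paths["go_obo"],
            "gene_hp": paths["gene_hp"],
            "gene_go": paths["gene_go"],
            "disease_hp": paths["disease_hp"],
            "lds": paths["lds"],
            "mappings": paths["mappings"],
            "associations": paths["associations"],
        }
        manifest.seeds["fixture"] = spec.seed
    else:
        file_cfg = {k: Path(v) for k, v in raw["inputs"].items()}

    for p in file_cfg.values():
        manifest.record_input(Path(p))

    hp = ontology_io.parse_ontology(file_cfg["hp_obo"], format="obo")
    go = ontology_io.parse_ontology(file_cfg["go_obo"], format="obo") if "go_obo" in file_cfg else None
    gene_hp = ontology_io.parse_gene_annotations(file_cfg["gene_hp"], dialect="generic-tsv", ontology=hp)
    gene_go = ontology_io.parse_gene_annotations(file_cfg["gene_go"], dialect="generic-tsv", ontology=go)
    disease_hp = ontology_io.parse_disease_annotations(file_cfg["disease_hp"], dialect="generic-tsv", ontology=hp)
    lds = ontology_io.extract_logical_definitions(file_cfg["lds"]) if "lds" in file_cfg else []
    mappings = ontology_io.parse_mappings(file_cfg["mappings"]) if "mappings" in file_cfg else []
    assoc_cfg = raw.get("association_columns", {})
    positives = ontology_io.parse_associations(file_cfg["associations"], **assoc_cfg)

    go_prefix = sorted(go.prefixes)[0] if go is not None else "GO"
    sources = KGSources(
        hp_ontology=hp,
        go_ontology=go,
        gene_hp_annotations=gene_hp.records,
        gene_go_annotations=gene_go.records,
        disease_hp_annotations=disease_hp.records,
        logical_definitions=lds,
        mappings=mappings,
        go_prefix=go_prefix,
    )
    _jlog("load_sources", n_positives=len(positives),
          n_lds=len(lds), n_mappings=len(mappings))
    return sources, positives


# ---------------------------------------------------------------------------
# Experiment core (shared by CLI, pipeline and acceptance)
# ---------------------------------------------------------------------------


def build_dataset(
    positives: Sequence[ontology_io.AssociationRecord],
    sources: KGSources,
    banned_sources: Sequence[str],
    seed: int,
    k: int = 10,
) -> tuple[PairDataset, FoldPlan]:
    kept = gda_dataset.filter_leakage(positives, banned_sources)
    kept = gda_dataset.filter_by_coverage(
        kept,
        sources.gene_hp_annotations,
        sources.gene_go_annotations,
        sources.disease_hp_annotations,
    )
    dataset = gda_dataset.sample_negatives(kept, seed=seed)
    folds = gda_dataset.make_folds(dataset, k=k, seed=seed)
    _jlog("build_dataset", n_positive=len(kept), n_pairs=len(dataset), k=k, seed=seed)
    return dataset, folds


def run_experiment(
    sources: KGSources,
    dataset: PairDataset,
    folds: FoldPlan,
    variant: str = "HPs+GO+LD",
    embedding: Optional[dict] = None,
    predict: Optional[dict] = None,
    mapping_threshold: float = 0.8,
    ablation: Optional[BranchAblation] = None,
    seed: int = 0,
    grid: Optional[Sequence[dict]] = None,
) -> EvalReport:
    """Build one graph variant, embed it, and cross-validate the predictor
    on the given dataset under the given (shared) fold plan."""
    embedding = {**_DEFAULTS["embedding"], **(embedding or {})}
    predict = {**_DEFAULTS["predict"], **(predict or {})}
    spec = KGVariantSpec.named(variant, mapping_threshold=mapping_threshold, ablation=ablation)
    kg = kg_builder.build_variant(spec, sources)
    _jlog("build_kg", variant=variant, n_triples=len(kg.triples),
          ablation=None if ablation is None else [ablation.branch_root, ablation.mode])

    entities = sorted(dataset.genes | dataset.diseases)
    # walk the graph's genes/diseases plus the ontology classes; dataset
    # entities that lost every annotation still emit singleton walks so a
    # vector exists for them
    starts = sorted(
        set(entities)
        | {e for e, k in kg.entities.items() if k in ("gene", "disease", "class")}
    )
    table = embed(
        kg,
        method=embedding["method"],
        dim=embedding["dim"],
        seed=seed,
        n_walks=embedding.get("walks", 500),
        depth=embedding.get("depth", 4),
        window=embedding.get("window", 5),
        epochs=embedding.get("epochs"),
        require=entities if embedding["method"] in ("rdf2vec", "axiom-sentence") else None,
        start_entities=starts if embedding["method"] == "rdf2vec" else None,
    )
    _jlog("embed", method=embedding["method"], dim=embedding["dim"],
          n_vectors=len(table.vectors), seed=seed)

    report = pair_model.cross_validate(
        dataset,
        folds,
        table,
        operator=predict["operator"],
        predictor=predict["predictor"],
        grid=grid,
        seed=seed,
        kg_variant=variant if ablation is None else f"{variant}(ablated {ablation.branch_root})",
    )
    _jlog("predict", predictor=predict["predictor"], operator=predict["operator"],
          median_waf=report.median_waf)
    return report


# ---------------------------------------------------------------------------
# Whole-pipeline entry points
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir: str | Path) -> tuple[RunManifest, EvalReport]:
    """Execute the four pipeline stages in order and write all artifacts plus
    a provenance manifest under ``out_dir``."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.raw)
    seed = int(config["seed"])
    manifest.seeds.update({"dataset": seed, "embedding": seed, "model": seed})

    sources, positives = load_sources(config, out, manifest)
    dataset, folds = build_dataset(
        positives, sources, config["dataset"]["banned_sources"], seed=seed,
        k=config["dataset"]["k"],
    )
    gda_dataset.write_dataset(dataset, folds, out)
    report = run_experiment(
        sources, dataset, folds,
        variant=config["variant"],
        embedding=config["embedding"],
        predict=config["predict"],
        mapping_threshold=config["mapping_threshold"],
        seed=seed,
    )
    report.to_json(out / "eval_report.json")
    report.to_frame().to_csv(out / "eval_report.tsv", sep="\t", index=False)
    for name in ("dataset.tsv", "dataset_manifest.json", "eval_report.json", "eval_report.tsv"):
        manifest.record_artifact(out / name)
    manifest.write(out / "run_manifest.json")
    return manifest, report


def run_ablation_suite(
    config: PipelineConfig | dict | str | Path,
    branches: Sequence[str],
    out_dir: str | Path,
    modes: Sequence[str] = ("remove",),
) -> "pd.DataFrame":
    """One run per (branch, mode) plus the unablated baseline, all sharing a
    single fold plan; returns a table of median WAFs with significance vs the
    baseline."""
    import pandas as pd

    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.raw)
    seed = int(config["seed"])

    sources, positives = load_sources(config, out, manifest)
    known = set(sources.hp_ontology.classes)
    if sources.go_ontology is not None:
        known |= sources.go_ontology.classes
    unknown = [b for b in branches if b not in known]
    if unknown:
        raise ValueError(f"unknown ablation branches: {unknown}")

    dataset, folds = build_dataset(
        positives, sources, config["dataset"]["banned_sources"], seed=seed,
        k=config["dataset"]["k"],
    )

    def one(ablation: Optional[BranchAblation]) -> EvalReport:
        return run_experiment(
            sources, dataset, folds,
            variant=config["variant"],
            embedding=config["embedding"],
            predict=config["predict"],
            mapping_threshold=config["mapping_threshold"],
            ablation=ablation,
            seed=seed,
        )

    baseline = one(None)
    rows = [{
        "ablation": "baseline", "mode": "-", "median_waf": baseline.median_waf,
        "p_value": 1.0, "significant": False,
    }]
    for branch in branches:
        for mode in modes:
            rep = one(BranchAblation(branch_root=branch, mode=mode))
            sig = pair_model.compare_runs(rep, baseline)
            rows.append({
                "ablation": branch, "mode": mode, "median_waf": rep.median_waf,
                "p_value": sig.p_value, "significant": sig.significant,
            })
    table = pd.DataFrame(rows)
    table.to_csv(out / "ablation_suite.tsv", sep="\t", index=False)
    manifest.record_artifact(out / "ablation_suite.tsv")
    manifest.write(out / "run_manifest.json")
    return table
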