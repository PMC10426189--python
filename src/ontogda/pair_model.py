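"""Pair representation, classification and cross-validated evaluation.

A gene-disease pair is represented by combining the two entity embeddings
with a binary operator — concatenation, average, Hadamard (elementwise
product), weighted-L1 (|g − d|) or weighted-L2 (|g − d|²).  Concatenation
doubles the vector size; the other four preserve it.

Classifiers are random forest or gradient-boosted trees with a small inner
grid search, plus a similarity baseline that thresholds the cosine of the two
raw embeddings (threshold learned on the training folds by grid search).

Evaluation is stratified k-fold cross-validation with the *same* fold plan
reused across every condition; the headline metric is the support-weighted
average of per-class F-measures (WAF), reported per fold and as a median.
Two runs sharing a fold plan are compared with an exact two-sided Wilcoxon
signed-rank test on the per-fold WAFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split

from .embeddings import EmbeddingTable
from .gda_dataset import FoldPlan, PairDataset

__all__ = [
    "OPERATORS",
    "PairVector",
    "EvalReport",
    "SignificanceResult",
    "combine",
    "pair_matrix",
    "cosine_similarity",
    "cosine_baseline",
    "waf",
    "cross_validate",
    "compare_runs",
    "DEFAULT_RF_GRID",
    "DEFAULT_XGB_GRID",
    "DEFAULT_COSINE_GRID",
]

OPERATORS = ("concatenation", "average", "hadamard", "weighted-L1", "weighted-L2")

# Hyperparameter grids are configuration, not code: pipelines may override
# them from the run config.  Defaults are deliberately small.
DEFAULT_RF_GRID: tuple[dict, ...] = (
    {"n_estimators": 200, "max_depth": None},
    {"n_estimators": 200, "max_depth": 8},
)
DEFAULT_XGB_GRID: tuple[dict, ...] = (
    {"n_estimators": 200, "max_depth": 6, "learning_rate": 0.1},
    {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.3},
)
DEFAULT_COSINE_GRID: np.ndarray = np.linspace(-1.0, 1.0, 101)


@dataclass(frozen=True)
class PairVector:
    values: np.ndarray
    operator: str

    @property
    def size(self) -> int:
        return len(self.values)


@dataclass
class EvalReport:
    """Per-fold metrics for one (kg-variant, method, operator, predictor)
    cell, with the fold plan they were computed under."""

    fold_waf: list[float]
    fold_precision: list[float]
    fold_recall: list[float]
    operator: str
    method: str
    predictor: str
    kg_variant: str = ""
    fold_plan: Optional[FoldPlan] = None
    extras: dict = field(default_factory=dict)

    @property
    def median_waf(self) -> float:
        return float(np.median(self.fold_waf))

    @property
    def median_precision(self) -> float:
        return float(np.median(self.fold_precision))

    @property
    def median_recall(self) -> float:
        return float(np.median(self.fold_recall))

    def validate(self) -> None:
        for series in (self.fold_waf, self.fold_precision, self.fold_recall):
            if any(not (0.0 <= v <= 1.0) for v in series):
                raise ValueError("metrics must lie in [0, 1]")
        if self.fold_plan is not None and len(self.fold_waf) != self.fold_plan.k:
            raise ValueError("one WAF per fold required")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": i,
                "waf": w,
                "precision": p,
                "recall": r,
                "kg_variant": self.kg_variant,
                "method": self.method,
                "operator": self.operator,
                "predictor": self.predictor,
            }
            for i, (w, p, r) in enumerate(
                zip(self.fold_waf, self.fold_precision, self.fold_recall)
            )
        ]
        rows.append(
            {
                "fold": "median",
                "waf": self.median_waf,
                "precision": self.median_precision,
                "recall": self.median_recall,
                "kg_variant": self.kg_variant,
                "method": self.method,
                "operator": self.operator,
                "predictor": self.predictor,
            }
        )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_waf": self.fold_waf,
            "fold_precision": self.fold_precision,
            "fold_recall": self.fold_recall,
            "median_waf": self.median_waf,
            "operator": self.operator,
            "method": self.method,
            "predictor": self.predictor,
            "kg_variant": self.kg_variant,
            "extras": {k: v for k, v in self.extras.items() if _json_safe(v)},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass(frozen=True)
class SignificanceResult:
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Pair representation
# ---------------------------------------------------------------------------


def combine(g: np.ndarray, d: np.ndarray, operator: str) -> PairVector:
    """Fuse a gene and a disease vector into one pair representation."""
    g = np.asarray(g, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError(f"dimension mismatch: {g.shape} vs {d.shape}")
    if operator == "concatenation":
        values = np.concatenate([g, d])
    elif operator == "average":
        values = (g + d) / 2.0
    elif operator == "hadamard":
        values = g * d
    elif operator == "weighted-L1":
        values = np.abs(g - d)
    elif operator == "weighted-L2":
        values = np.abs(g - d) ** 2
    else:
        raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")
    return PairVector(values=values, operator=operator)


def pair_matrix(
    dataset: PairDataset, embeddings: EmbeddingTable, operator: str
) -> np.ndarray:
    """Stack the combined pair vectors for every pair in the dataset."""
    entities = sorted(dataset.genes | dataset.diseases)
    embeddings.require(entities)
    return np.vstack(
        [
            combine(embeddings[p.gene_id], embeddings[p.disease_id], operator).values
            for p in dataset.pairs
        ]
    )


def cosine_similarity(g: np.ndarray, d: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either has zero norm."""
    ng, nd = np.linalg.norm(g), np.linalg.norm(d)
    if ng == 0.0 or nd == 0.0:
        return 0.0
    return float(np.dot(g, d) / (ng * nd))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def waf(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """Weighted average of per-class F-measures (support-weighted F1)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if len(labels) == 0:
        raise ValueError("need at least one instance")
    return float(f1_score(labels, predictions, average="weighted", zero_division=0))


# ---------------------------------------------------------------------------
# Cosine baseline
# ---------------------------------------------------------------------------


def cosine_baseline(
    train_sims: np.ndarray,
    train_labels: np.ndarray,
    test_sims: np.ndarray,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Pick the similarity threshold maximizing training WAF (smallest on
    ties) from a grid, then predict positive where test similarity >= it."""
    if grid is None:
        grid = DEFAULT_COSINE_GRID
    best_thr, best_waf = None, -1.0
    for thr in grid:  # ascending; strict > keeps the smallest maximizer
        score = waf(train_labels, (train_sims >= thr).astype(int))
        if score > best_waf:
            best_waf, best_thr = score, float(thr)
    return (test_sims >= best_thr).astype(int), best_thr


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _fit_with_grid(predictor, X_tr, y_tr, grid, seed):
    """Grid search on a single inner stratified 80/20 split of the training
    data, refit the winner on the full training fold."""
    if grid is None:
        grid = DEFAULT_RF_GRID if predictor == "rf" else DEFAULT_XGB_GRID
    if len(grid) > 1:
        X_in, X_val, y_in, y_val = train_test_split(
            X_tr, y_tr, test_size=0.2, stratify=y_tr, random_state=seed
        )
        best_params, best_score = None, -1.0
        for params in grid:
            model = _make_model(predictor, params, seed)
            model.fit(X_in, y_in)
            score = waf(y_val, model.predict(X_val))
            if score > best_score:
                best_score, best_params = score, params
    else:
        best_params = grid[0]
    model = _make_model(predictor, best_params, seed)
    model.fit(X_tr, y_tr)
    return model, best_params


def _make_model(predictor: str, params: dict, seed: int):
    if predictor == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if predictor == "xgb":
        import xgboost as xgb

        return xgb.XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **params
        )
    raise ValueError(f"unknown predictor {predictor!r}")


def cross_validate(
    dataset: PairDataset,
    folds: FoldPlan,
    embeddings: EmbeddingTable,
    operator: str = "hadamard",
    predictor: str = "rf",
    grid: Optional[Sequence[dict]] = None,
    seed: int = 0,
    kg_variant: str = "",
) -> EvalReport:
    """Stratified k-fold evaluation of one embedding/operator/classifier
    combination, reusing the supplied fold plan.

    For ``rf``/``xgb`` each fold runs an inner grid search on its training
    split only.  ``cosine`` ignores the operator and thresholds the cosine of
    the raw gene/disease embeddings.  Probability cut-off for the tree models
    is 0.5 (the data are balanced).
    """
    if len(folds.assignment) != len(dataset):
        raise ValueError("fold plan was not built from this dataset")
    labels = dataset.labels

    if predictor == "cosine":
        embeddings.require(sorted(dataset.genes | dataset.diseases))
        sims = np.array(
            [
                cosine_similarity(embeddings[p.gene_id], embeddings[p.disease_id])
                for p in dataset.pairs
            ]
        )
    else:
        X = pair_matrix(dataset, embeddings, operator)

    fold_waf, fold_prec, fold_rec = [], [], []
    chosen: list = []
    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        if predictor == "cosine":
            y_pred, thr = cosine_baseline(sims[tr], labels[tr], sims[te])
            chosen.append(thr)
        else:
            model, params = _fit_with_grid(predictor, X[tr], labels[tr], grid, seed)
            y_pred = model.predict(X[te])
            chosen.append(params)
        fold_waf.append(waf(labels[te], y_pred))
        fold_prec.append(float(precision_score(labels[te], y_pred, zero_division=0)))
        fold_rec.append(float(recall_score(labels[te], y_pred, zero_division=0)))

    report = EvalReport(
        fold_waf=fold_waf,
        fold_precision=fold_prec,
        fold_recall=fold_rec,
        operator=operator if predictor != "cosine" else "cosine",
        method=embeddings.method,
        predictor=predictor,
        kg_variant=kg_variant,
        fold_plan=folds,
        extras={"per_fold_choice": chosen, "seed": seed},
    )
    report.validate()
    return report


def compare_runs(
    report_a: EvalReport, report_b: EvalReport, alpha: float = 0.05
) -> SignificanceResult:
    """Paired two-sided Wilcoxon signed-rank test on per-fold WAFs.

    Both reports must share one fold plan.  Zero differences are dropped
    (standard Wilcoxon handling); if every pair ties the result is p = 1,
    not significant.
    """
    fa, fb = report_a.fold_plan, report_b.fold_plan
    if fa is None or fb is None or fa.k != fb.k or not np.array_equal(fa.assignment, fb.assignment):
        raise ValueError("reports do not share a fold plan")
    a = np.asarray(report_a.fold_waf)
    b = np.asarray(report_b.fold_waf)
    diffs = a - b
    if np.all(diffs == 0):
        return SignificanceResult(statistic=0.0, p_value=1.0, significant=False, alpha=alpha)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return SignificanceResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )
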