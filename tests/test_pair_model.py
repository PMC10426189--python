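"""Pair operators, the weighted-F metric, the cosine baseline,
cross-validation and significance testing."""

import numpy as np
import pytest

from ontogda.embeddings import EmbeddingTable
from ontogda.gda_dataset import FoldPlan, make_folds, sample_negatives
from ontogda.ontology_io import AssociationRecord
from ontogda.pair_model import (
    OPERATORS,
    EvalReport,
    combine,
    compare_runs,
    cosine_baseline,
    cosine_similarity,
    cross_validate,
    waf,
)


class TestCombine:
    @pytest.mark.parametrize(
        "op,g,d,expected",
        [
            ("hadamard", (1, 2, 3), (4, 5, 6), (4, 10, 18)),
            ("weighted-L1", (1, 5), (4, 2), (3, 3)),
            ("weighted-L2", (1, 5), (4, 2), (9, 9)),
            ("average", (1, 5), (4, 2), (2.5, 3.5)),
            ("concatenation", (1, 2), (3, 4), (1, 2, 3, 4)),
        ],
    )
    def test_formulas(self, op, g, d, expected):
        assert combine(np.array(g), np.array(d), op).values == pytest.approx(expected)

    def test_concatenation_doubles_size(self):
        rng = np.random.default_rng(0)
        g, d = rng.normal(size=(2, 200))
        assert combine(g, d, "concatenation").size == 400
        for op in ("hadamard", "average", "weighted-L1", "weighted-L2"):
            assert combine(g, d, op).size == 200

    def test_symmetry_of_all_but_concatenation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g, d = rng.normal(size=(2, 10))
            for op in OPERATORS:
                ab = combine(g, d, op).values
                ba = combine(d, g, op).values
                if op == "concatenation":
                    assert not np.allclose(ab, ba)
                else:
                    assert np.allclose(ab, ba)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine(np.ones(3), np.ones(4), "hadamard")
        with pytest.raises(ValueError, match="unknown operator"):
            combine(np.ones(3), np.ones(3), "frobnicate")


class TestWaf:
    def test_hand_computed_example(self):
        # class 1: P=1, R=1/2, F=2/3; class 0: P=2/3, R=1, F=4/5
        assert waf([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(11 / 15)

    def test_perfect(self):
        assert waf([0, 1, 1], [0, 1, 1]) == 1.0

    def test_balanced_equals_macro_mean(self):
        labels = [1, 1, 0, 0]
        preds = [1, 0, 1, 0]
        from sklearn.metrics import f1_score

        macro = f1_score(labels, preds, average="macro")
        assert waf(labels, preds) == pytest.approx(macro)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            waf([1, 0], [1])

    def test_matches_brute_force_confusion_matrix(self):
        """Independent oracle: per-class F1 from explicit confusion counts,
        weighted by support."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            labels = rng.integers(0, 2, n)
            if len(set(labels)) < 2:
                labels[0] = 1 - labels[0]
            preds = rng.integers(0, 2, n)
            expected = 0.0
            for cls in (0, 1):
                tp = np.sum((labels == cls) & (preds == cls))
                fp = np.sum((labels != cls) & (preds == cls))
                fn = np.sum((labels == cls) & (preds != cls))
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                f = 2 * p * r / (p + r) if p + r else 0.0
                expected += f * np.sum(labels == cls) / n
            assert waf(labels, preds) == pytest.approx(expected)


class TestCosine:
    def test_identical_and_orthogonal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_similarity(np.zeros(3), v) == 0.0

    def test_threshold_learned_on_separable_sims(self):
        train_sims = np.array([0.95, 0.9, 0.92, 0.05, 0.1, 0.02])
        train_labels = np.array([1, 1, 1, 0, 0, 0])
        preds, thr = cosine_baseline(train_sims, train_labels, train_sims)
        assert 0.1 < thr <= 0.9
        assert waf(train_labels, preds) == 1.0

    def test_smallest_maximizer_on_ties(self):
        sims = np.array([0.9, 0.1])
        labels = np.array([1, 0])
        _, thr = cosine_baseline(sims, labels, sims, grid=np.array([0.2, 0.5, 0.8]))
        assert thr == 0.2


def separable_setup(n_pairs=40, dim=12, seed=0, aligned=True):
    """Embeddings in which a pair is positive iff gene and disease vectors
    point the same way along the first axis (labels are a deterministic
    function of one pair-vector coordinate)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_pairs)]
    diseases = [f"d{i}" for i in range(n_pairs)]
    vectors = {}
    pairs = []
    for i in range(n_pairs):
        label = i % 2
        sign_g = 1.0 if rng.random() < 0.5 else -1.0
        sign_d = sign_g if label else -sign_g
        vg = rng.normal(scale=0.05, size=dim)
        vd = rng.normal(scale=0.05, size=dim)
        vg[0] = sign_g
        vd[0] = sign_d
        vectors[genes[i]] = vg
        vectors[diseases[i]] = vd
        pairs.append(AssociationRecord(genes[i], diseases[i], frozenset(), label))
    from ontogda.gda_dataset import PairDataset

    ds = PairDataset(pairs=pairs, seed=seed)
    table = EmbeddingTable(vectors=vectors, dimension=dim, method="synthetic")
    return ds, table


class TestCrossValidate:
    def test_separable_fixture_perfect_rf(self):
        ds, table = separable_setup()
        folds = make_folds(ds, k=5, seed=0)
        rep = cross_validate(
            ds, folds, table, operator="hadamard", predictor="rf",
            grid=[{"n_estimators": 50, "max_depth": None}], seed=0,
        )
        assert rep.median_waf == 1.0

    def test_separable_fixture_perfect_cosine(self):
        ds, table = separable_setup()
        folds = make_folds(ds, k=5, seed=0)
        rep = cross_validate(ds, folds, table, predictor="cosine", seed=0)
        assert rep.median_waf == 1.0

    def test_shuffled_labels_give_chance(self):
        wafs = []
        for seed in range(5):
            ds, table = separable_setup(n_pairs=60, seed=seed)
            rng = np.random.default_rng(seed)
            labels = np.array([p.label for p in ds.pairs])
            rng.shuffle(labels)
            ds.pairs = [
                AssociationRecord(p.gene_id, p.disease_id, p.sources, int(l))
                for p, l in zip(ds.pairs, labels)
            ]
            folds = make_folds(ds, k=5, seed=seed)
            rep = cross_validate(
                ds, folds, table, operator="hadamard", predictor="rf",
                grid=[{"n_estimators": 50, "max_depth": None}], seed=seed,
            )
            wafs.append(rep.median_waf)
        assert abs(np.mean(wafs) - 0.5) < 0.1

    def test_missing_embedding_is_reported(self):
        ds, table = separable_setup()
        del table.vectors["g0"]
        folds = make_folds(ds, k=5, seed=0)
        with pytest.raises(KeyError, match="g0"):
            cross_validate(ds, folds, table, predictor="cosine", seed=0)

    def test_fold_plan_reuse_identical_indices(self):
        ds, _ = separable_setup()
        a = make_folds(ds, k=5, seed=3)
        b = make_folds(ds, k=5, seed=3)
        for f in range(5):
            assert np.array_equal(a.test_indices(f), b.test_indices(f))
            assert np.array_equal(a.train_indices(f), b.train_indices(f))

    def test_xgb_path_runs(self):
        ds, table = separable_setup(n_pairs=30)
        folds = make_folds(ds, k=3, seed=0)
        rep = cross_validate(
            ds, folds, table, operator="hadamard", predictor="xgb",
            grid=[{"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3}], seed=0,
        )
        assert rep.median_waf > 0.9


def report(wafs, plan):
    k = len(wafs)
    return EvalReport(
        fold_waf=list(wafs),
        fold_precision=[0.5] * k,
        fold_recall=[0.5] * k,
        operator="hadamard",
        method="m",
        predictor="rf",
        fold_plan=plan,
    )


class TestCompareRuns:
    def plan(self, k=10):
        return FoldPlan(k=k, assignment=np.arange(k), seed=0)

    def test_self_comparison_not_significant(self):
        plan = self.plan()
        a = report([0.7] * 10, plan)
        res = compare_runs(a, a)
        assert res.p_value == 1.0
        assert not res.significant

    def test_clear_difference_flagged(self):
        plan = self.plan()
        res = compare_runs(report([0.9] * 10, plan), report([0.5] * 10, plan))
        assert res.significant
        # exact two-sided signed-rank p for 10 concordant differences
        assert res.p_value == pytest.approx(2 / 2**10, rel=1e-6)

    def test_single_tiny_difference_not_significant(self):
        plan = self.plan()
        wafs = [0.7] * 10
        wafs_b = list(wafs)
        wafs_b[3] += 1e-9
        res = compare_runs(report(wafs, plan), report(wafs_b, plan))
        assert not res.significant

    def test_differing_fold_plans_rejected(self):
        a = report([0.7] * 10, self.plan())
        b = report([0.7] * 10, FoldPlan(k=10, assignment=np.arange(10)[::-1], seed=1))
        with pytest.raises(ValueError):
            compare_runs(a, b)

    def test_median_invariant_to_fold_order(self):
        plan = self.plan()
        wafs = [0.1, 0.9, 0.5, 0.4, 0.6, 0.3, 0.7, 0.2, 0.8, 0.55]
        assert report(wafs, plan).median_waf == report(wafs[::-1], plan).median_waf
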