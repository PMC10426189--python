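"""Knowledge-graph embedding engines.

Four methods produce fixed-dimension vectors (default 200) for graph
entities:

* **rdf2vec** — uniform random walks over the directed triple graph
  (equivalence edges traversed both ways) fed to a skip-gram with negative
  sampling trainer.  Only the requested start entities are walked, but every
  token seen in the corpus receives a vector.
* **axiom-sentence** — each triple becomes a three-token sentence and each
  labelled entity a sentence of its identifier followed by its tokenized
  label; the same skip-gram trainer runs on that corpus.  This captures both
  graph structure and lexical signal without any pretrained text model.
* **transe** — translational distance model trained with a margin ranking
  loss over corrupted triples, entity vectors renormalized to the unit ball.
* **distmult** — bilinear-diagonal semantic matching model trained with a
  logistic loss over corrupted triples plus L2 regularization.

All training is seeded, single-threaded numpy, and deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kg_builder import EQUIVALENT_TO, KnowledgeGraph

__all__ = [
    "WalkCorpus",
    "EmbeddingTable",
    "generate_walks",
    "train_skipgram",
    "build_axiom_sentences",
    "transe_score",
    "distmult_score",
    "train_triple_model",
    "embed",
]

DEFAULT_DIM = 200
DEFAULT_WALKS = 500
DEFAULT_DEPTH = 4


@dataclass
class WalkCorpus:
    """A list of token sentences plus the parameters that generated them."""

    sentences: list[list[str]]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sentences)

    def vocabulary(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sentences:
            for tok in s:
                seen.setdefault(tok)
        return sorted(seen)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sentences:
                fh.write(" ".join(s) + "\n")


@dataclass
class EmbeddingTable:
    """Entity → fixed-dimension real vector map."""

    vectors: dict[str, np.ndarray]
    dimension: int
    method: str
    params: dict = field(default_factory=dict)

    def __getitem__(self, entity: str) -> np.ndarray:
        return self.vectors[entity]

    def __contains__(self, entity: str) -> bool:
        return entity in self.vectors

    def require(self, entities: Sequence[str]) -> None:
        missing = sorted(e for e in entities if e not in self.vectors)
        if missing:
            raise KeyError(f"no embedding for entities: {missing[:10]}")

    def validate(self) -> None:
        for e, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {e!r} has shape {v.shape}, expected ({self.dimension},)")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in vector for {e!r}")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[e])
                fh.write(f"{e}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, method: str = "loaded") -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for line in fh:
                entity, _, vals = line.rstrip("\n").partition("\t")
                vec = np.array([float(x) for x in vals.split()], dtype=np.float64)
                vectors[entity] = vec
                dim = len(vec)
        return cls(vectors=vectors, dimension=dim or 0, method=method)


# ---------------------------------------------------------------------------
# Walk generation
# ---------------------------------------------------------------------------


def _adjacency(kg: KnowledgeGraph) -> dict[str, list[tuple[str, str]]]:
    """Outgoing (predicate, neighbour) lists; equivalence edges go both ways.

    Literals/labels are not part of the triple set and are therefore never
    walked.  Sorted for determinism.
    """
    adj: dict[str, list[tuple[str, str]]] = {}
    for s, p, o in kg.triples:
        adj.setdefault(s, []).append((p, o))
        if p == EQUIVALENT_TO:
            adj.setdefault(o, []).append((p, s))
    for k in adj:
        adj[k].sort()
    return adj


def generate_walks(
    kg: KnowledgeGraph,
    n_walks: int = DEFAULT_WALKS,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    start_entities: Optional[Sequence[str]] = None,
) -> WalkCorpus:
    """Generate ``n_walks`` uniform random walks of at most ``depth`` hops
    from each start entity (default: every gene and disease).

    Sentences interleave predicate tokens between entity tokens, so a walk of
    h hops yields 2h+1 tokens.  An isolated start entity emits its singleton
    sentence.  Deterministic for a fixed seed.
    """
    if n_walks < 1 or depth < 1:
        raise ValueError("n_walks and depth must be >= 1")
    if start_entities is None:
        start_entities = sorted(
            e for e, kind in kg.entities.items() if kind in ("gene", "disease")
        )
    else:
        start_entities = list(start_entities)
    adj = _adjacency(kg)
    rng = np.random.default_rng(seed)
    sentences: list[list[str]] = []
    for start in start_entities:
        for _ in range(n_walks):
            tokens = [start]
            node = start
            for _ in range(depth):
                nbrs = adj.get(node)
                if not nbrs:
                    break
                pred, nxt = nbrs[rng.integers(len(nbrs))]
                tokens.extend((pred, nxt))
                node = nxt
            sentences.append(tokens)
    return WalkCorpus(
        sentences=sentences,
        params={"n_walks": n_walks, "depth": depth, "seed": seed,
                "n_start_entities": len(start_entities)},
    )


def build_axiom_sentences(kg: KnowledgeGraph) -> WalkCorpus:
    """One sentence per triple plus one sentence per labelled entity (the
    entity token followed by its lower-cased, tokenized label)."""
    sentences: list[list[str]] = [[s, p, o] for s, p, o in sorted(kg.triples)]
    for entity in sorted(kg.labels):
        label_tokens = kg.labels[entity].lower().split()
        if label_tokens:
            sentences.append([entity, *label_tokens])
    return WalkCorpus(sentences=sentences, params={"kind": "axiom-sentence"})


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling (SGNS)
# ---------------------------------------------------------------------------


def train_skipgram(
    corpus: WalkCorpus,
    dim: int = DEFAULT_DIM,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negatives: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    batch_size: int = 256,
    subsample: float = 1e-3,
    require: Optional[Sequence[str]] = None,
) -> EmbeddingTable:
    """Train skip-gram embeddings with negative sampling on a token corpus.

    Very frequent tokens (predicates, mostly) are down-sampled with the usual
    sqrt(t/f) rule before windowing; center/context pairs come from a fixed
    symmetric window; negatives are drawn from the unigram distribution
    raised to 3/4; logits are clamped to ±6 for stability.  The learning
    rate decays linearly over all updates.  Input vectors are returned.
    """
    if not corpus.sentences:
        raise ValueError("cannot train on an empty corpus")
    vocab = corpus.vocabulary()
    index = {tok: i for i, tok in enumerate(vocab)}
    if require is not None:
        missing = sorted(e for e in require if e not in index)
        if missing:
            raise KeyError(f"entities absent from corpus vocabulary: {missing[:10]}")

    rng = np.random.default_rng(seed)

    raw_counts = np.zeros(len(vocab), dtype=np.int64)
    encoded = []
    for sent in corpus.sentences:
        ids = [index[t] for t in sent]
        for i in ids:
            raw_counts[i] += 1
        encoded.append(ids)
    keep_p = np.ones(len(vocab))
    if subsample > 0:
        freq = raw_counts / raw_counts.sum()
        # only genuinely frequent tokens (predicates, hubs) are down-sampled;
        # rare tokens in small corpora are always kept
        frequent = raw_counts > 100
        keep_p[frequent] = np.minimum(
            1.0, np.sqrt(subsample / np.maximum(freq[frequent], 1e-12))
        )

    centers_list: list[int] = []
    contexts_list: list[int] = []
    counts = np.zeros(len(vocab), dtype=np.int64)
    for ids in encoded:
        kept = [i for i in ids if keep_p[i] >= 1.0 or rng.random() < keep_p[i]]
        for i in kept:
            counts[i] += 1
        n = len(kept)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_list.append(kept[i])
                    contexts_list.append(kept[j])
    centers = np.array(centers_list, dtype=np.int64)
    contexts = np.array(contexts_list, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus produced no training pairs")

    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))

    noise = np.maximum(counts, 1).astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    total_updates = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            batch = order[lo : lo + batch_size]
            c = centers[batch]
            ctx = contexts[batch]
            neg = np.searchsorted(noise_cdf, rng.random((len(batch), negatives)))

            alpha = max(min_lr, lr * (1 - step / total_updates))
            step += 1

            h = w_in[c]  # (B, d)
            # positive contexts
            v_pos = w_out[ctx]
            logit_pos = np.clip(np.einsum("bd,bd->b", h, v_pos), -6.0, 6.0)
            g_pos = _sigmoid(logit_pos) - 1.0  # (B,)
            # negative samples
            v_neg = w_out[neg]  # (B, k, d)
            logit_neg = np.clip(np.einsum("bd,bkd->bk", h, v_neg), -6.0, 6.0)
            g_neg = _sigmoid(logit_neg)  # (B, k)

            grad_h = g_pos[:, None] * v_pos + np.einsum("bk,bkd->bd", g_neg, v_neg)
            np.add.at(w_in, c, -alpha * grad_h)
            np.add.at(w_out, ctx, -alpha * g_pos[:, None] * h)
            np.add.at(
                w_out,
                neg.ravel(),
                (-alpha * g_neg[:, :, None] * h[:, None, :]).reshape(-1, dim),
            )

    table = EmbeddingTable(
        vectors={tok: w_in[i].copy() for tok, i in index.items()},
        dimension=dim,
        method=corpus.params.get("kind", "rdf2vec"),
        params={
            "dim": dim, "window": window, "epochs": epochs, "seed": seed,
            "negatives": negatives, "lr": lr,
        },
    )
    table.validate()
    return table


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Triple-scoring models
# ---------------------------------------------------------------------------


def transe_score(h: np.ndarray, r: np.ndarray, t: np.ndarray, norm: str = "L2") -> float:
    """Translational plausibility: ‖h + r − t‖ (lower is more plausible)."""
    h, r, t = (np.asarray(v, dtype=np.float64) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError(f"dimension mismatch: {h.shape}, {r.shape}, {t.shape}")
    diff = h + r - t
    if norm == "L1":
        return float(np.abs(diff).sum())
    if norm == "L2":
        return float(np.sqrt((diff * diff).sum()))
    raise ValueError(f"norm must be L1 or L2, got {norm!r}")


def distmult_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Bilinear-diagonal plausibility: Σ_i h_i r_i t_i (higher is more
    plausible); symmetric in h and t."""
    h, r, t = (np.asarray(v, dtype=np.float64) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError(f"dimension mismatch: {h.shape}, {r.shape}, {t.shape}")
    return float(np.sum(h * r * t))


def train_triple_model(
    kg: KnowledgeGraph,
    method: str = "transe",
    dim: int = DEFAULT_DIM,
    epochs: int = 100,
    lr: float = 0.05,
    neg_ratio: int = 1,
    margin: float = 1.0,
    l2: float = 1e-4,
    seed: int = 0,
    batch_size: int = 512,
    norm: str = "L2",
) -> EmbeddingTable:
    """Train TransE (margin ranking, entities renormalized each step) or
    DistMult (logistic loss + L2) on the graph's triples, embedding every
    registered entity.  Corrupted negatives replace the head or tail
    uniformly.  Deterministic for a fixed seed."""
    if method not in ("transe", "distmult"):
        raise ValueError(f"method must be transe or distmult, got {method!r}")
    triples = sorted(kg.triples)
    if not triples:
        raise ValueError("cannot train on an empty knowledge graph")
    entities = sorted(kg.entities)
    relations = sorted({p for _, p, _ in triples})
    e_idx = {e: i for i, e in enumerate(entities)}
    r_idx = {r: i for i, r in enumerate(relations)}
    heads = np.array([e_idx[s] for s, _, _ in triples])
    rels = np.array([r_idx[p] for _, p, _ in triples])
    tails = np.array([e_idx[o] for _, _, o in triples])
    triple_set = set(zip(heads.tolist(), rels.tolist(), tails.tolist()))
    n = len(triples)

    rng = np.random.default_rng(seed)
    bound = 6.0 / np.sqrt(dim)
    E = rng.uniform(-bound, bound, (len(entities), dim))
    R = rng.uniform(-bound, bound, (len(relations), dim))
    if method == "transe":
        R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)

    history = []
    for _ in range(epochs):
        if method == "transe":
            E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1.0)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, batch_size):
            batch = order[lo : lo + batch_size]
            h, r, t = heads[batch], rels[batch], tails[batch]
            if neg_ratio > 1:
                h = np.repeat(h, neg_ratio)
                r = np.repeat(r, neg_ratio)
                t = np.repeat(t, neg_ratio)
            h_neg, t_neg = _corrupt(h, r, t, len(entities), triple_set, rng)
            if method == "transe":
                epoch_loss += _transe_step(E, R, h, r, t, h_neg, t_neg, lr, margin, norm)
            else:
                epoch_loss += _distmult_step(E, R, h, r, t, h_neg, t_neg, lr, l2)
        history.append(epoch_loss / n)

    table = EmbeddingTable(
        vectors={e: E[i].copy() for e, i in e_idx.items()},
        dimension=dim,
        method=method,
        params={
            "dim": dim, "epochs": epochs, "lr": lr, "neg_ratio": neg_ratio,
            "margin": margin, "l2": l2, "seed": seed, "loss_history": history,
            "relations": {r: R[i].copy() for r, i in r_idx.items()},
        },
    )
    table.validate()
    return table


def _corrupt(h, r, t, n_entities, triple_set, rng):
    """Replace head or tail (coin flip each) with a random entity, re-drawing
    any corruption that collides with a known positive triple."""
    h_neg, t_neg = h.copy(), t.copy()
    corrupt_head = rng.random(len(h)) < 0.5
    replacement = rng.integers(0, n_entities, len(h))
    h_neg[corrupt_head] = replacement[corrupt_head]
    t_neg[~corrupt_head] = replacement[~corrupt_head]
    for i in range(len(h)):
        tries = 0
        while (int(h_neg[i]), int(r[i]), int(t_neg[i])) in triple_set and tries < 20:
            repl = int(rng.integers(0, n_entities))
            if corrupt_head[i]:
                h_neg[i] = repl
            else:
                t_neg[i] = repl
            tries += 1
    return h_neg, t_neg


def _transe_step(E, R, h, r, t, h_neg, t_neg, lr, margin, norm):
    d_pos = E[h] + R[r] - E[t]
    d_neg = E[h_neg] + R[r] - E[t_neg]
    if norm == "L1":
        s_pos = np.abs(d_pos).sum(axis=1)
        s_neg = np.abs(d_neg).sum(axis=1)
        g_pos, g_neg = np.sign(d_pos), np.sign(d_neg)
    else:
        s_pos = np.linalg.norm(d_pos, axis=1)
        s_neg = np.linalg.norm(d_neg, axis=1)
        g_pos = d_pos / np.maximum(s_pos[:, None], 1e-12)
        g_neg = d_neg / np.maximum(s_neg[:, None], 1e-12)
    viol = margin + s_pos - s_neg > 0
    if not viol.any():
        return 0.0
    gp = lr * g_pos[viol]
    gn = lr * g_neg[viol]
    np.add.at(E, h[viol], -gp)
    np.add.at(E, t[viol], gp)
    np.add.at(R, r[viol], -gp + gn)
    np.add.at(E, h_neg[viol], gn)
    np.add.at(E, t_neg[viol], -gn)
    return float(np.maximum(margin + s_pos - s_neg, 0).sum())


def _distmult_step(E, R, h, r, t, h_neg, t_neg, lr, l2):
    def grads(hi, ri, ti, label):
        s = np.sum(E[hi] * R[ri] * E[ti], axis=1)
        p = _sigmoid(s)
        g = p - label  # d loss / d score
        gh = g[:, None] * R[ri] * E[ti] + l2 * E[hi]
        gt = g[:, None] * R[ri] * E[hi] + l2 * E[ti]
        gr = g[:, None] * E[hi] * E[ti] + l2 * R[ri]
        loss = -(label * np.log(np.maximum(p, 1e-12))
                 + (1 - label) * np.log(np.maximum(1 - p, 1e-12)))
        return gh, gr, gt, float(loss.sum())

    gh, gr, gt, l_pos = grads(h, r, t, 1.0)
    np.add.at(E, h, -lr * gh)
    np.add.at(R, r, -lr * gr)
    np.add.at(E, t, -lr * gt)
    gh, gr, gt, l_neg = grads(h_neg, r, t_neg, 0.0)
    np.add.at(E, h_neg, -lr * gh)
    np.add.at(R, r, -lr * gr)
    np.add.at(E, t_neg, -lr * gt)
    return l_pos + l_neg


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------


def embed(
    kg: KnowledgeGraph,
    method: str = "rdf2vec",
    dim: int = DEFAULT_DIM,
    seed: int = 0,
    n_walks: int = DEFAULT_WALKS,
    depth: int = DEFAULT_DEPTH,
    window: int = 5,
    epochs: Optional[int] = None,
    require: Optional[Sequence[str]] = None,
    start_entities: Optional[Sequence[str]] = None,
    **kwargs,
) -> EmbeddingTable:
    """Produce embeddings for a knowledge graph with the named method.

    Walk-based methods (``rdf2vec``) walk only the gene/disease entities (or
    an explicit ``start_entities`` list); ``axiom-sentence`` and the triple
    models (``transe``, ``distmult``) cover every entity in the graph.
    """
    if method == "rdf2vec":
        corpus = generate_walks(
            kg, n_walks=n_walks, depth=depth, seed=seed, start_entities=start_entities
        )
        table = train_skipgram(
            corpus, dim=dim, window=window, epochs=epochs or 5, seed=seed,
            require=require, **kwargs,
        )
        table.method = "rdf2vec"
        return table
    if method == "axiom-sentence":
        corpus = build_axiom_sentences(kg)
        table = train_skipgram(
            corpus, dim=dim, window=window, epochs=epochs or 5, seed=seed,
            require=require, **kwargs,
        )
        table.method = "axiom-sentence"
        return table
    if method in ("transe", "distmult"):
        table = train_triple_model(
            kg, method=method, dim=dim, epochs=epochs or 100, seed=seed, **kwargs
        )
        if require is not None:
            table.require(require)
        return table
    raise ValueError(f"unknown embedding method {method!r}")
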