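"""Node embeddings of the knowledge graph: Node2Vec and FastRP.

Node2Vec samples second-order biased random walks — the bias is the
piecewise transition weight 1/p (return), 1 (stay at distance one from the
previous node), 1/q (move outward) — and feeds the walk corpus to a
skip-gram model with negative sampling. The skip-gram trainer here is a
self-contained numpy implementation of the standard word2vec SGNS procedure
(two embedding tables, sigmoid scoring, unigram^0.75 negative distribution,
linearly decaying step size).

FastRP embeds by random projection of the adjacency matrix: draw a Gaussian
matrix R, orthonormalize A @ R by QR, and take X = A @ W with W the
orthonormal factor. This follows the single-projection description used by
the outlier-detection study; the canonical multi-iteration, degree-weighted
FastRP is available behind ``canonical=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import sparse

from .cohort import CohortTable
from .kgraph import KnowledgeGraph, adjacency_matrix, patient_node


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class WalkConfig:
    """Biased random-walk parameters (defaults are the original Node2Vec ones)."""

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise EmbeddingError("p and q must be > 0")
        if self.walk_length < 2:
            raise EmbeddingError("walk_length must be >= 2")


@dataclass(frozen=True)
class SkipGramConfig:
    """word2vec-style SGNS settings.

    ``subsample`` is the frequent-token threshold t: a node with relative
    corpus frequency z is kept with probability (sqrt(z/t) + 1) * t / z.
    On bipartite patient/risk-factor graphs a handful of hub value nodes
    dominate the walks; subsampling keeps their batched gradient updates
    bounded and is the standard word2vec treatment of hub tokens.
    """

    dim: int = 32
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    step_size: float = 0.025
    subsample: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1 or self.window < 1:
            raise EmbeddingError("dim and window must be >= 1")


@dataclass
class EmbeddingMatrix:
    """One row of ``vectors`` per entry of ``node_ids``, in that order."""

    node_ids: list[str]
    vectors: np.ndarray
    method_tag: str

    def __post_init__(self):
        if len(self.node_ids) != self.vectors.shape[0]:
            raise EmbeddingError("node_ids / vectors length mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, node_id: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node_id)]

    def save(self, path) -> None:
        """TSV (node_id + coordinates) with a JSON sidecar recording the method."""
        path = Path(path)
        with open(path, "w") as fh:
            cols = "\t".join(f"e{i}" for i in range(self.dim))
            fh.write(f"node_id\t{cols}\n")
            for nid, vec in zip(self.node_ids, self.vectors):
                fh.write(nid + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"method_tag": self.method_tag, "dim": self.dim,
                        "n_nodes": len(self.node_ids)}, indent=2)
        )


def _as_nx(g) -> nx.Graph:
    return g.nx if isinstance(g, KnowledgeGraph) else g


def transition_weights(g, prev_node, current_node, p: float, q: float) -> dict:
    """Unnormalized second-order walk weights over neighbours of ``current_node``.

    For a neighbour y, with d the shortest-path distance from ``prev_node``:
    weight 1/p if d(prev, y) = 0 (i.e. y is the previous node), 1 if
    d(prev, y) = 1, and 1/q otherwise. Normalizing to a probability
    distribution is left to the caller (see :func:`normalized_transition`).
    """
    if p <= 0 or q <= 0:
        raise EmbeddingError("p and q must be > 0")
    graph = _as_nx(g)
    if not graph.has_edge(prev_node, current_node):
        raise EmbeddingError(f"{prev_node!r} is not adjacent to {current_node!r}")
    prev_nbrs = set(graph.neighbors(prev_node))
    out = {}
    for y in graph.neighbors(current_node):
        if y == prev_node:
            out[y] = 1.0 / p
        elif y in prev_nbrs:
            out[y] = 1.0
        else:
            out[y] = 1.0 / q
    return out


def normalized_transition(g, prev_node, current_node, p: float, q: float) -> dict:
    w = transition_weights(g, prev_node, current_node, p, q)
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _uniform_walks(adj: sparse.csr_array, nodes: list, cfg: WalkConfig,
                   rng: np.random.Generator) -> list[list]:
    """Vectorized first-order walks for the unbiased p = q = 1 case.

    In an undirected graph a walk can only dead-end at an isolated start
    node, so non-isolated starts always reach full length.
    """
    n = len(nodes)
    deg = np.diff(adj.indptr)
    starts = np.tile(np.arange(n), cfg.walks_per_node)
    live = deg[starts] > 0
    cur = starts[live]
    steps = np.empty((cfg.walk_length, len(cur)), dtype=np.int64)
    steps[0] = cur
    for t in range(1, cfg.walk_length):
        u = rng.random(len(cur))
        picks = adj.indptr[cur] + (u * deg[cur]).astype(np.int64)
        cur = adj.indices[picks]
        steps[t] = cur
    walks: list[list] = []
    li = 0
    for j, s in enumerate(starts):
        if live[j]:
            walks.append([nodes[i] for i in steps[:, li]])
            li += 1
        else:
            walks.append([nodes[s]])
    return walks


def generate_walks(g, config: WalkConfig) -> list[list]:
    """Sample ``walks_per_node`` second-order walks from every node.

    Walks terminate early only at dead ends (isolated nodes yield length-1
    walks). With p = q = 1 the walk is first-order and a fast vectorized
    sampler is used; the general case samples each step from the normalized
    transition weights. Reproducible from ``config.seed``.
    """
    graph = _as_nx(g)
    if graph.number_of_nodes() == 0:
        raise EmbeddingError("empty graph")
    nodes = list(graph.nodes)
    rng = np.random.default_rng(config.seed)

    if config.p == 1.0 and config.q == 1.0:
        adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None,
                                       format="csr", dtype=np.int8)
        return _uniform_walks(adj, nodes, config, rng)

    nbrs = {u: list(graph.neighbors(u)) for u in nodes}
    nbr_sets = {u: set(v) for u, v in nbrs.items()}
    walks = []
    for _ in range(config.walks_per_node):
        for start in nodes:
            walk = [start]
            if not nbrs[start]:
                walks.append(walk)
                continue
            cur = nbrs[start][int(rng.integers(len(nbrs[start])))]
            walk.append(cur)
            while len(walk) < config.walk_length:
                cand = nbrs[cur]
                if not cand:
                    break
                prev = walk[-2]
                prev_nbrs = nbr_sets[prev]
                w = np.array([
                    1.0 / config.p if y == prev
                    else 1.0 if y in prev_nbrs
                    else 1.0 / config.q
                    for y in cand
                ])
                w /= w.sum()
                cur = cand[int(rng.choice(len(cand), p=w))]
                walk.append(cur)
            walks.append(walk)
    return walks


def _skipgram_pairs(corpus: list[list], vocab: dict, window: int):
    """(center, context) index pairs within ±window inside each walk, vectorized."""
    flat = np.fromiter((vocab[w] for walk in corpus for w in walk), dtype=np.int64)
    lengths = np.fromiter((len(walk) for walk in corpus), dtype=np.int64)
    walk_of = np.repeat(np.arange(len(lengths)), lengths)
    cs, os = [], []
    for off in range(1, window + 1):
        ok = np.flatnonzero(walk_of[off:] == walk_of[:-off]) if off < len(flat) else []
        if len(ok):
            a, b = flat[ok], flat[ok + off]
            cs.extend((a, b))
            os.extend((b, a))
    if not cs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(cs), np.concatenate(os)


def _scatter_add(target: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """target[idx] += updates with duplicate indices, via sorted reduceat."""
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    bounds = np.flatnonzero(np.r_[True, idx_s[1:] != idx_s[:-1]])
    sums = np.add.reduceat(updates[order], bounds, axis=0)
    target[idx_s[bounds]] += sums


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def skipgram_objective(emb_in: np.ndarray, emb_out: np.ndarray,
                       centers: np.ndarray, contexts: np.ndarray,
                       noise_cdf: np.ndarray, negatives: int,
                       rng: np.random.Generator) -> float:
    """Mean SGNS objective log s(u'v) + sum log s(-u'n) over all pairs."""
    pos = np.einsum("ij,ij->i", emb_in[centers], emb_out[contexts])
    obj = np.log(_sigmoid(pos) + 1e-12).mean()
    negs = np.searchsorted(noise_cdf, rng.random((len(centers), negatives)))
    neg_scores = np.einsum("ij,ikj->ik", emb_in[centers], emb_out[negs])
    obj += np.log(_sigmoid(-neg_scores) + 1e-12).sum(axis=1).mean()
    return float(obj)


def train_skipgram(corpus: list[list], config: SkipGramConfig,
                   return_history: bool = False) -> EmbeddingMatrix:
    """Skip-gram with negative sampling over a walk corpus.

    Vocabulary order is order of first appearance in the corpus. Negative
    contexts are drawn from the unigram distribution raised to 3/4. The step
    size decays linearly from ``step_size`` over the training pairs. With
    ``return_history=True`` also returns the per-epoch mean objective trace
    (evaluated on freshly sampled negatives, so stochastic).
    """
    if not corpus or not any(corpus):
        raise EmbeddingError("empty corpus")
    vocab: dict = {}
    counts: list[int] = []
    for walk in corpus:
        for w in walk:
            if w not in vocab:
                vocab[w] = len(vocab)
                counts.append(0)
            counts[vocab[w]] += 1
    V, d = len(vocab), config.dim
    if d >= V:
        import warnings
        warnings.warn(f"embedding dim {d} >= vocabulary size {V}", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    emb_in = (rng.random((V, d)) - 0.5) / d
    emb_out = np.zeros((V, d))

    work_corpus = corpus
    if config.subsample > 0:
        total = float(sum(counts))
        z = np.asarray(counts) / total
        t = config.subsample
        keep = np.minimum(1.0, (np.sqrt(z / t) + 1.0) * t / z)
        work_corpus = []
        for walk in corpus:
            kept = [w for w in walk if rng.random() < keep[vocab[w]]]
            if kept:
                work_corpus.append(kept)
        if not work_corpus:
            work_corpus = corpus

    centers, contexts = _skipgram_pairs(work_corpus, vocab, config.window)
    if len(centers) == 0:
        centers, contexts = _skipgram_pairs(corpus, vocab, config.window)
    noise = np.asarray(counts, dtype=float) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    history = []
    if return_history:
        history.append(skipgram_objective(emb_in, emb_out, centers, contexts,
                                          noise_cdf, config.negatives, rng))
    n_pairs = len(centers)
    total_steps = max(1, n_pairs * config.epochs)
    # batch scales with vocabulary: accumulating many stale-gradient updates
    # for one node in a single batch multiplies its effective step size, so
    # small vocabularies need small batches to stay stable
    batch, done = int(np.clip(4 * V, 32, 4096)), 0
    for _ in range(config.epochs):
        order = rng.permutation(n_pairs) if n_pairs else np.array([], dtype=int)
        for s in range(0, n_pairs, batch):
            sel = order[s:s + batch]
            c, o = centers[sel], contexts[sel]
            lr = config.step_size * max(1e-4, 1.0 - done / total_steps)
            negs = np.searchsorted(noise_cdf, rng.random((len(sel), config.negatives)))

            vin = emb_in[c]                                   # (B, d)
            g_pos = _sigmoid(np.einsum("ij,ij->i", vin, emb_out[o])) - 1.0
            g_neg = _sigmoid(np.einsum("ij,ikj->ik", vin, emb_out[negs]))

            grad_in = g_pos[:, None] * emb_out[o] + np.einsum(
                "ik,ikj->ij", g_neg, emb_out[negs])
            out_idx = np.concatenate([o, negs.ravel()])
            out_upd = np.concatenate([
                -lr * g_pos[:, None] * vin,
                -lr * (g_neg[:, :, None] * vin[:, None, :]).reshape(-1, d),
            ])
            _scatter_add(emb_out, out_idx, out_upd)
            _scatter_add(emb_in, c, -lr * grad_in)
            done += len(sel)
        if return_history:
            history.append(skipgram_objective(emb_in, emb_out, centers, contexts,
                                              noise_cdf, config.negatives, rng))

    em = EmbeddingMatrix(list(vocab), emb_in, f"node2vec {d}")
    if return_history:
        return em, history
    return em


def node2vec_embed(g, walk_config: WalkConfig, sg_config: SkipGramConfig) -> EmbeddingMatrix:
    """Walks + skip-gram, reordered to the graph's node order."""
    graph = _as_nx(g)
    corpus = generate_walks(g, walk_config)
    em = train_skipgram(corpus, sg_config)
    order = list(graph.nodes)
    lookup = {nid: i for i, nid in enumerate(em.node_ids)}
    vecs = np.zeros((len(order), em.dim))
    for i, nid in enumerate(order):
        if nid in lookup:  # isolated nodes may miss from pair corpus; stay zero
            vecs[i] = em.vectors[lookup[nid]]
    return EmbeddingMatrix(order, vecs, em.method_tag)


def fastrp_embed(g, dim: int, seed: int = 0, canonical: bool = False) -> EmbeddingMatrix:
    """Random-projection embedding of the graph adjacency.

    Default behaviour: R ~ iid N(0,1) of shape (|nodes|, dim); W is the
    orthonormal factor of the reduced QR of A @ R; row embeddings X = A @ W.
    W'W = I, and nodes with identical adjacency rows get exactly identical
    embeddings. ``canonical=True`` instead computes the iterated
    degree-normalized variant (sum of weighted powers of D^-1 A applied to a
    projection), which emphasises multi-hop structure.
    """
    graph = _as_nx(g)
    order = list(graph.nodes)
    n = len(order)
    if dim > n:
        raise EmbeddingError(f"dim {dim} exceeds node count {n}")
    A = nx.to_scipy_sparse_array(graph, nodelist=order, weight=None,
                                 format="csr", dtype=float)
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((n, dim))
    if canonical:
        deg = np.maximum(A.sum(axis=1), 1.0)
        L = sparse.diags(1.0 / deg) @ A
        h = L @ R
        X = np.zeros_like(h)
        for w in (0.0, 1.0, 1.0):  # weights over successive propagation depths
            if w:
                X += w * h
            h = L @ h
        return EmbeddingMatrix(order, X, f"fastrp-canonical {dim}")
    Q, _ = np.linalg.qr(A @ R)
    W = Q  # (n, dim), orthonormal columns
    X = A @ W
    return EmbeddingMatrix(order, X, f"fastrp {dim}")


def combine_embeddings(e1: EmbeddingMatrix, e2: EmbeddingMatrix) -> EmbeddingMatrix:
    """Row-wise concatenation of two embeddings over the same node order."""
    if e1.node_ids != e2.node_ids:
        raise EmbeddingError("node_ids mismatch between embeddings")
    d = e1.dim if e1.dim == e2.dim else None
    tag = f"combine {d}" if d else "combine"
    return EmbeddingMatrix(e1.node_ids, np.hstack([e1.vectors, e2.vectors]), tag)


def patient_embedding_block(e: EmbeddingMatrix, table: CohortTable) -> np.ndarray:
    """Patient-node rows of ``e`` in cohort row order (n_patients x dim)."""
    lookup = {nid: i for i, nid in enumerate(e.node_ids)}
    rows = []
    for pid in table.patient_id:
        nid = patient_node(pid)
        if nid not in lookup:
            raise EmbeddingError(f"no embedding row for patient {pid!r}")
        rows.append(lookup[nid])
    return e.vectors[np.asarray(rows)]
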