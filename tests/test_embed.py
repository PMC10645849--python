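import itertools

import networkx as nx
import numpy as np
import pytest

from perigraph.embed import (EmbeddingError, EmbeddingMatrix, SkipGramConfig,
                             WalkConfig, combine_embeddings, fastrp_embed,
                             generate_walks, node2vec_embed,
                             normalized_transition, patient_embedding_block,
                             train_skipgram, transition_weights)
from perigraph.kgraph import build_graph, patient_node


def bfs_distances(g: nx.Graph, source):
    """Independent oracle: plain breadth-first shortest-path distances."""
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_weights(g, prev, cur, p, q):
    dist = bfs_distances(g, prev)
    out = {}
    for y in g.neighbors(cur):
        d = dist.get(y, np.inf)
        out[y] = 1.0 / p if d == 0 else (1.0 if d == 1 else 1.0 / q)
    return out


class TestTransitionWeights:
    def test_piecewise_values(self):
        g = nx.path_graph(4)  # 0-1-2-3; prev=0, cur=1 -> nbrs {0, 2}
        w = transition_weights(g, 0, 1, p=2.0, q=0.5)
        assert w[0] == pytest.approx(0.5)   # return to prev: 1/p
        assert w[2] == pytest.approx(2.0)   # distance 2 from prev: 1/q
        g.add_edge(0, 2)                    # now 2 is adjacent to prev
        w = transition_weights(g, 0, 1, p=2.0, q=0.5)
        assert w[2] == pytest.approx(1.0)

    def test_unbiased_collapse(self):
        g = nx.complete_graph(5)
        w = transition_weights(g, 0, 1, p=1.0, q=1.0)
        assert all(v == 1.0 for v in w.values())

    def test_star_graph_leaves_at_distance_two(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        w = transition_weights(g, 1, 0, p=4.0, q=0.25)
        assert w[1] == pytest.approx(0.25)  # the previous leaf
        for leaf in range(2, 6):
            assert w[leaf] == pytest.approx(4.0)  # distance 2 via the center

    def test_non_adjacent_pair_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(EmbeddingError):
            transition_weights(g, 0, 3, p=1, q=1)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_exhaustive_small_graphs_match_bfs_oracle(self, n):
        """All labeled graphs on n nodes, all adjacent (prev, cur) pairs."""
        pairs = list(itertools.combinations(range(n), 2))
        for mask in range(1, 2 ** len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(e for i, e in enumerate(pairs) if mask >> i & 1)
            for u, v in g.edges:
                for prev, cur in ((u, v), (v, u)):
                    got = transition_weights(g, prev, cur, p=3.0, q=0.7)
                    assert got == oracle_weights(g, prev, cur, 3.0, 0.7)


class TestGenerateWalks:
    def test_path_graph_alternates(self):
        g = nx.path_graph(2)
        walks = generate_walks(g, WalkConfig(walk_length=6, walks_per_node=2, seed=0))
        for w in walks:
            assert len(w) == 6
            assert w[::2] == [w[0]] * 3 and w[1::2] == [1 - w[0]] * 3

    def test_every_node_starts_walks(self):
        g = nx.cycle_graph(5)
        cfg = WalkConfig(walk_length=10, walks_per_node=3, seed=1)
        walks = generate_walks(g, cfg)
        assert len(walks) == 15
        starts = [w[0] for w in walks]
        assert all(starts.count(v) == 3 for v in g.nodes)
        for w in walks:
            assert all(g.has_edge(a, b) for a, b in zip(w, w[1:]))

    def test_isolated_node_length_one(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(0, 1)
        walks = generate_walks(g, WalkConfig(walk_length=5, walks_per_node=1, seed=0))
        iso = [w for w in walks if w[0] == 2]
        assert iso == [[2]]

    def test_same_seed_identical_corpus(self):
        g = nx.karate_club_graph()
        cfg = WalkConfig(p=2.0, q=0.5, walk_length=10, walks_per_node=2, seed=9)
        assert generate_walks(g, cfg) == generate_walks(g, cfg)

    @pytest.mark.parametrize("p,q", [(1.0, 1.0), (4.0, 0.25)])
    def test_step_frequencies_match_normalized_weights(self, p, q):
        """Empirical (prev, cur) -> next frequencies vs the exact distribution."""
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])  # triangle + pendant
        cfg = WalkConfig(p=p, q=q, walk_length=2000, walks_per_node=13, seed=5)
        walks = generate_walks(g, cfg)
        counts: dict = {}
        total_steps = 0
        for w in walks:
            for a, b, c in zip(w, w[1:], w[2:]):
                counts.setdefault((a, b), {}).setdefault(c, 0)
                counts[(a, b)][c] += 1
                total_steps += 1
        assert total_steps >= 10 ** 5
        for (a, b), nxt_counts in counts.items():
            m = sum(nxt_counts.values())
            if m < 500:
                continue
            probs = normalized_transition(g, a, b, p, q)
            for c, prob in probs.items():
                se = np.sqrt(prob * (1 - prob) / m)
                assert abs(nxt_counts.get(c, 0) / m - prob) <= 3 * se + 1e-12


class TestSkipGram:
    def test_two_cliques_within_above_between(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        walks = generate_walks(g, WalkConfig(walk_length=20, walks_per_node=10, seed=0))
        em = train_skipgram(walks, SkipGramConfig(dim=8, window=4, epochs=5, seed=0,
                                                  subsample=0))
        V = em.vectors / np.linalg.norm(em.vectors, axis=1, keepdims=True)
        idx = {n: i for i, n in enumerate(em.node_ids)}
        a = [idx[n] for n in range(6)]
        b = [idx[n] for n in range(6, 12)]
        cos = V @ V.T
        within = np.mean([cos[i, j] for i in a for j in a if i != j] +
                         [cos[i, j] for i in b for j in b if i != j])
        between = np.mean([cos[i, j] for i in a for j in b])
        assert within > between

    def test_single_node_corpus(self):
        em = train_skipgram([["solo"]], SkipGramConfig(dim=4, seed=0))
        assert em.vectors.shape == (1, 4)
        assert np.all(np.isfinite(em.vectors))

    def test_objective_improves_over_training(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        walks = generate_walks(g, WalkConfig(walk_length=15, walks_per_node=8, seed=2))
        deltas = []
        for seed in range(5):
            _, hist = train_skipgram(
                walks, SkipGramConfig(dim=6, window=3, epochs=5, seed=seed,
                                      subsample=0),
                return_history=True)
            deltas.append(hist[-1] - hist[0])
        assert np.mean(deltas) > 0

    def test_determinism(self):
        g = nx.cycle_graph(8)
        walks = generate_walks(g, WalkConfig(walk_length=10, walks_per_node=4, seed=3))
        cfg = SkipGramConfig(dim=5, window=2, epochs=2, seed=4)
        a = train_skipgram(walks, cfg)
        b = train_skipgram(walks, cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_dim_exceeding_vocab_warns(self):
        with pytest.warns(UserWarning, match="vocabulary"):
            train_skipgram([["a", "b"]], SkipGramConfig(dim=8, epochs=1, seed=0))


class TestFastRP:
    def test_projection_is_orthonormal(self, small_cohort):
        g = build_graph(small_cohort)
        from perigraph.kgraph import adjacency_matrix
        A = adjacency_matrix(g).toarray()
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(A @ rng.standard_normal((A.shape[0], 16)))
        assert np.allclose(Q.T @ Q, np.eye(16), atol=1e-8)
        # and the embedding equals A @ W for that same construction
        em = fastrp_embed(g, 16, seed=0)
        np.testing.assert_allclose(em.vectors, A @ Q, atol=1e-10)

    def test_identical_adjacency_identical_rows(self, toy_schema):
        import pandas as pd
        from perigraph.cohort import CohortTable
        table = CohortTable(
            patient_id=pd.Index(["A", "B", "C"]),
            features=pd.DataFrame({"smoker": [1.0, 1.0, 0.0],
                                   "priorPTB": [0.0, 0.0, 1.0]}),
            parity=pd.Series(["parous"] * 3),
            labels=pd.DataFrame({"PTB": [0, 0, 1]}),
            schema=toy_schema,
        )
        g = build_graph(table)
        em = fastrp_embed(g, 4, seed=1)
        ia = em.node_ids.index(patient_node("A"))
        ib = em.node_ids.index(patient_node("B"))
        np.testing.assert_array_equal(em.vectors[ia], em.vectors[ib])

    def test_isolated_node_zero_row(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b")
        em = fastrp_embed(g, 2, seed=0)
        np.testing.assert_array_equal(em.row("c"), np.zeros(2))

    def test_projection_preserves_adjacency_geometry(self):
        g = nx.gnp_random_graph(200, 0.1, seed=42)
        A = nx.to_numpy_array(g)
        em = fastrp_embed(g, 128, seed=7)
        gram_a = (A @ A.T)[np.triu_indices(200, 1)]
        gram_x = (em.vectors @ em.vectors.T)[np.triu_indices(200, 1)]
        r = np.corrcoef(gram_a, gram_x)[0, 1]
        assert r > 0.9

    def test_dim_exceeding_nodes_rejected(self):
        with pytest.raises(EmbeddingError):
            fastrp_embed(nx.path_graph(3), 4, seed=0)

    def test_deterministic(self):
        g = nx.karate_club_graph()
        a, b = fastrp_embed(g, 8, seed=3), fastrp_embed(g, 8, seed=3)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestCombineAndBlocks:
    def test_combine_tag_and_width(self):
        ids = ["a", "b"]
        e1 = EmbeddingMatrix(ids, np.ones((2, 32)), "fastrp 32")
        e2 = EmbeddingMatrix(ids, np.zeros((2, 32)), "node2vec 32")
        c = combine_embeddings(e1, e2)
        assert c.dim == 64 and c.method_tag == "combine 32"
        np.testing.assert_array_equal(c.vectors[:, :32], e1.vectors)

    def test_zero_block_preserves_first(self):
        ids = ["a", "b", "c"]
        e = EmbeddingMatrix(ids, np.arange(6.0).reshape(3, 2), "fastrp 2")
        z = EmbeddingMatrix(ids, np.zeros((3, 2)), "node2vec 2")
        c = combine_embeddings(e, z)
        np.testing.assert_array_equal(c.vectors[:, :2], e.vectors)

    def test_node_mismatch_rejected(self):
        e1 = EmbeddingMatrix(["a"], np.ones((1, 2)), "fastrp 2")
        e2 = EmbeddingMatrix(["b"], np.ones((1, 2)), "node2vec 2")
        with pytest.raises(EmbeddingError):
            combine_embeddings(e1, e2)

    def test_patient_block_alignment(self, toy_table):
        g = build_graph(toy_table)
        em = fastrp_embed(g, 3, seed=0)
        block = patient_embedding_block(em, toy_table)
        assert block.shape == (3, 3)
        # reversing table row order reverses the block
        import pandas as pd
        rev = type(toy_table)(
            patient_id=toy_table.patient_id[::-1],
            features=toy_table.features.iloc[::-1].reset_index(drop=True),
            parity=pd.Series(list(toy_table.parity)[::-1]),
            labels=toy_table.labels.iloc[::-1].reset_index(drop=True),
            schema=toy_table.schema,
        )
        np.testing.assert_array_equal(patient_embedding_block(em, rev), block[::-1])

    def test_node2vec_rows_cover_all_nodes(self, toy_table):
        g = build_graph(toy_table)
        em = node2vec_embed(g, WalkConfig(walk_length=10, walks_per_node=5, seed=0),
                            SkipGramConfig(dim=4, window=3, epochs=2, seed=0))
        assert em.node_ids == list(g.nx.nodes)
        assert np.all(np.isfinite(em.vectors))
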