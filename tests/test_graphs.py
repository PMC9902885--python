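"""Graph construction, Louvain clustering, modularity, ordering, display."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gcorrnet import (
    EdgeList,
    GenCorrMatrix,
    LouvainClusterer,
    build_cluster_graph,
    display_graph,
    hclust_order,
    louvain,
    modularity,
    vech_dim,
)


def corr_matrix(S, labels=None):
    t = S.shape[0]
    labels = labels or [f"t{i}" for i in range(t)]
    return GenCorrMatrix(labels=labels, S=np.asarray(S, dtype=float),
                         V=np.zeros((vech_dim(t), vech_dim(t))),
                         pvals=np.full((t, t), np.nan))


def edge_list(nodes, triples):
    return EdgeList(nodes=list(nodes),
                    edges=pd.DataFrame(triples,
                                       columns=["trait_a", "trait_b", "weight"]))


def modularity_double_loop(edges, membership):
    """Independent oracle: Q = (1/2W) sum_ij [A_ij - s_i s_j / 2W] d(ci,cj)."""
    nodes = edges.nodes
    A = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for a, b, w in edges.edges.itertuples(index=False):
        A.loc[a, b] += w
        A.loc[b, a] += w
    two_w = A.to_numpy().sum()
    s = A.sum(axis=1)
    q = 0.0
    for i in nodes:
        for j in nodes:
            if membership[i] == membership[j]:
                q += A.loc[i, j] - s[i] * s[j] / two_w
    return q / two_w


def partitions_of(items):
    """All set partitions (Bell-number enumeration, fine for <= 7 items)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in partitions_of(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def random_graph(seed, max_nodes=7):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, max_nodes + 1)
    nodes = [f"v{i}" for i in range(n)]
    triples = []
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.6:
            triples.append((a, b, float(rng.uniform(0.05, 1.0))))
    if not triples:
        triples.append((nodes[0], nodes[1], 0.5))
    return edge_list(nodes, triples)


class TestBuildGraph:
    def test_absolute_values_used(self):
        m = corr_matrix(np.array([[1, -0.4, -0.4], [-0.4, 1, -0.4],
                                  [-0.4, -0.4, 1.0]]))
        e = build_cluster_graph(m)
        assert len(e.edges) == 3
        assert np.allclose(e.edges["weight"], 0.4)

    def test_missing_pair_omitted(self):
        S = np.array([[1, 0.5, np.nan], [0.5, 1, 0.3], [np.nan, 0.3, 1.0]])
        e = build_cluster_graph(corr_matrix(S))
        assert len(e.edges) == 2

    def test_identity_gives_empty_edges(self):
        e = build_cluster_graph(corr_matrix(np.eye(4)))
        assert e.edges.empty

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError):
            build_cluster_graph(corr_matrix(np.ones((1, 1))))


class TestModularity:
    def test_single_cluster_zero(self):
        e = random_graph(0)
        assert modularity(e, {v: 0 for v in e.nodes}) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self):
        nodes = ["a", "b", "c", "d", "e", "f"]
        triples = [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0),
                   ("d", "e", 1.0), ("d", "f", 1.0), ("e", "f", 1.0)]
        mem = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity(edge_list(nodes, triples), mem) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        for seed in range(5):
            e = random_graph(seed)
            rng = np.random.default_rng(100 + seed)
            mem = {v: int(rng.integers(0, 3)) for v in e.nodes}
            assert modularity(e, mem) == pytest.approx(
                modularity_double_loop(e, mem), abs=1e-12)

    def test_unknown_vertex_rejected(self):
        e = edge_list(["a", "b"], [("a", "b", 1.0)])
        with pytest.raises(ValueError):
            modularity(e, {"a": 0, "b": 0, "zzz": 1})


class TestLouvain:
    def test_planted_cliques_recovered(self):
        nodes = [f"v{i}" for i in range(6)]
        triples = [(a, b, 1.0) for a, b in itertools.combinations(nodes[:3], 2)]
        triples += [(a, b, 1.0) for a, b in itertools.combinations(nodes[3:], 2)]
        triples.append((nodes[0], nodes[3], 0.05))
        part = louvain(edge_list(nodes, triples), seed=1)
        assert len(set(part.membership.values())) == 2
        assert len({part.membership[v] for v in nodes[:3]}) == 1
        assert len({part.membership[v] for v in nodes[3:]}) == 1

    def test_single_clique_one_cluster(self):
        nodes = ["a", "b", "c", "d"]
        triples = [(a, b, 1.0) for a, b in itertools.combinations(nodes, 2)]
        e = edge_list(nodes, triples)
        part = louvain(e, seed=1)
        assert len(set(part.membership.values())) == 1
        assert part.q == pytest.approx(0.0)

    def test_beats_trivial_partitions(self):
        for seed in range(5):
            e = random_graph(seed + 50)
            part = louvain(e, seed=1)
            q_one = modularity(e, {v: 0 for v in e.nodes})
            q_single = modularity(e, {v: i for i, v in enumerate(e.nodes)})
            assert part.q >= q_one - 1e-12
            assert part.q >= q_single - 1e-12

    def test_relabeling_invariance(self):
        e = random_graph(7)
        part = louvain(e, seed=3)
        renamed = edge_list(
            [v.upper() for v in e.nodes],
            [(a.upper(), b.upper(), w)
             for a, b, w in e.edges.itertuples(index=False)],
        )
        part2 = louvain(renamed, seed=3)
        assert part2.q == pytest.approx(part.q, abs=1e-12)
        groups1 = {frozenset(v for v in e.nodes
                             if part.membership[v] == c)
                   for c in set(part.membership.values())}
        groups2 = {frozenset(v.lower() for v in renamed.nodes
                             if part2.membership[v] == c)
                   for c in set(part2.membership.values())}
        assert groups1 == groups2

    def test_matches_exhaustive_maximum_usually(self):
        """On tiny graphs Louvain finds the global modularity optimum."""
        hits = 0
        n_graphs = 20
        for seed in range(n_graphs):
            e = random_graph(seed + 200)
            part = louvain(e, seed=1)
            best = max(
                modularity(e, {v: k for k, blk in enumerate(p) for v in blk})
                for p in partitions_of(e.nodes)
            )
            if part.q >= best - 1e-10:
                hits += 1
        assert hits >= 18

    def test_estimator_interface(self):
        S = np.full((6, 6), 0.05)
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.9
        np.fill_diagonal(S, 1.0)
        clus = LouvainClusterer(seed=1).fit(corr_matrix(S))
        assert len(set(clus.labels_)) == 2
        assert clus.modularity_ > 0.3
        assert clus.get_params() == {"seed": 1}


class TestHclustOrder:
    def test_strong_pair_adjacent(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.9
        order = hclust_order(corr_matrix(S, labels=["A", "B", "C", "D"]))
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_identity_preserves_input_order(self):
        order = hclust_order(corr_matrix(np.eye(5)))
        assert order == [f"t{i}" for i in range(5)]

    def test_is_a_permutation(self, planted_two_block):
        order = hclust_order(planted_two_block)
        assert sorted(order) == sorted(planted_two_block.labels)


class TestDisplayGraph:
    def test_star_center_max_centrality(self):
        t = 6
        S = np.eye(t)
        S[0, 1:] = S[1:, 0] = 0.5
        edges, cent = display_graph(corr_matrix(S))
        assert cent.iloc[0] == pytest.approx(1.0)
        assert (cent.iloc[1:] < 1.0).all()

    def test_clique_equal_centrality(self):
        S = np.full((5, 5), 0.4)
        np.fill_diagonal(S, 1.0)
        _, cent = display_graph(corr_matrix(S))
        assert np.allclose(cent, 1.0)

    def test_threshold_empties_graph(self):
        S = np.full((4, 4), 0.08)
        np.fill_diagonal(S, 1.0)
        edges, _ = display_graph(corr_matrix(S))
        assert edges.edges.empty

    def test_subgraph_of_full_graph_with_topk(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(15, 30))
        S = np.corrcoef(a)
        m = corr_matrix(S)
        disp, _ = display_graph(m, k=3, min_abs=0.10)
        full = build_cluster_graph(m)
        full_pairs = {frozenset((a_, b_))
                      for a_, b_, _ in full.edges.itertuples(index=False)}
        for a_, b_, w in disp.edges.itertuples(index=False):
            assert frozenset((a_, b_)) in full_pairs
            assert w > 0.10
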