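"""Trait graphs from genetic correlations: Louvain clustering, modularity,
hierarchical ordering, and the thresholded display graph.

The clustering graph is the complete weighted graph on the traits with edge
weight |r_G| — the sign is disregarded, so a consistently negative
correlation still binds two traits. Community structure is found with the
Louvain modularity heuristic (seeded, hence deterministic); the display
graph additionally keeps, per vertex, only the strongest k edges above an
absolute-correlation floor, with node importance given by eigenvector
centrality of the absolute correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .corrmat import GenCorrMatrix

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    """Undirected weighted edges over a fixed vertex set (no self-edges)."""

    nodes: list[str]
    edges: pd.DataFrame  # columns trait_a, trait_b, weight

    def __post_init__(self):
        e = self.edges
        if len(e):
            if not np.isfinite(e["weight"].to_numpy(dtype=float)).all():
                raise ValueError("edge weights must be finite")
            keys = {frozenset((a, b)) for a, b in zip(e["trait_a"], e["trait_b"])}
            if len(keys) != len(e):
                raise ValueError("duplicate edges for an unordered pair")
            if any(a == b for a, b in zip(e["trait_a"], e["trait_b"])):
                raise ValueError("self-edges are not allowed")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, w in self.edges.itertuples(index=False):
            g.add_edge(a, b, weight=float(w))
        return g

    def write(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class Partition:
    """Trait -> cluster assignment with the modularity of that split."""

    membership: dict[str, int]
    q: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, c in self.membership.items():
            out.setdefault(c, []).append(lab)
        return out

    def write(self, path) -> None:
        pd.DataFrame(
            {"trait": list(self.membership), "cluster": list(self.membership.values())}
        ).to_csv(path, sep="\t", index=False)


def build_cluster_graph(m: GenCorrMatrix) -> EdgeList:
    """Complete |r_G|-weighted graph on the traits; missing/zero pairs omitted."""
    t = m.n_traits
    if t < 2:
        raise ValueError("need at least 2 traits to build a graph")
    rows = []
    for j in range(t):
        for i in range(j + 1, t):
            w = m.S[i, j]
            if np.isfinite(w) and abs(w) > 0:
                rows.append((m.labels[j], m.labels[i], abs(float(w))))
    edges = pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight"])
    return EdgeList(nodes=list(m.labels), edges=edges)


def modularity(edges: EdgeList, membership: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    q = sum_c [ W_in,c / W - (s_c / 2W)^2 ] with W the total edge weight,
    W_in,c the within-cluster weight and s_c the summed vertex strengths.
    """
    unknown = set(membership) - set(edges.nodes)
    if unknown:
        raise ValueError(f"membership names unknown vertices: {sorted(unknown)}")
    missing = set(edges.nodes) - set(membership)
    if missing:
        raise ValueError(f"membership missing vertices: {sorted(missing)}")
    e = edges.edges
    if not len(e):
        return 0.0
    W = float(e["weight"].sum())
    win: dict[int, float] = {}
    strength: dict[str, float] = {v: 0.0 for v in edges.nodes}
    for a, b, w in e.itertuples(index=False):
        w = float(w)
        strength[a] += w
        strength[b] += w
        if membership[a] == membership[b]:
            win[membership[a]] = win.get(membership[a], 0.0) + w
    q = 0.0
    clusters = set(membership.values())
    for c in clusters:
        s_c = sum(strength[v] for v in edges.nodes if membership[v] == c)
        q += win.get(c, 0.0) / W - (s_c / (2.0 * W)) ** 2
    return q


def louvain(edges: EdgeList, seed: int = 1) -> Partition:
    """Louvain community detection on a weighted edge list.

    Uses the seeded multi-level modularity heuristic (local moves over a
    random node order, graph aggregation, repeated to a fixpoint).
    Deterministic given the seed. Cluster ids are densified by each
    community's first vertex in input order.
    """
    if not len(edges.edges):
        raise ValueError("graph has no edges")
    g = edges.to_graph()
    comms = nx.community.louvain_communities(g, weight="weight", seed=int(seed))
    order = {v: k for k, v in enumerate(edges.nodes)}
    comms = sorted(comms, key=lambda c: min(order[v] for v in c))
    membership = {v: cid for cid, comm in enumerate(comms) for v in comm}
    return Partition(membership=membership, q=modularity(edges, membership))


class LouvainClusterer(BaseEstimator):
    """Community detection on the |r_G| graph of a :class:`GenCorrMatrix`.

    Attributes after ``fit``: ``labels_`` (cluster id per trait, input
    order), ``membership_``, ``modularity_``, ``partition_``.
    """

    def __init__(self, seed: int = 1):
        self.seed = seed

    def fit(self, m: GenCorrMatrix) -> "LouvainClusterer":
        part = louvain(build_cluster_graph(m), seed=self.seed)
        self.partition_ = part
        self.membership_ = part.membership
        self.modularity_ = part.q
        self.labels_ = np.array([part.membership[lab] for lab in m.labels])
        return self

    def fit_predict(self, m: GenCorrMatrix) -> np.ndarray:
        return self.fit(m).labels_


def hclust_order(m: GenCorrMatrix, method: str = "average") -> list[str]:
    """Dendrogram leaf order from agglomeration on distance d = 1 - r_G.

    Missing pairs get the maximum observed distance (logged). Exact ties are
    broken deterministically toward input order by an infinitesimal
    lexicographic perturbation of the pair distances.
    """
    S = m.S.copy()
    d = 1.0 - S
    np.fill_diagonal(d, 0.0)
    miss = ~np.isfinite(d)
    if miss.any():
        dmax = np.nanmax(d)
        logger.info("hclust_order: %d missing distances set to max %.3f",
                    int(miss.sum() // 2), dmax)
        d[miss] = dmax
    d = (d + d.T) / 2
    cond = squareform(d, checks=False)
    if len(cond):
        tie_eps = 1e-9 * max(float(np.max(cond)), 1.0) / len(cond)
        cond = cond + tie_eps * np.arange(len(cond))
    Z = linkage(cond, method=method)
    return [m.labels[k] for k in _leaf_order(Z, len(m.labels))]


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order, orienting each node so the subtree holding the
    smallest original index comes first (deterministic tie convention)."""
    children = {n + k: (int(a), int(b)) for k, (a, b) in enumerate(Z[:, :2])}
    min_leaf: dict[int, int] = {}

    def mn(node: int) -> int:
        if node < n:
            return node
        if node not in min_leaf:
            a, b = children[node]
            min_leaf[node] = min(mn(a), mn(b))
        return min_leaf[node]

    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if mn(a) <= mn(b) else (b, a)
        stack.extend([second, first])  # LIFO: ``first`` visited first
    return order


def display_graph(
    m: GenCorrMatrix, k: int = 10, min_abs: float = 0.10
) -> tuple[EdgeList, pd.Series]:
    """Figure-style display graph: per-vertex top-k edges above a floor.

    An edge (i, j) is kept iff |S[i,j]| > min_abs and it ranks among the k
    largest-|weight| edges of i OR of j. Returns the edge list plus the
    eigenvector centrality of each trait, computed as the leading eigenvector
    of |S| with zeroed diagonal, scaled to a maximum of 1.
    """
    t = m.n_traits
    A = np.abs(np.where(np.isfinite(m.S), m.S, 0.0)).astype(float)
    np.fill_diagonal(A, 0.0)
    keep_rank = np.zeros((t, t), dtype=bool)
    for i in range(t):
        order = np.argsort(-A[i], kind="stable")
        keep_rank[i, order[:k]] = True
    rows = []
    for j in range(t):
        for i in range(j + 1, t):
            if A[i, j] > min_abs and (keep_rank[i, j] or keep_rank[j, i]):
                rows.append((m.labels[j], m.labels[i], A[i, j]))
    edges = EdgeList(
        nodes=list(m.labels),
        edges=pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight"]),
    )
    evals, evecs = np.linalg.eigh(A)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.abs(v)
    vmax = v.max()
    cent = v / vmax if vmax > 0 else np.ones(t)
    return edges, pd.Series(cent, index=m.labels, name="eigen_centrality")
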