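"""Cluster-stability assessment by Monte-Carlo resampling of the genetic
correlation matrix.

The half-vectorized matrix vech(S) is treated as a multivariate-normal
estimate with covariance V (the jackknife sampling covariance). Each
resample draws a new vech vector, reshapes it into a symmetric matrix with
unit diagonal, rebuilds the |r_G| graph, and re-runs Louvain clustering.
The concordance matrix records, for every trait pair, the fraction of
resamples in which the two traits land in the same cluster.

Jackknife covariance matrices of K ~ 1000 entries estimated from a couple
hundred blocks are rank deficient by construction, so V is projected to the
positive-semidefinite cone by clipping negative eigenvalues at zero before
sampling. Resampled correlations are NOT clipped to [-1, 1] and matrices
are NOT re-sign-aligned (the graph uses absolute weights, so alignment
cannot change the clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .corrmat import GenCorrMatrix, vech, vech_dim, vech_indices
from .graphs import EdgeList, Partition, louvain

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceMatrix:
    """Pairwise co-clustering frequency across resampled partitions."""

    labels: list[str]
    C: np.ndarray
    n_resamples: int

    def __post_init__(self):
        t = len(self.labels)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (t, t):
            raise ValueError("C must be T x T")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.labels, columns=self.labels)

    def co_cluster_with(self, focal: str) -> pd.Series:
        """Co-clustering frequency of every other trait with ``focal``."""
        if focal not in self.labels:
            raise ValueError(f"unknown trait {focal!r}")
        s = self.frame().loc[focal].drop(focal)
        return s.sort_values(ascending=False)

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t", float_format="%.17g")


def resample_matrices(
    m: GenCorrMatrix, n: int = 1000, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` correlation matrices from MVN(vech(S), V); shape (n, T, T).

    V is PSD-projected by eigenvalue clipping when needed (logged). Each
    draw is reshaped through the fixed vech convention, symmetrized exactly,
    and has its diagonal reset to 1. Entries are not clipped to [-1, 1].
    """
    t = m.n_traits
    K = vech_dim(t)
    if m.V.shape != (K, K):
        raise ValueError(f"V has shape {m.V.shape}; expected ({K}, {K})")
    mu = vech(np.where(np.isfinite(m.S), m.S, 0.0))
    V = (m.V + m.V.T) / 2
    evals, evecs = np.linalg.eigh(V)
    if evals.min() < -1e-12 * max(evals.max(), 1.0):
        logger.info(
            "projecting V to PSD: clipping %d negative eigenvalues (min %.3e)",
            int((evals < 0).sum()), evals.min(),
        )
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))

    rng = np.random.default_rng(seed)
    draws = mu[None, :] + rng.standard_normal((n, K)) @ root.T
    idx_i = np.array([i for i, _ in vech_indices(t)])
    idx_j = np.array([j for _, j in vech_indices(t)])
    out = np.zeros((n, t, t))
    out[:, idx_i, idx_j] = draws
    out[:, idx_j, idx_i] = draws
    out[:, np.arange(t), np.arange(t)] = 1.0
    return out


def concordance(partitions: list[Partition]) -> ConcordanceMatrix:
    """Fraction of partitions in which each trait pair shares a cluster.

    Cluster ids are compared within each partition only, so the result is
    invariant to relabeling of clusters.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    labels = sorted(partitions[0].membership)
    for p in partitions:
        if sorted(p.membership) != labels:
            raise ValueError("partitions cover different label sets")
    t = len(labels)
    counts = np.zeros((t, t))
    for p in partitions:
        mem = np.array([p.membership[lab] for lab in labels])
        counts += (mem[:, None] == mem[None, :]).astype(float)
    C = counts / len(partitions)
    return ConcordanceMatrix(labels=labels, C=C, n_resamples=len(partitions))


def _abs_graph(labels: list[str], S: np.ndarray) -> EdgeList:
    t = len(labels)
    rows = [
        (labels[j], labels[i], abs(float(S[i, j])))
        for j in range(t)
        for i in range(j + 1, t)
        if np.isfinite(S[i, j]) and abs(S[i, j]) > 0
    ]
    return EdgeList(
        nodes=list(labels),
        edges=pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight"]),
    )


def stability_run(
    m: GenCorrMatrix,
    n: int = 1000,
    seed: int = 0,
    focal: str | None = None,
) -> ConcordanceMatrix:
    """Resample, re-cluster, and count pairwise cluster concordance.

    Resample ``r`` is clustered with Louvain seed ``(seed + 1 + r) mod 2^31``
    so that runs are reproducible yet streams are distinct per resample.
    When ``focal`` is given, the focal trait's co-clustering frequencies are
    logged (retrieve them with :meth:`ConcordanceMatrix.co_cluster_with`).
    """
    mats = resample_matrices(m, n=n, seed=seed)
    partitions = []
    for r in range(n):
        edges = _abs_graph(m.labels, mats[r])
        partitions.append(louvain(edges, seed=(seed + 1 + r) % 2**31))
    cm = concordance(partitions)
    if focal is not None:
        top = cm.co_cluster_with(focal)
        logger.info("co-clustering with %s: %s", focal,
                    ", ".join(f"{k}={v:.2f}" for k, v in top.items()))
    return cm


class ClusterStability(BaseEstimator):
    """Estimator wrapper around :func:`stability_run`.

    Attributes after ``fit``: ``concordance_`` (:class:`ConcordanceMatrix`),
    ``C_`` and, when a focal trait is set, ``focal_frequencies_``.
    """

    def __init__(self, n_resamples: int = 1000, seed: int = 0,
                 focal: str | None = None):
        self.n_resamples = n_resamples
        self.seed = seed
        self.focal = focal

    def fit(self, m: GenCorrMatrix) -> "ClusterStability":
        cm = stability_run(m, n=self.n_resamples, seed=self.seed,
                           focal=self.focal)
        self.concordance_ = cm
        self.C_ = cm.C
        if self.focal is not None:
            self.focal_frequencies_ = cm.co_cluster_with(self.focal)
        return self
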