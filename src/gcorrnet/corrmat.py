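"""Genetic correlation matrix assembly, sign alignment, and FDR control.

The T x T matrix S of pairwise genetic correlations is carried together with
the sampling covariance V of its unique elements, indexed by the half
vectorization vech(S): lower triangle, column major, diagonal included, so
K = T(T+1)/2 (990 entries for 44 traits). Diagonal vech entries are the
fixed value 1 and carry zero sampling variance.

Reverse-coded traits (e.g. satisfaction items among symptom scales) are
detected from the loadings on the first unrotated principal component of S:
any trait loading below -0.05 has its whole row and column of correlations
negated before clustering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ldsc import BivariateFit, pairwise_sampling_covariance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# vech indexing (lower triangle, column major, diagonal included)
# ---------------------------------------------------------------------------

def vech_dim(t: int) -> int:
    """Number of unique elements of a symmetric T x T matrix (diag included)."""
    return t * (t + 1) // 2


def vech_index(i: int, j: int, t: int) -> int:
    """Flat vech position of entry (i, j), 0-based, requires j <= i < T."""
    if not 0 <= j <= i < t:
        raise ValueError(f"need 0 <= j <= i < T, got ({i}, {j}, {t})")
    return j * t - j * (j - 1) // 2 + (i - j)

def vech_indices(t: int) -> list[tuple[int, int]]:
    """(row, col) pairs in vech order."""
    return [(i, j) for j in range(t) for i in range(j, t)]


def vech(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S)
    t = S.shape[0]
    return np.array([S[i, j] for i, j in vech_indices(t)])


def unvech(v: np.ndarray, t: int) -> np.ndarray:
    v = np.asarray(v)
    if len(v) != vech_dim(t):
        raise ValueError(f"vector length {len(v)} != T(T+1)/2 = {vech_dim(t)}")
    S = np.empty((t, t), dtype=v.dtype)
    for k, (i, j) in enumerate(vech_indices(t)):
        S[i, j] = v[k]
        S[j, i] = v[k]
    return S


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class GenCorrMatrix:
    """Genetic correlation matrix with sampling covariance and inference.

    Attributes
    ----------
    labels : trait names (length T)
    S : (T, T) correlation matrix, unit diagonal; NaN marks a missing pair
    V : (K, K) sampling covariance of vech(S), K = T(T+1)/2
    pvals, qvals : (T, T) symmetric matrices, NaN on the diagonal
    flipped : per-trait reverse-coding flags set by :func:`align_signs`
    """

    labels: list[str]
    S: np.ndarray
    V: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray | None = None
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        t = len(self.labels)
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.S.shape != (t, t):
            raise ValueError("S must be T x T")
        if self.V.shape != (vech_dim(t), vech_dim(t)):
            raise ValueError("V must be K x K with K = T(T+1)/2")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.S - self.S.T)) > 1e-10:
                raise ValueError("S must be symmetric")
        if self.flipped is None:
            self.flipped = np.zeros(t, dtype=bool)

    @property
    def n_traits(self) -> int:
        return len(self.labels)

    def frame(self, which: str = "S") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.labels, columns=self.labels)

    def write(self, out_dir) -> dict:
        """Write S/V/p/q as labeled TSV matrices and flip flags as JSON."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("S", "pvals", "qvals"):
            mat = getattr(self, name)
            if mat is None:
                continue
            p = out / f"{name}.tsv"
            pd.DataFrame(mat, index=self.labels, columns=self.labels).to_csv(
                p, sep="\t", float_format="%.17g"
            )
            paths[name] = str(p)
        pv = out / "V.tsv"
        pd.DataFrame(self.V).to_csv(pv, sep="\t", header=False, index=False,
                                    float_format="%.17g")
        paths["V"] = str(pv)
        pf = out / "flipped.json"
        with open(pf, "w") as fh:
            json.dump({lab: bool(f) for lab, f in zip(self.labels, self.flipped)},
                      fh, indent=2)
        paths["flipped"] = str(pf)
        return paths

    @classmethod
    def read(cls, in_dir) -> "GenCorrMatrix":
        from pathlib import Path

        d = Path(in_dir)
        s = pd.read_csv(d / "S.tsv", sep="\t", index_col=0)
        labels = list(s.index)
        pvals = pd.read_csv(d / "pvals.tsv", sep="\t", index_col=0).to_numpy()
        qpath = d / "qvals.tsv"
        qvals = (
            pd.read_csv(qpath, sep="\t", index_col=0).to_numpy()
            if qpath.exists()
            else None
        )
        V = pd.read_csv(d / "V.tsv", sep="\t", header=None).to_numpy()
        with open(d / "flipped.json") as fh:
            flips = json.load(fh)
        return cls(
            labels=labels,
            S=s.to_numpy(),
            V=V,
            pvals=pvals,
            qvals=qvals,
            flipped=np.array([flips[lab] for lab in labels], dtype=bool),
        )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(
    labels: list[str],
    fits: dict[tuple[int, int], BivariateFit],
    V_raw: np.ndarray | None = None,
    apply_fdr: bool = True,
) -> GenCorrMatrix:
    """Build a :class:`GenCorrMatrix` from all pairwise bivariate fits.

    ``fits`` maps (i, j) with j < i to a :class:`BivariateFit`. The sampling
    covariance of the off-diagonal vech entries is either supplied via
    ``V_raw`` (K_off x K_off, ordered as the off-diagonal entries appear in
    vech order) or computed from the fits' r_G pseudovalues, which must share
    one block partition. Diagonal vech entries get zero variance rows and
    columns. Undefined r_G values are stored as NaN (missing) with a warning.
    P-values are FDR adjusted across all trait combinations in one family.
    """
    t = len(labels)
    S = np.eye(t)
    pvals = np.full((t, t), np.nan)
    missing_pairs = []
    for j in range(t):
        for i in range(j + 1, t):
            key = (i, j) if (i, j) in fits else (j, i)
            if key not in fits:
                missing_pairs.append((labels[i], labels[j]))
                continue
            f = fits[key]
            if f.rg_defined and np.isfinite(f.rg):
                S[i, j] = S[j, i] = f.rg
                pvals[i, j] = pvals[j, i] = f.p_rg
            else:
                S[i, j] = S[j, i] = np.nan
                warnings.warn(
                    f"undefined r_G for pair ({labels[i]}, {labels[j]}); "
                    "stored as missing",
                    stacklevel=2,
                )
    if missing_pairs:
        raise ValueError(f"missing bivariate fits for pairs: {missing_pairs}")

    off_positions = [
        (k, i, j) for k, (i, j) in enumerate(vech_indices(t)) if i != j
    ]
    if V_raw is None:
        pv_cols, bounds = [], []
        for _, i, j in off_positions:
            f = fits[(i, j) if (i, j) in fits else (j, i)]
            pv_cols.append(f.rg_pseudovalues)
            bounds.append(f.boundaries)
        V_off = pairwise_sampling_covariance(np.column_stack(pv_cols), bounds)
    else:
        V_off = np.asarray(V_raw, dtype=float)
        k_off = len(off_positions)
        if V_off.shape != (k_off, k_off):
            raise ValueError(
                f"V_raw must be {k_off} x {k_off} (off-diagonal vech entries)"
            )

    K = vech_dim(t)
    V = np.zeros((K, K))
    idx = np.array([k for k, _, _ in off_positions])
    V[np.ix_(idx, idx)] = V_off

    m = GenCorrMatrix(labels=list(labels), S=S, V=V, pvals=pvals)
    if apply_fdr:
        m.qvals = fdr_matrix(pvals)
    return m


def fdr_matrix(pvals: np.ndarray) -> np.ndarray:
    """BH-adjust the upper-triangle p-values of a symmetric matrix in one family."""
    t = pvals.shape[0]
    iu = np.triu_indices(t, k=1)
    p = pvals[iu]
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        # normal-tail p-values underflow to 0 for |z| beyond ~39
        q[ok] = bh_fdr(np.maximum(p[ok], np.nextafter(0.0, 1.0)))
    qmat = np.full((t, t), np.nan)
    qmat[iu] = q
    qmat.T[iu] = q
    return qmat


# ---------------------------------------------------------------------------
# Sign alignment (reverse-coding detection)
# ---------------------------------------------------------------------------

def align_signs(m: GenCorrMatrix, loading_threshold: float = -0.05) -> GenCorrMatrix:
    """Negate correlations of traits loading below the threshold on PC1.

    The leading eigenvector of S (missing entries zero-filled for the
    decomposition only) is oriented so its component sum is non-negative;
    every trait with a loading below ``loading_threshold`` has its row and
    column of S negated (diagonal untouched) and its flip flag set. Single
    pass, no iteration. V is transformed consistently (each vech entry's
    sign change is the product of its two traits' flips, so
    V -> D V D with D diagonal +-1).
    """
    t = m.n_traits
    S_fill = np.where(np.isfinite(m.S), m.S, 0.0)
    S_fill = (S_fill + S_fill.T) / 2
    np.fill_diagonal(S_fill, 1.0)
    evals, evecs = np.linalg.eigh(S_fill)
    if t > 1 and abs(evals[-1] - evals[-2]) < 1e-12 * max(abs(evals[-1]), 1.0):
        logger.warning("degenerate leading eigenvalue; using an arbitrary "
                       "leading eigenvector")
    lead = evecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    flip = lead < loading_threshold
    sign = np.where(flip, -1.0, 1.0)
    S_new = m.S * np.outer(sign, sign)
    np.fill_diagonal(S_new, np.diag(m.S))
    d = np.array([sign[i] * sign[j] for i, j in vech_indices(t)])
    V_new = m.V * np.outer(d, d)
    return replace(
        m,
        S=S_new,
        V=V_new,
        flipped=np.asarray(m.flipped, dtype=bool) ^ flip,
        pvals=m.pvals.copy(),
        qvals=None if m.qvals is None else m.qvals.copy(),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, returned in input order.

    q_(i) = min_{k >= i} p_(k) * m / k over the ascending order statistics,
    capped at 1. Input values must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    if not np.all(np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
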