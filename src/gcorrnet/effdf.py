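"""Effective number of independent tests from the spectrum of a correlation
matrix, and the Bonferroni-style corrected significance threshold.

Highly correlated test batteries (e.g. the same gene's association tested
against expression in many tissues) need fewer than M independent-test
corrections. The effective degrees of freedom follow Nyholt's spectral
formula

.. math::  M_{eff} = 1 + (M - 1)\\,(1 - \\mathrm{var}(\\lambda)/M),

where lambda are the eigenvalues of the M x M correlation matrix and the
variance uses the (M - 1) denominator. var(lambda) = 0 (independence) gives
M_eff = M; a rank-one all-ones matrix gives M_eff = 1. The Li-Ji integer
partitioning variant is available for comparison. The corrected threshold
is alpha / M_eff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass
class EffDfResult:
    """Spectral effective-df estimate with the corrected alpha."""

    m: int
    eigenvalues: np.ndarray
    var_lambda: float
    meff: float
    alpha_in: float
    alpha_corrected: float
    method: str = "nyholt"

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "var_lambda": self.var_lambda,
            "meff": self.meff,
            "alpha_in": self.alpha_in,
            "alpha_corrected": self.alpha_corrected,
            "method": self.method,
        }


def read_zmatrix(path) -> pd.DataFrame:
    """Read a z-score matrix TSV (gene rows, tissue columns, blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.apply(pd.to_numeric, errors="coerce")


def pairwise_complete_corr(zmat: pd.DataFrame) -> np.ndarray:
    """Pearson correlation over pairwise-complete rows for each column pair.

    May be indefinite (logged); raises if any column pair shares fewer than
    3 complete rows, naming the pair.
    """
    df = pd.DataFrame(zmat)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    notna = df.notna().to_numpy().astype(np.int64)
    counts = notna.T @ notna
    cols = list(df.columns)
    mcol = df.shape[1]
    for a in range(mcol):
        for b in range(a + 1, mcol):
            if counts[a, b] < 3:
                raise ValueError(
                    f"columns ({cols[a]}, {cols[b]}) share only "
                    f"{int(counts[a, b])} complete rows (need >= 3)"
                )
    corr = df.corr(method="pearson", min_periods=3).to_numpy()
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh((corr + corr.T) / 2).min() < -1e-10:
        logger.info("pairwise-complete correlation matrix is indefinite")
    return corr


def effective_df(
    corr: np.ndarray, alpha: float = 0.05, method: str = "nyholt"
) -> EffDfResult:
    """Effective number of independent tests of a correlation matrix.

    ``method='nyholt'`` applies the spectral formula above (non-integer
    result, matching reported fractional dfs); ``method='liji'`` applies the
    Li-Ji partitioning f(|lambda|) = 1_{|lambda| >= 1} + frac(|lambda|).
    """
    corr = np.asarray(corr, dtype=float)
    M = corr.shape[0]
    if corr.shape != (M, M):
        raise ValueError("correlation matrix must be square")
    if np.abs(corr - corr.T).max() > 1e-8:
        raise ValueError("correlation matrix must be symmetric (tol 1e-8)")
    evals = np.linalg.eigvalsh((corr + corr.T) / 2)
    if method == "nyholt":
        var_l = float(np.var(evals, ddof=1)) if M > 1 else 0.0
        meff = 1.0 + (M - 1) * (1.0 - var_l / M)
    elif method == "liji":
        a = np.abs(evals)
        fl = np.floor(a + 1e-8)  # tolerate eigenvalues a hair below integers
        meff = float(np.sum((a >= 1 - 1e-8).astype(float)
                            + np.clip(a - fl, 0.0, 1.0)))
        var_l = float(np.var(evals, ddof=1)) if M > 1 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    meff = float(np.clip(meff, 1.0, M))
    return EffDfResult(
        m=M,
        eigenvalues=evals,
        var_lambda=var_l,
        meff=meff,
        alpha_in=alpha,
        alpha_corrected=corrected_alpha(alpha, meff),
        method=method,
    )


def corrected_alpha(alpha: float, meff: float) -> float:
    """Bonferroni-style threshold alpha / meff."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return alpha / meff


class EffectiveTests(BaseEstimator):
    """Spectral effective-df estimator over a z-score matrix or correlation.

    ``fit`` accepts either a gene x tissue z-score DataFrame (pairwise
    complete correlations are computed first) or a ready correlation matrix.
    Attributes after ``fit``: ``corr_``, ``eigenvalues_``, ``meff_``,
    ``alpha_corrected_``, ``result_``.
    """

    def __init__(self, alpha: float = 0.05, method: str = "nyholt"):
        self.alpha = alpha
        self.method = method

    def fit(self, X) -> "EffectiveTests":
        if isinstance(X, pd.DataFrame) and not (
            X.shape[0] == X.shape[1] and np.allclose(np.diag(X.to_numpy()), 1.0)
        ):
            corr = pairwise_complete_corr(X)
        else:
            corr = np.asarray(X, dtype=float)
        res = effective_df(corr, alpha=self.alpha, method=self.method)
        self.corr_ = corr
        self.eigenvalues_ = res.eigenvalues
        self.meff_ = res.meff
        self.alpha_corrected_ = res.alpha_corrected
        self.result_ = res
        return self
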