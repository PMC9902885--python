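"""Univariate and bivariate LD-score regression with block-jackknife errors.

The univariate model regresses the per-SNP association statistic
:math:`\\chi^2_j = z_j^2` on the LD score :math:`\\ell_j`:

.. math::  E[\\chi^2_j] = 1 + a + N h^2 \\ell_j / M,

so the heritability estimate is ``slope * M / N``. The bivariate model
regresses the z-score product of a harmonized trait pair on
:math:`\\ell_j`; its slope scales to the genetic covariance and, normalized
by the two heritabilities, the genetic correlation r_G.

Weighting is two-pass: pass 1 uses 1/max(ell, 1) (over-counting correction),
pass 2 additionally divides by the squared expected statistic from the
pass-1 fit (heteroskedasticity correction). Standard errors come from a
delete-one-block jackknife over contiguous SNP blocks in genomic order;
because weighted least squares with fixed weights is linear in per-block
sufficient statistics, all leave-one-out fits are computed from block sums
at negligible cost, and pseudovalues for every fitted quantity share one
block partition — which is what makes the cross-pair sampling covariance
of a whole correlation matrix well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator


class SingularDesignError(ValueError):
    """Regressor has zero variance; the 2x2 normal equations are singular."""


# ---------------------------------------------------------------------------
# Weighted least squares on (l2, y) via per-block sufficient statistics
# ---------------------------------------------------------------------------

def ldsc_regression(y, l2, weights) -> tuple[float, float]:
    """Weighted least squares of ``y`` on ``l2`` with an intercept.

    Exact solution of the 2x2 normal equations; returns (slope, intercept).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(l2, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(y) == len(x) == len(w)) or len(y) < 3:
        raise ValueError("y, l2, weights must have equal length >= 3")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return _solve(np.array([w.sum(), (w * x).sum(), (w * x * x).sum(),
                            (w * y).sum(), (w * x * y).sum()]))


def _solve(s: np.ndarray) -> tuple[float, float]:
    """Slope/intercept from sufficient statistics (Sw, Swx, Swxx, Swy, Swxy)."""
    sw, sx, sxx, sy, sxy = s[..., 0], s[..., 1], s[..., 2], s[..., 3], s[..., 4]
    det = sw * sxx - sx * sx
    if np.any(np.asarray(det) <= 0) or np.any(~np.isfinite(np.asarray(det))):
        raise SingularDesignError("zero variance in LD scores")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def block_boundaries(n: int, n_blocks: int) -> np.ndarray:
    """Offsets of ``n_blocks`` contiguous, near-equal blocks over ``n`` rows."""
    if not 2 <= n_blocks < n:
        raise ValueError(f"need 2 <= n_blocks < n rows (got {n_blocks}, {n})")
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def _block_sums(x, y, w, bounds) -> np.ndarray:
    """Per-block sufficient statistics, shape (n_blocks, 5)."""
    cols = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    csum = np.vstack([np.zeros(5), np.cumsum(cols, axis=0)])
    return csum[bounds[1:]] - csum[bounds[:-1]]


def _full_and_loo(x, y, w, bounds):
    """Full-sample and leave-one-block-out (slope, intercept) arrays."""
    bs = _block_sums(x, y, w, bounds)
    total = bs.sum(axis=0)
    slope, intercept = _solve(total)
    slope_loo, intercept_loo = _solve(total[None, :] - bs)
    return float(slope), float(intercept), slope_loo, intercept_loo


def _pseudovalues(full: float, loo: np.ndarray) -> np.ndarray:
    b = len(loo)
    return b * full - (b - 1) * loo


def _jackknife_se(pv: np.ndarray) -> float:
    return float(np.sqrt(np.var(pv, ddof=1) / len(pv)))


# ---------------------------------------------------------------------------
# Generic delete-one-block jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    """Delete-one-block jackknife of an arbitrary statistic.

    ``estimate`` is the mean of the pseudovalues (bias corrected);
    ``se = sqrt(var(pseudovalues, ddof=1) / n_blocks)``.
    """

    estimate: float
    se: float
    pseudovalues: np.ndarray
    boundaries: np.ndarray


def delete_block_jackknife(statistic, rows, n_blocks: int) -> JackknifeResult:
    """Jackknife ``statistic`` (callable on a row subset) over contiguous blocks."""
    rows = np.asarray(rows)
    n = rows.shape[0]
    bounds = block_boundaries(n, n_blocks)
    theta_full = float(statistic(rows))
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.concatenate([rows[: bounds[b]], rows[bounds[b + 1]:]])
        try:
            loo[b] = float(statistic(keep))
        except Exception as exc:  # noqa: BLE001 - re-raise with block index
            raise RuntimeError(f"statistic failed on leave-out block {b}") from exc
    pv = _pseudovalues(theta_full, loo)
    return JackknifeResult(
        estimate=float(pv.mean()),
        se=_jackknife_se(pv),
        pseudovalues=pv,
        boundaries=bounds,
    )


def pairwise_sampling_covariance(pseudovalues, boundaries=None) -> np.ndarray:
    """Sampling covariance of K jackknifed statistics.

    ``pseudovalues`` is (n_blocks, K), every column jackknifed on the SAME
    block partition (pass ``boundaries``, a sequence of boundary arrays, to
    have this verified). Returns V = cov(pseudovalues) / n_blocks with the
    (n_blocks - 1) denominator; diag(V) equals each statistic's se^2.
    """
    pv = np.atleast_2d(np.asarray(pseudovalues, dtype=float))
    if pv.shape[0] < 2:
        raise ValueError("need at least 2 blocks")
    if boundaries is not None:
        ref = np.asarray(boundaries[0])
        for b in boundaries[1:]:
            if not np.array_equal(ref, np.asarray(b)):
                raise ValueError("mismatched block partitions across statistics")
    n_blocks = pv.shape[0]
    centered = pv - pv.mean(axis=0, keepdims=True)
    return (centered.T @ centered) / (n_blocks - 1) / n_blocks


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    """Univariate LDSC fit: SNP heritability and confounding intercept."""

    h2: float
    h2_se: float
    z_h2: float
    p_h2: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_snps: int
    n_blocks: int
    m_ref: int
    n_bar: float
    h2_pseudovalues: np.ndarray = field(repr=False)
    intercept_pseudovalues: np.ndarray = field(repr=False)
    boundaries: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            k: (float(v) if np.isscalar(v) or isinstance(v, (int, float)) else v)
            for k, v in {
                "h2": self.h2, "h2_se": self.h2_se, "z_h2": self.z_h2,
                "p_h2": self.p_h2, "intercept": self.intercept,
                "intercept_se": self.intercept_se, "mean_chi2": self.mean_chi2,
                "n_snps": self.n_snps, "n_blocks": self.n_blocks,
                "m_ref": self.m_ref, "n_bar": self.n_bar,
            }.items()
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class BivariateFit:
    """Bivariate LDSC fit: genetic covariance, cross-trait intercept, r_G."""

    gcov: float
    gcov_se: float
    cross_intercept: float
    cross_intercept_se: float
    rg: float
    rg_se: float
    p_rg: float
    rg_defined: bool
    rg_out_of_bounds: bool
    n_snps: int
    n_blocks: int
    rg_pseudovalues: np.ndarray = field(repr=False)
    boundaries: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "gcov": self.gcov, "gcov_se": self.gcov_se,
            "cross_intercept": self.cross_intercept,
            "cross_intercept_se": self.cross_intercept_se,
            "rg": self.rg, "rg_se": self.rg_se, "p_rg": self.p_rg,
            "rg_defined": self.rg_defined,
            "rg_out_of_bounds": self.rg_out_of_bounds,
            "n_snps": self.n_snps, "n_blocks": self.n_blocks,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _merge(stats: pd.DataFrame, ldscores: pd.DataFrame) -> pd.DataFrame:
    m = stats.merge(ldscores[["SNP", "L2"]], on="SNP")
    return m.sort_values(["CHR", "BP"], kind="mergesort", ignore_index=True)


class UnivariateLDSC(BaseEstimator):
    """SNP-heritability estimator by LD-score regression.

    Parameters
    ----------
    n_blocks : int, default 200
        Jackknife blocks (contiguous, genomic order).
    m_override : int or None
        Reference number of SNPs M; defaults to the regression SNP count.

    Attributes (after ``fit``)
    --------------------------
    h2_, h2_se_, z_h2_, p_h2_ : heritability estimate and inference
    intercept_, intercept_se_ : confounding intercept (1 under the null)
    mean_chi2_ : mean association chi-square
    result_ : :class:`UnivariateFit`
    """

    def __init__(self, n_blocks: int = 200, m_override: int | None = None):
        self.n_blocks = n_blocks
        self.m_override = m_override

    def fit(self, stats: pd.DataFrame, ldscores: pd.DataFrame) -> "UnivariateLDSC":
        m = _merge(stats, ldscores)
        n_snps = len(m)
        if n_snps <= self.n_blocks:
            raise ValueError(
                f"n_snps ({n_snps}) must exceed n_blocks ({self.n_blocks})"
            )
        l2 = m["L2"].to_numpy(dtype=float)
        chi2 = m["Z"].to_numpy(dtype=float) ** 2
        n_bar = float(pd.to_numeric(m["N"]).mean())
        M = int(self.m_override) if self.m_override else n_snps

        base = np.maximum(l2, 1.0)
        slope1, _ = ldsc_regression(chi2, l2, 1.0 / base)
        h2_w = float(np.clip(slope1 * M / n_bar, 0.0, 1.0))
        w2 = 1.0 / (base * (1.0 + n_bar * h2_w * l2 / M) ** 2)

        bounds = block_boundaries(n_snps, self.n_blocks)
        slope, intercept, slope_loo, int_loo = _full_and_loo(l2, chi2, w2, bounds)

        scale = M / n_bar
        h2_pv = _pseudovalues(slope, slope_loo) * scale
        int_pv = _pseudovalues(intercept, int_loo)
        h2 = slope * scale
        h2_se = _jackknife_se(h2_pv)
        z = h2 / h2_se if h2_se > 0 else np.inf * np.sign(h2)
        self.result_ = UnivariateFit(
            h2=h2,
            h2_se=h2_se,
            z_h2=float(z),
            p_h2=float(2 * sps.norm.sf(abs(z))),
            intercept=intercept,
            intercept_se=_jackknife_se(int_pv),
            mean_chi2=float(chi2.mean()),
            n_snps=n_snps,
            n_blocks=self.n_blocks,
            m_ref=M,
            n_bar=n_bar,
            h2_pseudovalues=h2_pv,
            intercept_pseudovalues=int_pv,
            boundaries=bounds,
        )
        for name in ("h2", "h2_se", "z_h2", "p_h2", "intercept",
                     "intercept_se", "mean_chi2", "n_snps"):
            setattr(self, name + "_", getattr(self.result_, name))
        return self


class BivariateLDSC(BaseEstimator):
    """Genetic covariance / correlation estimator for a harmonized trait pair.

    ``fit`` takes the two aligned summary-statistic tables, the LD scores,
    and the two univariate fits (which supply the pass-2 weighting). The
    univariate slope regressions are recomputed on the shared harmonized
    rows so that r_G is a ratio of quantities estimated on one SNP panel:
    this makes rg(trait, itself) exactly 1 and the jackknife of the full
    ratio internally consistent. r_G outside [-1, 1] is reported as-is with
    an out-of-bounds flag, never clamped.
    """

    def __init__(self, n_blocks: int = 200, m_override: int | None = None):
        self.n_blocks = n_blocks
        self.m_override = m_override

    def fit(
        self,
        stats1: pd.DataFrame,
        stats2: pd.DataFrame,
        ldscores: pd.DataFrame,
        fit1: UnivariateFit,
        fit2: UnivariateFit,
    ) -> "BivariateLDSC":
        if not stats1["SNP"].equals(stats2["SNP"]):
            raise ValueError("stats1/stats2 are not row-aligned; harmonize first")
        m1 = _merge(stats1, ldscores)
        m2 = _merge(stats2, ldscores)
        n_snps = len(m1)
        if n_snps <= self.n_blocks:
            raise ValueError(
                f"n_snps ({n_snps}) must exceed n_blocks ({self.n_blocks})"
            )
        l2 = m1["L2"].to_numpy(dtype=float)
        z1 = m1["Z"].to_numpy(dtype=float)
        z2 = m2["Z"].to_numpy(dtype=float)
        n1 = float(pd.to_numeric(m1["N"]).mean())
        n2 = float(pd.to_numeric(m2["N"]).mean())
        M = int(self.m_override) if self.m_override else n_snps

        base = np.maximum(l2, 1.0)
        h1w = float(np.clip(fit1.h2, 0.0, 1.0))
        h2w = float(np.clip(fit2.h2, 0.0, 1.0))
        c1 = 1.0 + n1 * h1w * l2 / M
        c2 = 1.0 + n2 * h2w * l2 / M
        w_biv = 1.0 / (base * c1 * c2)
        w_u1 = 1.0 / (base * c1 * c1)
        w_u2 = 1.0 / (base * c2 * c2)

        bounds = block_boundaries(n_snps, self.n_blocks)
        sb, ib, sb_loo, ib_loo = _full_and_loo(l2, z1 * z2, w_biv, bounds)
        s1, _, s1_loo, _ = _full_and_loo(l2, z1 * z1, w_u1, bounds)
        s2, _, s2_loo, _ = _full_and_loo(l2, z2 * z2, w_u2, bounds)

        gcov = sb * M / np.sqrt(n1 * n2)
        gcov_pv = _pseudovalues(sb, sb_loo) * M / np.sqrt(n1 * n2)
        int_pv = _pseudovalues(ib, ib_loo)

        defined = s1 > 0 and s2 > 0
        if defined:
            # M and N cancel: gcov / sqrt(h2_1 h2_2) = slope_biv / sqrt(s1 s2)
            rg = float(sb / np.sqrt(s1 * s2))
            with np.errstate(invalid="ignore"):
                rg_loo = sb_loo / np.sqrt(np.where(s1_loo * s2_loo > 0,
                                                   s1_loo * s2_loo, np.nan))
            rg_pv = _pseudovalues(rg, rg_loo)
            if np.isnan(rg_pv).any():
                defined = bool(np.isfinite(rg))
                rg_se = float("nan")
            else:
                rg_se = _jackknife_se(rg_pv)
        else:
            rg, rg_se = float("nan"), float("nan")
            rg_pv = np.full(self.n_blocks, np.nan)
        zr = rg / rg_se if defined and rg_se and rg_se > 0 else np.nan
        self.result_ = BivariateFit(
            gcov=float(gcov),
            gcov_se=_jackknife_se(gcov_pv),
            cross_intercept=float(ib),
            cross_intercept_se=_jackknife_se(int_pv),
            rg=rg,
            rg_se=rg_se,
            p_rg=float(2 * sps.norm.sf(abs(zr))) if np.isfinite(zr) else float("nan"),
            rg_defined=bool(defined),
            rg_out_of_bounds=bool(defined and abs(rg) > 1.0),
            n_snps=n_snps,
            n_blocks=self.n_blocks,
            rg_pseudovalues=rg_pv,
            boundaries=bounds,
        )
        for name in ("gcov", "gcov_se", "cross_intercept", "rg", "rg_se",
                     "p_rg", "rg_defined", "n_snps"):
            setattr(self, name + "_", getattr(self.result_, name))
        return self


# thin functional wrappers ---------------------------------------------------

def fit_univariate(
    stats: pd.DataFrame,
    ldscores: pd.DataFrame,
    m_override: int | None = None,
    n_blocks: int = 200,
) -> UnivariateFit:
    """Univariate LDSC fit; see :class:`UnivariateLDSC`."""
    return UnivariateLDSC(n_blocks=n_blocks, m_override=m_override).fit(
        stats, ldscores
    ).result_


def fit_bivariate(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    ldscores: pd.DataFrame,
    fit1: UnivariateFit,
    fit2: UnivariateFit,
    n_blocks: int = 200,
    m_override: int | None = None,
) -> BivariateFit:
    """Bivariate LDSC fit; see :class:`BivariateLDSC`."""
    return BivariateLDSC(n_blocks=n_blocks, m_override=m_override).fit(
        stats1, stats2, ldscores, fit1, fit2
    ).result_
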