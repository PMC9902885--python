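"""Reading, QC filtering, and allele harmonization of GWAS summary statistics.

Filters follow the conventional LDSC-style munging: MAF > 0.01,
HWE p > 1e-8 (each applied only where the field is available), restriction
to an include-list of well-imputed SNPs (a HapMap3 stand-in), and exclusion
of high-LD regions (by default one window standing in for the MHC on
chromosome 6).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import LDSCORE_COLUMNS, SUMSTATS_COLUMNS

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class FormatError(ValueError):
    """Malformed summary-statistic or LD-score file."""


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval ``chr:start-end``."""

    chrom: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start > end: {self}")

    @classmethod
    def parse(cls, text: str) -> "Region":
        m = re.fullmatch(r"(\d+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r}; expected chr:start-end")
        return cls(int(m.group(1)), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


#: Default exclusion window standing in for the MHC.
MHC_STAND_IN = Region(6, 26_000_000, 34_000_000)


@dataclass
class SNPFilterConfig:
    """QC thresholds and panel restrictions applied by :func:`filter_sumstats`."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-8
    include_list: set[str] | None = None
    exclude_regions: list[Region] = field(default_factory=lambda: [MHC_STAND_IN])
    drop_ambiguous: bool = False

    def __post_init__(self):
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 <= self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must be in [0, 1)")
        self.exclude_regions = [
            Region.parse(r) if isinstance(r, str) else r for r in self.exclude_regions
        ]


@dataclass
class FilterReport:
    """Per-rule removal counts; each removed SNP is attributed to the first
    failing rule in the fixed order maf -> hwe -> region -> include_list
    (-> ambiguous, when enabled)."""

    n_input: int
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_region: int = 0
    removed_include: int = 0
    removed_ambiguous: int = 0
    retained: int = 0

    def check(self) -> None:
        removed = (
            self.removed_maf
            + self.removed_hwe
            + self.removed_region
            + self.removed_include
            + self.removed_ambiguous
        )
        assert removed + self.retained == self.n_input


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistic TSV; rows with missing/non-finite Z dropped."""
    df = _read_table(path, SUMSTATS_COLUMNS)
    z = pd.to_numeric(df["Z"], errors="coerce")
    ok = np.isfinite(z)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("%s: dropped %d rows with missing/non-finite Z", path, n_drop)
    df = df.loc[ok].reset_index(drop=True)
    df["Z"] = z[ok].to_numpy()
    if df["SNP"].duplicated().any():
        raise FormatError(f"{path}: duplicate SNP ids")
    if (pd.to_numeric(df["N"]) <= 0).any():
        raise FormatError(f"{path}: non-positive N")
    return df


def read_ldscores(path) -> pd.DataFrame:
    df = _read_table(path, LDSCORE_COLUMNS)
    if not np.isfinite(df["L2"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite L2 values")
    if df["SNP"].duplicated().any():
        raise FormatError(f"{path}: duplicate SNP ids")
    return df


def read_include_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def filter_sumstats(
    stats: pd.DataFrame, cfg: SNPFilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply QC filters; returns the retained table and a :class:`FilterReport`.

    A row passes when MAF > maf_min AND HWE p > hwe_p_min (rows missing the
    field pass that rule), lies outside every exclusion region, and — if an
    include-list is set — appears on it. Emits a warning (not an error) if
    nothing survives.
    """
    cfg = cfg or SNPFilterConfig()
    n = len(stats)
    maf = pd.to_numeric(stats["MAF"], errors="coerce").to_numpy(dtype=float)
    hwe = pd.to_numeric(stats["HWE_P"], errors="coerce").to_numpy(dtype=float)
    fail_maf = np.isfinite(maf) & (maf <= cfg.maf_min)
    fail_hwe = np.isfinite(hwe) & (hwe <= cfg.hwe_p_min)

    chrom = stats["CHR"].to_numpy()
    bp = stats["BP"].to_numpy()
    fail_region = np.zeros(n, dtype=bool)
    for r in cfg.exclude_regions:
        fail_region |= (chrom == r.chrom) & (bp >= r.start) & (bp <= r.end)

    if cfg.include_list:
        fail_include = ~stats["SNP"].isin(cfg.include_list).to_numpy()
    else:
        fail_include = np.zeros(n, dtype=bool)

    if cfg.drop_ambiguous:
        pairs = [frozenset((a, b)) for a, b in zip(stats["A1"], stats["A2"])]
        fail_amb = np.array([p in _AMBIGUOUS for p in pairs])
    else:
        fail_amb = np.zeros(n, dtype=bool)

    # first-failing-rule attribution
    report = FilterReport(n_input=n)
    report.removed_maf = int(fail_maf.sum())
    rest = ~fail_maf
    report.removed_hwe = int((rest & fail_hwe).sum())
    rest &= ~fail_hwe
    report.removed_region = int((rest & fail_region).sum())
    rest &= ~fail_region
    report.removed_include = int((rest & fail_include).sum())
    rest &= ~fail_include
    report.removed_ambiguous = int((rest & fail_amb).sum())
    rest &= ~fail_amb
    report.retained = int(rest.sum())
    report.check()
    if report.retained == 0:
        warnings.warn("all SNPs removed by filtering", stacklevel=2)
    return stats.loc[rest].reset_index(drop=True), report


def harmonize_pair(
    stats1: pd.DataFrame, stats2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two QC'd tables on SNP id and align stats2's alleles to stats1.

    Where stats2 carries the same alleles swapped, its z-score is negated;
    SNPs whose allele sets disagree entirely are dropped (count logged).
    Returns two row-aligned tables in stats1's genomic order.
    """
    m = stats1.merge(stats2, on="SNP", suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError("no SNPs in common between the two tables")
    same = (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
    swapped = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
    keep = same | swapped
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("harmonize_pair: dropped %d SNPs with mismatched alleles", n_drop)
    m = m.loc[keep].reset_index(drop=True)
    if m.empty:
        raise ValueError("no SNPs left after allele harmonization")
    m = m.sort_values(["CHR_1", "BP_1"], kind="mergesort", ignore_index=True)
    # swapped-but-not-identical alleles get a z sign flip in table 2
    flip = (
        (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"]) & ~(
            (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
        )
    ).to_numpy()

    def build(side: str, flip_z: np.ndarray | None) -> pd.DataFrame:
        z = m[f"Z_{side}"].to_numpy(dtype=float)
        if flip_z is not None:
            z = np.where(flip_z, -z, z)
        return pd.DataFrame(
            {
                "SNP": m["SNP"],
                "CHR": m["CHR_1"],
                "BP": m["BP_1"],
                "A1": m["A1_1"],
                "A2": m["A2_1"],
                "Z": z,
                "N": m[f"N_{side}"],
                "MAF": m[f"MAF_{side}"],
                "HWE_P": m[f"HWE_P_{side}"],
            }
        )

    return build("1", None), build("2", flip)
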