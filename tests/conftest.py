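import numpy as np
import pandas as pd
import pytest

from gcorrnet import (
    GenCorrMatrix,
    SimulationConfig,
    simulate_ld_scores,
    simulate_multitrait_sumstats,
    vech_dim,
)
from gcorrnet.corrmat import vech_indices


@pytest.fixture(scope="session")
def small_pair():
    """Two correlated traits (rG = 0.5, h2 = 0.4) on a 4,000-SNP panel."""
    cfg = SimulationConfig(n_traits=2, n_snps=4000, sample_sizes=[20_000] * 2,
                           h2=[0.4, 0.4], seed=11)
    ld = simulate_ld_scores(cfg)
    tabs = simulate_multitrait_sumstats(cfg, ld)
    return cfg, ld, tabs


@pytest.fixture()
def planted_two_block():
    """8-trait correlation matrix with two planted blocks and diagonal V."""
    T = 8
    S = np.full((T, T), 0.05)
    S[:4, :4] = 0.5
    S[4:, 4:] = 0.5
    np.fill_diagonal(S, 1.0)
    K = vech_dim(T)
    V = np.zeros((K, K))
    for k, (i, j) in enumerate(vech_indices(T)):
        if i != j:
            V[k, k] = 0.02**2
    labels = [f"x{i}" for i in range(T)]
    return GenCorrMatrix(labels=labels, S=S, V=V,
                         pvals=np.full((T, T), np.nan))


def toy_sumstats(snp, chrom, bp, a1, a2, z, n=1000, maf=0.3, hwe=0.5):
    """Hand-built summary-statistic table for filter/harmonization tests."""
    k = len(snp)

    def rep(x):
        return list(x) if isinstance(x, (list, tuple, np.ndarray)) else [x] * k

    return pd.DataFrame(
        {"SNP": snp, "CHR": rep(chrom), "BP": rep(bp), "A1": rep(a1),
         "A2": rep(a2), "Z": rep(z), "N": rep(n), "MAF": rep(maf),
         "HWE_P": rep(hwe)}
    )
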