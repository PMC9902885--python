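"""LD-score regression: exact WLS, jackknife oracles, parameter recovery."""

import numpy as np
import pytest

from gcorrnet import (
    SimulationConfig,
    delete_block_jackknife,
    fit_bivariate,
    fit_univariate,
    harmonize_pair,
    ldsc_regression,
    pairwise_sampling_covariance,
    simulate_ld_scores,
    simulate_multitrait_sumstats,
)
from gcorrnet.ldsc import SingularDesignError, block_boundaries

from conftest import toy_sumstats


def make_panel(l2, z, n=1000):
    m = len(l2)
    ld = toy_sumstats([f"rs{i}" for i in range(m)], 1,
                      list(range(100, 100 + m)), "A", "G", 0.0)[
        ["SNP", "CHR", "BP"]
    ].assign(L2=l2)
    stats = toy_sumstats([f"rs{i}" for i in range(m)], 1,
                         list(range(100, 100 + m)), "A", "G", list(z), n=n)
    return stats, ld


class TestWLS:
    def test_noiseless_linear_recovered_exactly(self):
        rng = np.random.default_rng(0)
        l2 = rng.gamma(2, 20, 200) + 1
        y = 1.0 + 0.5 * l2
        for w in (np.ones(200), 1.0 / l2, rng.uniform(0.1, 5, 200)):
            slope, intercept = ldsc_regression(y, l2, w)
            assert slope == pytest.approx(0.5, abs=1e-12)
            assert intercept == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self):
        slope, intercept = ldsc_regression([3.0] * 5, [1, 2, 3, 4, 5],
                                           [1.0] * 5)
        assert slope == pytest.approx(0.0, abs=1e-14)
        assert intercept == pytest.approx(3.0)

    def test_three_points_match_hand_ols(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 2.5, 5.0])
        # closed-form 2x2 solve: slope = cov(x,y)/var(x)
        slope_hand = ((x - x.mean()) * (y - y.mean())).sum() / (
            (x - x.mean()) ** 2
        ).sum()
        intercept_hand = y.mean() - slope_hand * x.mean()
        slope, intercept = ldsc_regression(y, x, np.ones(3))
        assert slope == pytest.approx(slope_hand, abs=1e-14)
        assert intercept == pytest.approx(intercept_hand, abs=1e-14)

    def test_zero_variance_design_raises(self):
        with pytest.raises(SingularDesignError):
            ldsc_regression([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], [1.0] * 3)


class TestJackknife:
    def test_constant_values_zero_se(self):
        res = delete_block_jackknife(np.mean, np.full(40, 7.0), 8)
        assert res.estimate == pytest.approx(7.0)
        assert res.se == pytest.approx(0.0, abs=1e-14)

    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)  # 60 divisible by 6 blocks
        res = delete_block_jackknife(np.mean, x, 6)
        block_means = x.reshape(6, 10).mean(axis=1)
        assert res.estimate == pytest.approx(x.mean())
        assert res.se == pytest.approx(block_means.std(ddof=1) / np.sqrt(6))
        assert np.allclose(res.pseudovalues, block_means)

    def test_two_block_enumeration(self):
        x = np.array([0.0] * 4 + [1.0] * 4)
        res = delete_block_jackknife(np.mean, x, 2)
        # theta_full = 0.5; leave-out means are 1 and 0, pv = 2*0.5 - 1*loo
        assert np.allclose(res.pseudovalues, [0.0, 1.0])
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.5)

    def test_failing_statistic_reports_block(self):
        def bad(rows):
            if len(rows) < 10:
                raise ValueError("boom")
            return rows.mean()

        with pytest.raises(RuntimeError, match="block 0"):
            delete_block_jackknife(bad, np.arange(12.0), 4)

    def test_block_boundaries_cover_rows(self):
        b = block_boundaries(103, 10)
        assert b[0] == 0 and b[-1] == 103
        assert set(np.diff(b)) <= {10, 11}


class TestSamplingCovariance:
    def test_single_statistic_matches_jackknife_se(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        res = delete_block_jackknife(np.mean, x, 8)
        V = pairwise_sampling_covariance(res.pseudovalues[:, None])
        assert V[0, 0] == pytest.approx(res.se**2)

    def test_duplicated_columns_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        pv = rng.normal(size=(20, 1))
        V = pairwise_sampling_covariance(np.hstack([pv, pv]))
        rho = V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])
        assert rho == pytest.approx(1.0)

    def test_mismatched_partitions_rejected(self):
        pv = np.zeros((10, 2))
        with pytest.raises(ValueError, match="partition"):
            pairwise_sampling_covariance(
                pv, boundaries=[np.array([0, 5, 10]), np.array([0, 4, 10])]
            )

    def test_independent_traits_near_zero_covariance(self):
        cfg = SimulationConfig(n_traits=2, n_snps=6000, h2=[0.3, 0.3],
                               rg=np.eye(2), seed=21)
        ld = simulate_ld_scores(cfg)
        tabs = simulate_multitrait_sumstats(cfg, ld)
        f1 = fit_univariate(tabs[0], ld, n_blocks=100)
        f2 = fit_univariate(tabs[1], ld, n_blocks=100)
        V = pairwise_sampling_covariance(
            np.column_stack([f1.h2_pseudovalues, f2.h2_pseudovalues]),
            boundaries=[f1.boundaries, f2.boundaries],
        )
        rho = V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])
        assert abs(rho) < 0.35  # MC noise around 0 for 100 blocks


class TestUnivariate:
    def test_noiseless_chi2_gives_exact_h2_and_intercept(self):
        rng = np.random.default_rng(4)
        l2 = rng.gamma(2, 20, 500) + 1
        z = np.sqrt(1.0 + 0.5 * l2)  # chi2 = 1 + 0.5 * l2 exactly
        stats, ld = make_panel(l2, z, n=1000)
        fit = fit_univariate(stats, ld, m_override=200, n_blocks=50)
        assert fit.h2 == pytest.approx(0.5 * 200 / 1000, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.h2_se == pytest.approx(0.0, abs=1e-8)

    def test_recovers_simulated_h2(self, small_pair):
        cfg, ld, tabs = small_pair
        fit = fit_univariate(tabs[0], ld, n_blocks=100)
        assert abs(fit.h2 - 0.4) < 3 * fit.h2_se

    def test_null_intercept_near_one(self):
        cfg = SimulationConfig(n_traits=1, n_snps=8000, h2=[0.0],
                               rg=np.ones((1, 1)), seed=13)
        ld = simulate_ld_scores(cfg)
        (tab,) = simulate_multitrait_sumstats(cfg, ld)
        fit = fit_univariate(tab, ld, n_blocks=100)
        assert abs(fit.intercept - 1.0) < 3 * fit.intercept_se
        assert abs(fit.z_h2) < 4

    def test_too_few_snps_raises(self, small_pair):
        _, ld, tabs = small_pair
        with pytest.raises(ValueError, match="n_blocks"):
            fit_univariate(tabs[0].head(150), ld, n_blocks=200)

    def test_jackknife_se_calibrated_over_replicates(self):
        """Empirical SD of h2-hat within 30% of mean jackknife SE (null)."""
        h2s, ses = [], []
        for rep in range(50):
            cfg = SimulationConfig(n_traits=1, n_snps=2500, h2=[0.0],
                                   rg=np.ones((1, 1)), seed=1000 + rep)
            ld = simulate_ld_scores(cfg)
            (tab,) = simulate_multitrait_sumstats(cfg, ld)
            fit = fit_univariate(tab, ld, n_blocks=50)
            h2s.append(fit.h2)
            ses.append(fit.h2_se)
        ratio = np.std(h2s, ddof=1) / np.mean(ses)
        assert 0.7 < ratio < 1.3


class TestBivariate:
    def test_self_correlation_is_exactly_one(self, small_pair):
        _, ld, tabs = small_pair
        f = fit_univariate(tabs[0], ld, n_blocks=100)
        biv = fit_bivariate(tabs[0], tabs[0], ld, f, f, n_blocks=100)
        assert biv.rg == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_trait_order(self, small_pair):
        _, ld, tabs = small_pair
        f1 = fit_univariate(tabs[0], ld, n_blocks=100)
        f2 = fit_univariate(tabs[1], ld, n_blocks=100)
        a, b = harmonize_pair(tabs[0], tabs[1])
        rg_ab = fit_bivariate(a, b, ld, f1, f2, n_blocks=100).rg
        b2, a2 = harmonize_pair(tabs[1], tabs[0])
        rg_ba = fit_bivariate(b2, a2, ld, f2, f1, n_blocks=100).rg
        assert rg_ab == pytest.approx(rg_ba, abs=1e-12)

    def test_recovers_simulated_rg(self, small_pair):
        _, ld, tabs = small_pair
        f1 = fit_univariate(tabs[0], ld, n_blocks=100)
        f2 = fit_univariate(tabs[1], ld, n_blocks=100)
        a, b = harmonize_pair(tabs[0], tabs[1])
        biv = fit_bivariate(a, b, ld, f1, f2, n_blocks=100)
        assert abs(biv.rg - 0.5) < 3 * biv.rg_se

    def test_independent_traits_null_cross_intercept(self):
        cfg = SimulationConfig(n_traits=2, n_snps=6000, h2=[0.3, 0.3],
                               rg=np.eye(2), seed=17)
        ld = simulate_ld_scores(cfg)
        tabs = simulate_multitrait_sumstats(cfg, ld)
        f1 = fit_univariate(tabs[0], ld, n_blocks=100)
        f2 = fit_univariate(tabs[1], ld, n_blocks=100)
        biv = fit_bivariate(tabs[0], tabs[1], ld, f1, f2, n_blocks=100)
        assert abs(biv.cross_intercept) < 3 * biv.cross_intercept_se

    def test_zero_h2_flags_undefined_rg(self):
        cfg = SimulationConfig(n_traits=2, n_snps=3000, h2=[0.0, 0.0],
                               rg=np.eye(2), seed=19)
        ld = simulate_ld_scores(cfg)
        tabs = simulate_multitrait_sumstats(cfg, ld)
        f1 = fit_univariate(tabs[0], ld, n_blocks=50)
        f2 = fit_univariate(tabs[1], ld, n_blocks=50)
        biv = fit_bivariate(tabs[0], tabs[1], ld, f1, f2, n_blocks=50)
        # null slopes can land either side of zero; either a defined noisy
        # rg or an explicit undefined flag, never an exception
        assert isinstance(biv.rg_defined, bool)

    def test_cross_intercept_shifts_without_biasing_rg(self):
        """Sample overlap (c = 0.2) moves the cross intercept, not r_G."""
        results = {}
        for c in (0.0, 0.2):
            ints, rgs = [], []
            for rep in range(8):
                cross = np.array([[0.0, c], [c, 0.0]])
                cfg = SimulationConfig(n_traits=2, n_snps=8000,
                                       h2=[0.4, 0.4], seed=300 + rep,
                                       cross_intercept=cross)
                ld = simulate_ld_scores(cfg)
                tabs = simulate_multitrait_sumstats(cfg, ld)
                f1 = fit_univariate(tabs[0], ld, n_blocks=100)
                f2 = fit_univariate(tabs[1], ld, n_blocks=100)
                biv = fit_bivariate(tabs[0], tabs[1], ld, f1, f2, n_blocks=100)
                ints.append(biv.cross_intercept)
                rgs.append(biv.rg)
            results[c] = (np.mean(ints), np.mean(rgs))
        assert results[0.2][0] - results[0.0][0] > 0.1
        assert abs(results[0.2][1] - 0.5) < 0.05
        assert abs(results[0.0][1] - 0.5) < 0.05
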