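"""LD-score regression: slopes, intercepts, jackknife V, PD smoothing."""

import numpy as np
import pytest

from ldsem.exceptions import DataError
from ldsem.ldsc import (GeneticCovariance, LdscFitConfig, cross_trait_ldsc,
                        genetic_correlations, multivariate_ldsc, smooth_to_pd,
                        univariate_ldsc)
from ldsem.simulate import (CohortDesign, make_ld_panel, simulate_sumstats,
                            SummaryStats)
from ldsem.studies import jackknife_coverage_study

NO_CAP = dict(chisq_max=np.inf)


def one_trait(m=20_000, n=50_000, h2=0.25, seed=0, panel_seed=None):
    panel = make_ld_panel(m, seed=seed if panel_seed is None else panel_seed)
    design = CohortDesign(n_per_trait=(n,), labels=("t",))
    stats = simulate_sumstats(np.array([[h2]]), design, panel, seed=seed,
                              ambiguous_frac=0.0, allele_swap_frac=0.0)
    return stats[0], panel


def two_traits(m=20_000, rg=0.95, h2=0.25, seed=0):
    panel = make_ld_panel(m, seed=seed)
    S = np.array([[h2, rg * h2], [rg * h2, h2]])
    design = CohortDesign(n_per_trait=(50_000, 50_000), labels=("a", "b"))
    stats = simulate_sumstats(S, design, panel, seed=seed,
                              ambiguous_frac=0.0, allele_swap_frac=0.0)
    return stats, panel


class TestUnivariate:
    def test_null_calibration(self):
        stats, panel = one_trait(h2=0.0, seed=11)
        fit = univariate_ldsc(stats, panel, LdscFitConfig(**NO_CAP))
        assert abs(fit.estimate) < 3 * fit.se
        assert abs(fit.intercept - 1.0) < 0.05  # intercept SE ~ 0.01 here

    def test_h2_recovered_within_jackknife_se(self):
        stats, panel = one_trait(h2=0.25, seed=12)
        fit = univariate_ldsc(stats, panel, LdscFitConfig(**NO_CAP))
        assert abs(fit.estimate - 0.25) < 3 * fit.se

    def test_doubling_z_scales_slope_fourfold(self):
        stats, panel = one_trait(seed=13)
        cfg = LdscFitConfig(weight_iterations=1, **NO_CAP)
        base = univariate_ldsc(stats, panel, cfg)
        doubled = SummaryStats(stats.trait,
                               stats.table.assign(Z=2 * stats.table["Z"]))
        quad = univariate_ldsc(doubled, panel, cfg)
        assert quad.estimate == pytest.approx(4 * base.estimate, rel=1e-10)
        assert quad.intercept == pytest.approx(4 * base.intercept, rel=1e-10)

    def test_estimates_invariant_to_row_order(self):
        stats, panel = one_trait(seed=14)
        shuffled = SummaryStats(
            stats.trait,
            stats.table.sample(frac=1.0, random_state=0).reset_index(drop=True))
        a = univariate_ldsc(stats, panel, LdscFitConfig(**NO_CAP))
        b = univariate_ldsc(shuffled, panel, LdscFitConfig(**NO_CAP))
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)

    def test_weighted_regression_matches_statsmodels_oracle(self):
        # replicate the full two-pass weighting scheme with statsmodels WLS
        sm = pytest.importorskip("statsmodels.api")
        stats, panel = one_trait(m=5_000, seed=15)
        cfg = LdscFitConfig(n_blocks=50, **NO_CAP)
        fit = univariate_ldsc(stats, panel, cfg)

        tab = stats.table.merge(panel.to_frame()[["SNP", "L2"]], on="SNP")
        tab = tab.sort_values(["CHR", "BP", "SNP"], kind="mergesort")
        ell = tab["L2"].to_numpy()
        y = tab["Z"].to_numpy() ** 2
        nbar, M = 50_000.0, panel.m_total
        x = np.column_stack([ell * nbar / M, np.ones_like(ell)])
        h2 = 0.0
        for _ in range(cfg.weight_iterations):
            w = 1.0 / (np.maximum(ell, 1.0)
                       * (1.0 + nbar * max(h2, 0.0) * ell / M) ** 2)
            res = sm.WLS(y, x, weights=w).fit()
            h2 = res.params[0]
        assert fit.estimate == pytest.approx(h2, rel=1e-10)
        assert fit.intercept == pytest.approx(res.params[1], rel=1e-10)

    def test_fewer_snps_than_blocks_errors(self):
        stats, panel = one_trait(m=150, seed=16)
        with pytest.raises(DataError):
            univariate_ldsc(stats, panel, LdscFitConfig(n_blocks=200, **NO_CAP))


class TestCrossTrait:
    def test_same_trait_reproduces_univariate_fit(self):
        stats, panel = one_trait(seed=20)
        cfg = LdscFitConfig(**NO_CAP)
        uni = univariate_ldsc(stats, panel, cfg)
        cross = cross_trait_ldsc(stats, stats, panel, cfg)
        assert cross.estimate == uni.estimate
        assert cross.intercept == uni.intercept

    def test_rg_recovered_within_jackknife_se(self):
        stats, panel = two_traits(rg=0.95, seed=21)
        cfg = LdscFitConfig(**NO_CAP)
        cross = cross_trait_ldsc(stats[0], stats[1], panel, cfg)
        assert abs(cross.estimate - 0.95 * 0.25) < 3 * cross.se

    def test_independent_traits_covariance_near_zero(self):
        stats, panel = two_traits(rg=0.0, seed=22)
        cross = cross_trait_ldsc(stats[0], stats[1], panel,
                                 LdscFitConfig(**NO_CAP))
        assert abs(cross.estimate) < 3 * cross.se

    def test_misaligned_snp_sets_error(self):
        stats, panel = two_traits(seed=23)
        truncated = SummaryStats(stats[1].trait, stats[1].table.iloc[:-10])
        with pytest.raises(DataError):
            cross_trait_ldsc(stats[0], truncated, panel,
                             LdscFitConfig(**NO_CAP))


class TestAssemble:
    def test_diag_V_matches_pairwise_jackknife_ses(self):
        stats, panel = two_traits(seed=30)
        cfg = LdscFitConfig(**NO_CAP)
        gc = multivariate_ldsc(stats, panel, cfg)
        uni_a = univariate_ldsc(stats[0], panel, cfg)
        cross = cross_trait_ldsc(stats[0], stats[1], panel, cfg)
        # vech order: (1,1), (2,1), (2,2)
        assert gc.se[0] == pytest.approx(uni_a.se, rel=1e-9)
        assert gc.se[1] == pytest.approx(cross.se, rel=1e-9)

    def test_k1_V_is_univariate_jackknife_variance(self):
        stats, panel = one_trait(seed=31)
        cfg = LdscFitConfig(**NO_CAP)
        gc = multivariate_ldsc([stats], panel, cfg)
        uni = univariate_ldsc(stats, panel, cfg)
        assert gc.V.shape == (1, 1)
        assert gc.V[0, 0] == pytest.approx(uni.se**2, rel=1e-9)
        assert gc.S[0, 0] == pytest.approx(uni.estimate, rel=1e-12)

    def test_V_symmetric_psd(self, factor_gc):
        assert np.allclose(factor_gc.V, factor_gc.V.T)
        assert np.linalg.eigvalsh(factor_gc.V).min() > -1e-18

    def test_jackknife_coverage_near_nominal(self):
        # 95% intervals should cover the generating h2 in ~95% of replicates
        res = jackknife_coverage_study(n_reps=100, seed=5)
        n_cov = res.extra["n_covered"]
        # binomial 95% band around 0.95 with n = 100
        band = 1.96 * np.sqrt(0.95 * 0.05 / 100)
        assert 0.95 - band <= n_cov / 100 <= 1.0

    def test_json_roundtrip(self, factor_gc, tmp_path):
        factor_gc.to_json(tmp_path / "gc.json")
        back = GeneticCovariance.from_json(tmp_path / "gc.json")
        assert np.allclose(back.S, factor_gc.S)
        assert np.allclose(back.V, factor_gc.V)
        assert back.labels == factor_gc.labels


class TestSmoothToPd:
    def test_pd_input_unchanged(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.array_equal(smooth_to_pd(S), S)

    def test_identity_unchanged(self):
        assert np.array_equal(smooth_to_pd(np.eye(4)), np.eye(4))

    def test_overunity_correlation_clipped(self):
        S = np.array([[1.0, 1.02], [1.02, 1.0]])
        out = smooth_to_pd(S)
        corr = out[0, 1] / np.sqrt(out[0, 0] * out[1, 1])
        assert corr <= 1.0
        assert np.linalg.eigvalsh(out).min() > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(DataError):
            smooth_to_pd(np.array([[1.0, 0.2], [0.3, 1.0]]))


class TestGeneticCorrelations:
    def test_diagonal_S_gives_identity(self):
        R = genetic_correlations(np.diag([0.2, 0.3, 0.4]))
        assert np.array_equal(R, np.eye(3))

    def test_near_unity_correlation_rounds_to_one(self):
        S = np.array([[0.23, 0.2445], [0.2445, 0.26]])
        R = genetic_correlations(S)
        assert f"{R[0, 1]:.2f}" == "1.00"

    def test_rank_one_generative_recovers_unit_correlations(self):
        stats, panel = two_traits(rg=1.0, seed=33)
        gc = multivariate_ldsc(stats, panel, LdscFitConfig(**NO_CAP))
        R = genetic_correlations(gc)
        # delta-method SE of rg from the jackknife SEs of S entries
        s11, s12, s22 = gc.S[0, 0], gc.S[0, 1], gc.S[1, 1]
        se = R[0, 1] * np.sqrt((gc.se[1] / s12) ** 2
                               + (gc.se[0] / (2 * s11)) ** 2
                               + (gc.se[2] / (2 * s22)) ** 2)
        assert abs(R[0, 1] - 1.0) < 3 * se

    def test_nonpositive_diagonal_names_trait(self):
        gc = GeneticCovariance(S=np.array([[0.2, 0.0], [0.0, -0.1]]),
                               V=np.eye(3), intercepts=np.eye(2),
                               n_per_trait=(1, 1), labels=("x", "bad_trait"))
        with pytest.raises(DataError, match="bad_trait"):
            genetic_correlations(gc)
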