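"""Synthetic-data generator: LD panels, implied covariances, z-score moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldsem.exceptions import DataError
from ldsem.simulate import (CohortDesign, FactorModel, LDScorePanel,
                            SimplexModel, default_design,
                            default_factor_model, default_simplex_model,
                            implied_genetic_covariance, make_ld_panel,
                            read_ld_panel, simulate_sumstats, write_ld_panel,
                            write_sumstats)


class TestLdPanel:
    def test_gamma_mean_matches_1_plus_shape_scale(self):
        # E[l] = 1 + shape*scale = 21; check within 3 SE by CLT
        panel = make_ld_panel(100_000, shape=2.0, scale=10.0, seed=1)
        se = np.sqrt(2.0 * 10.0**2 / 100_000)
        assert abs(panel.ld_score.mean() - 21.0) < 3 * se

    def test_degenerate_shape_gives_unit_ld_scores(self):
        # gamma draws underflow to 0 as shape -> 0, leaving l = 1 exactly
        panel = make_ld_panel(1000, shape=1e-12, scale=10.0, seed=0)
        assert np.all(panel.ld_score == 1.0)

    def test_same_seed_identical_panels(self):
        a = make_ld_panel(500, seed=3)
        b = make_ld_panel(500, seed=3)
        assert np.array_equal(a.ld_score, b.ld_score)
        assert np.array_equal(a.snp_id, b.snp_id)

    @pytest.mark.parametrize("kwargs", [dict(m_snps=50), dict(shape=-1.0),
                                        dict(scale=0.0)])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_ld_panel(**{"m_snps": 1000, **kwargs})

    def test_panel_invariants_enforced(self):
        with pytest.raises(DataError):
            LDScorePanel(snp_id=np.array(["a"]), chrom=np.array(["1"]),
                         bp=np.array([1]), ld_score=np.array([0.5]), m_total=1)
        with pytest.raises(DataError):
            LDScorePanel(snp_id=np.array(["a", "b"]), chrom=np.array(["1", "1"]),
                         bp=np.array([1, 2]), ld_score=np.array([1.0, 1.0]),
                         m_total=1)


class TestImpliedCovariance:
    def test_factor_zero_loadings_is_diagonal(self):
        model = FactorModel(loadings=(0.0, 0.0, 0.0), factor_variance=0.5,
                            residuals=(0.1, 0.2, 0.3))
        assert np.allclose(implied_genetic_covariance(model),
                           np.diag([0.1, 0.2, 0.3]))

    def test_single_persistent_innovation_gives_unit_correlations(self):
        model = SimplexModel(betas=(1.0, 1.0), innovations=(0.24, 0.0, 0.0),
                             residuals=(0.0, 0.0, 0.0))
        S = implied_genetic_covariance(model)
        assert np.allclose(S, 0.24)

    def test_simplex_hand_recursion(self):
        model = SimplexModel(betas=(0.5, 0.5), innovations=(1.0, 1.0, 1.0),
                             residuals=(0.0, 0.0, 0.0))
        S = implied_genetic_covariance(model)
        expect = np.array([[1.0, 0.5, 0.25],
                           [0.5, 1.25, 0.625],
                           [0.25, 0.625, 1.3125]])
        assert np.allclose(S, expect)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            implied_genetic_covariance(FactorModel(
                loadings=(1.0, 1.0, 1.0), factor_variance=-0.1,
                residuals=(0.0, 0.0, 0.0)))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(betas=st.lists(st.floats(-1.5, 1.5), min_size=3, max_size=3),
           zetas=st.lists(st.floats(0.0, 2.0), min_size=4, max_size=4),
           thetas=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
    def test_simplex_implied_always_symmetric_psd(self, betas, zetas, thetas):
        S = implied_genetic_covariance(SimplexModel(
            betas=tuple(betas), innovations=tuple(zetas),
            residuals=tuple(thetas)))
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-9


class TestSimulateSumstats:
    def test_null_model_mean_chisq_near_one(self):
        # S_true = 0, C = I: each z is standard normal
        panel = make_ld_panel(20_000, seed=2)
        design = CohortDesign(n_per_trait=(50_000, 50_000), labels=("a", "b"))
        stats = simulate_sumstats(np.zeros((2, 2)), design, panel, seed=2,
                                  ambiguous_frac=0.0, allele_swap_frac=0.0)
        se = np.sqrt(2.0 / 20_000)  # var(z^2) = 2 under the null
        for st_ in stats:
            assert abs((st_.table["Z"] ** 2).mean() - 1.0) < 3 * se

    def test_mean_chisq_matches_closed_form(self):
        # constant l = 20, M = 1e5, N = 50k, h2 = 0.25: E[chi2] = 3.5
        m = 20_000
        panel = LDScorePanel(
            snp_id=np.array([f"rs{j}" for j in range(m)]),
            chrom=np.full(m, "1"), bp=1000 * np.arange(1, m + 1),
            ld_score=np.full(m, 20.0), m_total=100_000)
        design = CohortDesign(n_per_trait=(50_000,), labels=("t",))
        stats = simulate_sumstats(np.array([[0.25]]), design, panel, seed=5,
                                  ambiguous_frac=0.0, allele_swap_frac=0.0)
        chisq = stats[0].table["Z"].to_numpy() ** 2
        se = np.sqrt(2 * 3.5**2 / m)  # var(z^2) = 2 sigma^4
        assert abs(chisq.mean() - 3.5) < 3 * se

    def test_cross_trait_products_track_ld_scores(self):
        # rank-1 S_true with rg = 1: E[z1 z2 | l] has slope sqrt(N1 N2) s12 / M
        panel = make_ld_panel(20_000, seed=7)
        h = np.array([0.25, 0.25])
        S_true = np.outer(np.sqrt(h), np.sqrt(h))
        design = CohortDesign(n_per_trait=(40_000, 60_000), labels=("a", "b"))
        stats = simulate_sumstats(S_true, design, panel, seed=7,
                                  ambiguous_frac=0.0, allele_swap_frac=0.0)
        y = stats[0].table["Z"].to_numpy() * stats[1].table["Z"].to_numpy()
        x = panel.ld_score * np.sqrt(40_000 * 60_000) / panel.m_total
        X = np.column_stack([x, np.ones_like(x)])
        slope = np.linalg.lstsq(X, y, rcond=None)[0][0]
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        se = np.sqrt(np.sum(resid**2) / (len(y) - 2)
                     / np.sum((x - x.mean())**2))
        assert abs(slope - 0.25) < 3 * se

    def test_non_psd_intercepts_error_names_snp(self):
        panel = make_ld_panel(200, seed=0)
        design = CohortDesign(n_per_trait=(1000, 1000), labels=("a", "b"))
        bad_C = np.array([[1.0, 1.5], [1.5, 1.0]])  # indefinite
        with pytest.raises(DataError, match="rs"):
            simulate_sumstats(np.zeros((2, 2)), design, panel,
                              cross_intercepts=bad_C, seed=0)

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        design = default_design()
        from ldsem.simulate import implied_genetic_covariance as igc
        S_true = igc(default_factor_model())
        for rep in ("a", "b"):
            panel = make_ld_panel(500, seed=9)
            stats = simulate_sumstats(S_true, design, panel, seed=9)
            write_ld_panel(panel, tmp_path / f"panel_{rep}")
            write_sumstats(stats[0], tmp_path / f"s_{rep}.tsv")
        assert ((tmp_path / "panel_a.l2.ldscore").read_bytes()
                == (tmp_path / "panel_b.l2.ldscore").read_bytes())
        assert ((tmp_path / "s_a.tsv").read_bytes()
                == (tmp_path / "s_b.tsv").read_bytes())

    def test_panel_roundtrip(self, tmp_path):
        panel = make_ld_panel(300, seed=4)
        write_ld_panel(panel, tmp_path / "p")
        back = read_ld_panel(tmp_path / "p")
        assert back.m_total == panel.m_total
        assert np.allclose(back.ld_score, panel.ld_score, atol=1e-6)


class TestDefaults:
    def test_default_factor_model_matches_study_conditions(self):
        S = implied_genetic_covariance(default_factor_model())
        # heritabilities in the reported 0.22-0.29 band
        assert np.all(np.diag(S) >= 0.21) and np.all(np.diag(S) <= 0.30)
        R = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        off = R[np.triu_indices(6, 1)]
        assert off.min() > 0.88 and off.max() <= 1.0

    def test_default_simplex_correlations_decay_with_lag(self):
        S = implied_genetic_covariance(default_simplex_model())
        R = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        assert R[0, 1] > R[0, 2] > R[0, 3] > R[0, 4] > R[0, 5]

    def test_design_overlap_validation(self):
        with pytest.raises(ValueError):
            CohortDesign(n_per_trait=(10, 20), labels=("a", "b"),
                         overlap=np.array([[10, 15], [15, 20]]))
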