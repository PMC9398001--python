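"""Seeded simulation studies: parameter recovery, calibration, selection.

Each study re-runs the full generative chain (simulate summary statistics ->
optional munge -> multivariate LDSC -> DWLS fit) under the default study
conditions and summarizes the replicates. These functions back both the
test suite and the reproduction script; replicate counts and SNP counts are
arguments so callers choose their own compute scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fit import FitOptions, compare_models, fit_baseline, fit_dwls, fit_indices
from .ldsc import GeneticCovariance, LdscFitConfig, multivariate_ldsc, univariate_ldsc
from .models import build_factor_model, build_simplex_model
from .qc import QCThresholds, munge
from .simulate import (CohortDesign, default_design, default_factor_model,
                       default_simplex_model, implied_genetic_covariance,
                       make_ld_panel, simulate_sumstats)

__all__ = [
    "simulate_gc",
    "factor_recovery_study",
    "typeI_error_study",
    "jackknife_calibration_study",
    "jackknife_coverage_study",
    "simplex_recovery_study",
    "selection_consistency_study",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def simulate_gc(kind: str, m_snps: int, seed: int, *,
                design: CohortDesign | None = None,
                run_munge: bool = True,
                n_blocks: int = 200) -> GeneticCovariance:
    """One replicate of simulate -> (munge) -> multivariate LDSC.

    ``kind`` selects the generative structure ("factor" or "simplex") with
    the default study-condition parameters. With ``run_munge=False`` the
    simulator emits clean records (no ambiguous or swapped alleles) and the
    QC stage is skipped, for calibration studies where QC is irrelevant.
    """
    design = design or default_design()
    model = default_factor_model() if kind == "factor" else default_simplex_model()
    S_true = implied_genetic_covariance(model, design.k)
    rng = np.random.default_rng(seed)
    panel = make_ld_panel(m_snps, seed=int(rng.integers(2**31 - 1)))
    sim_seed = int(rng.integers(2**31 - 1))
    if run_munge:
        stats = simulate_sumstats(S_true, design, panel, seed=sim_seed)
        stats, _ = munge(stats, QCThresholds(
            mhc_interval=("1", 26_000_000, 34_000_000)))
    else:
        stats = simulate_sumstats(S_true, design, panel, seed=sim_seed,
                                  ambiguous_frac=0.0, allele_swap_frac=0.0)
    # simulated z-scores contain no artifacts, so the chi-square outlier cap
    # (a real-data robustness guard) is disabled: at desk-scale M the
    # expected per-SNP chi-square is large and a cap would truncate signal
    cfg = LdscFitConfig(n_blocks=n_blocks, chisq_max=np.inf)
    return multivariate_ldsc(stats, panel, cfg)


@dataclass
class StudyResult:
    """Per-replicate values plus their mean and Monte-Carlo SE."""

    values: np.ndarray
    extra: dict

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def mc_se(self) -> float:
        return float(np.std(self.values, ddof=1) / np.sqrt(len(self.values)))


def factor_recovery_study(n_reps: int = 20, m_snps: int = 100_000,
                          seed: int = 0, run_munge: bool = True) -> StudyResult:
    """Recover the common-factor SNP heritability through the full pipeline.

    Simulates the six age tranches under the single-factor generative model
    (factor variance 0.24, first loading fixed at 1), runs munge ->
    multivariate LDSC -> DWLS factor fit, and collects the fitted factor
    variance psi-hat per replicate. ``values`` are on the percent scale, so
    the generating value is 24.
    """
    model = build_factor_model(default_design().k)
    psis = np.empty(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        gc = simulate_gc("factor", m_snps, int(s), run_munge=run_munge)
        fit = fit_dwls(model, gc, FitOptions(seed=int(s)))
        psis[i] = 100.0 * fit.estimates["psi"]
    return StudyResult(values=psis, extra={"generating_pct": 24.0,
                                           "m_snps": m_snps})


def typeI_error_study(n_reps: int = 200, m_snps: int = 12_000, seed: int = 0,
                      n_blocks: int = 100, alpha: float = 0.05) -> StudyResult:
    """Calibration of the residual-based chi-square under the true model.

    Fits the k=6 factor model to (S, V) simulated under that factor model
    and counts replicates whose chi-square exceeds the (1 - alpha) quantile
    of chi-square(df). ``values`` holds the chi-square statistics; the
    exceedance count is in ``extra``.
    """
    model = build_factor_model(default_design().k)
    crit = sps.chi2.ppf(1 - alpha, model.df)
    chis = np.empty(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        gc = simulate_gc("factor", m_snps, int(s), run_munge=False,
                         n_blocks=n_blocks)
        fit = fit_dwls(model, gc, FitOptions(seed=int(s), n_starts=2))
        chis[i] = fit.chisq
    return StudyResult(values=chis, extra={
        "df": model.df, "critical": float(crit), "alpha": alpha,
        "n_exceed": int(np.sum(chis > crit)), "n_reps": n_reps})


def _univariate_replicates(n_reps: int, m_snps: int, n_samples: int,
                           h2: float, seed: int, n_blocks: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(h2 estimates, jackknife SEs) for a one-trait design."""
    design = CohortDesign(n_per_trait=(n_samples,), labels=("trait",))
    S_true = np.array([[h2]])
    ests = np.empty(n_reps)
    ses = np.empty(n_reps)
    cfg = LdscFitConfig(n_blocks=n_blocks, chisq_max=np.inf)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        rng = np.random.default_rng(int(s))
        panel = make_ld_panel(m_snps, seed=int(rng.integers(2**31 - 1)))
        stats = simulate_sumstats(S_true, design, panel,
                                  seed=int(rng.integers(2**31 - 1)),
                                  ambiguous_frac=0.0, allele_swap_frac=0.0)
        fit = univariate_ldsc(stats[0], panel, cfg)
        ests[i], ses[i] = fit.estimate, fit.se
    return ests, ses


def jackknife_calibration_study(n_reps: int = 200, m_snps: int = 20_000,
                                n_samples: int = 50_000, h2: float = 0.25,
                                seed: int = 0, n_blocks: int = 100
                                ) -> StudyResult:
    """Ratio of the empirical SD of h2-hat to the mean jackknife SE."""
    ests, ses = _univariate_replicates(n_reps, m_snps, n_samples, h2, seed,
                                       n_blocks)
    ratio = float(np.std(ests, ddof=1) / np.mean(ses))
    return StudyResult(values=ests, extra={"ratio": ratio,
                                           "mean_se": float(np.mean(ses))})


def jackknife_coverage_study(n_reps: int = 100, m_snps: int = 50_000,
                             n_samples: int = 50_000, h2: float = 0.25,
                             seed: int = 0, n_blocks: int = 200
                             ) -> StudyResult:
    """Coverage of nominal 95% jackknife intervals for h2."""
    ests, ses = _univariate_replicates(n_reps, m_snps, n_samples, h2, seed,
                                       n_blocks)
    crit = sps.norm.ppf(0.975)
    covered = np.abs(ests - h2) <= crit * ses
    return StudyResult(values=ests, extra={
        "coverage": float(np.mean(covered)), "n_covered": int(covered.sum()),
        "n_reps": n_reps})


def simplex_recovery_study(n_reps: int = 30, m_snps: int = 20_000,
                           seed: int = 0, n_blocks: int = 100) -> StudyResult:
    """Recover the transmission coefficient under the simplex generative model.

    Fits the full autoregression (free innovations, betas and residuals)
    and collects the mean fitted beta over the identified coefficients
    beta_3..beta_k per replicate; the generating value (0.95 at every
    interval) sits in ``extra``. beta_2 is excluded: in the quasi-simplex
    only the product zeta_1 * beta_2 enters the off-diagonal moments while
    zeta_1 trades freely against theta_1 in var(1), so beta_2 is not
    separately identified and wanders with the optimizer start.
    """
    gen = default_simplex_model()
    k = default_design().k
    model = build_simplex_model(k)
    betas = np.empty(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        gc = simulate_gc("simplex", m_snps, int(s), run_munge=False,
                         n_blocks=n_blocks)
        fit = fit_dwls(model, gc, FitOptions(seed=int(s), n_starts=3))
        betas[i] = np.mean([fit.estimates[f"beta_{t}"] for t in range(3, k + 1)])
    return StudyResult(values=betas,
                       extra={"generating_beta": float(np.mean(gen.betas))})


def selection_consistency_study(n_reps: int = 20, m_snps: int = 20_000,
                                seed: int = 0, n_blocks: int = 100
                                ) -> StudyResult:
    """How often pseudoAIC picks the factor model when it generated the data."""
    k = default_design().k
    factor = build_factor_model(k)
    simplex = build_simplex_model(k)
    wins = np.empty(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        gc = simulate_gc("factor", m_snps, int(s), run_munge=False,
                         n_blocks=n_blocks)
        opts = FitOptions(seed=int(s), n_starts=3)
        base = fit_baseline(gc, opts)
        fits = [fit_indices(fit_dwls(m, gc, opts), base)
                for m in (factor, simplex)]
        tab = compare_models(fits)
        wins[i] = 1.0 if tab.attrs["winner"] == "factor" else 0.0
    return StudyResult(values=wins, extra={"fraction_factor": float(wins.mean())})
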