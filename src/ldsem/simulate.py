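"""Synthetic LD-score panels and multi-trait GWAS summary statistics.

The generator draws per-SNP z-scores directly from the second-moment model
that LD-score regression estimates: for SNP j with LD score l_j and panel
size M, the z-scores of the k traits are multivariate normal with

    Cov(z_t, z_u | j) = C[t, u] + sqrt(N_t N_u) * S_true[t, u] * l_j / M,

where C holds the LDSC intercepts (identity for no confounding and no sample
overlap) and S_true is the generative genetic covariance matrix. SNPs are
drawn independently, so the LDSC estimand is exact by construction; realized
inter-SNP LD correlation is deliberately not simulated (see docs/methods.md
for what this does to jackknife standard errors).

The default study design emulates six non-overlapping age tranches of one
quantitative trait (BMI between ages 40 and 73): sample sizes 34,001-89,824,
SNP heritabilities 0.22-0.29, pairwise genetic correlations around 0.94-0.95,
generated under either a single-common-factor or a simplex (autoregressive)
genetic covariance structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "LDScorePanel",
    "CohortDesign",
    "FactorModel",
    "SimplexModel",
    "GenerativeModel",
    "SummaryStats",
    "SUMSTATS_COLUMNS",
    "TRANCHE_LABELS",
    "TRANCHE_N",
    "TRANCHE_H2",
    "make_ld_panel",
    "implied_genetic_covariance",
    "simulate_sumstats",
    "default_design",
    "default_factor_model",
    "default_simplex_model",
    "write_sumstats",
    "read_ld_panel",
    "write_ld_panel",
]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "INFO", "FRQ"]

#: Age-tranche labels, sample sizes and SNP heritabilities of the six
#: pseudo-longitudinal BMI GWAS the default design emulates.
TRANCHE_LABELS = ("bmi_40_44", "bmi_45_49", "bmi_50_54",
                  "bmi_55_59", "bmi_60_64", "bmi_65_73")
TRANCHE_N = (34001, 45294, 53602, 64891, 89824, 71178)
TRANCHE_H2 = (0.23, 0.26, 0.26, 0.29, 0.24, 0.22)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LDScorePanel:
    """Per-SNP LD scores plus the denominator SNP count M.

    ``ld_score`` must be >= 1 for every SNP (a SNP is in LD with itself);
    ``m_total`` is the M used as the LDSC denominator and must be at least
    the number of rows.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    ld_score: np.ndarray
    m_total: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.ld_score) < 1.0):
            raise DataError("LD scores must all be >= 1")
        if self.m_total < len(self.snp_id):
            raise DataError("m_total must be >= number of panel SNPs")

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"CHR": self.chrom, "SNP": self.snp_id,
                             "BP": self.bp, "L2": self.ld_score})


@dataclass(frozen=True)
class CohortDesign:
    """Sample sizes, tranche labels and (optional) sample overlap counts.

    ``overlap`` is a k x k symmetric matrix of shared-subject counts; the
    diagonal equals the per-trait sample sizes. The default (None) means
    non-overlapping cohorts, as in the independent age tranches.
    """

    n_per_trait: tuple[int, ...]
    labels: tuple[str, ...]
    overlap: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.n_per_trait):
            raise ValueError("labels and n_per_trait must have equal length")
        if any(n <= 0 for n in self.n_per_trait):
            raise ValueError("sample sizes must be positive")
        if self.overlap is not None:
            ov = np.asarray(self.overlap)
            n = np.asarray(self.n_per_trait)
            if ov.shape != (self.k, self.k) or not np.allclose(ov, ov.T):
                raise ValueError("overlap must be symmetric k x k")
            if not np.array_equal(np.diag(ov), n):
                raise ValueError("overlap diagonal must equal n_per_trait")
            if np.any(ov < 0) or np.any(ov > np.minimum.outer(n, n)):
                raise ValueError("overlap counts must lie in [0, min(N_t, N_u)]")

    @property
    def k(self) -> int:
        return len(self.n_per_trait)


@dataclass(frozen=True)
class FactorModel:
    """Single common genetic factor: S = lam lam' psi + diag(theta)."""

    loadings: tuple[float, ...]
    factor_variance: float
    residuals: tuple[float, ...]


@dataclass(frozen=True)
class SimplexModel:
    """First-order autoregression with innovations.

    Latent genetic levels follow eta_t = beta_t * eta_{t-1} + zeta_t with
    innovation variances ``innovations`` (zeta, length k) and transmission
    coefficients ``betas`` (length k-1, beta_t for t = 2..k); each observed
    genetic variance adds a residual ``residuals[t]`` on the diagonal.
    """

    betas: tuple[float, ...]
    innovations: tuple[float, ...]
    residuals: tuple[float, ...]


GenerativeModel = Union[FactorModel, SimplexModel]


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait.

    ``table`` has columns SNP CHR BP A1 A2 Z N INFO FRQ (INFO/FRQ optional).
    ``qc_notes`` accumulates per-file bookkeeping (malformed or duplicate
    rows) that the munge step folds into its QC report.
    """

    trait: str
    table: pd.DataFrame
    qc_notes: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        if self.table["SNP"].duplicated().any():
            raise DataError(f"duplicate SNP ids in trait {self.trait!r}")
        for col, lo, hi in (("INFO", 0.0, 1.0), ("FRQ", 0.0, 1.0)):
            if col in self.table and len(self.table):
                v = self.table[col].to_numpy(dtype=float)
                v = v[~np.isnan(v)]
                if v.size and (v.min() < lo or v.max() > hi):
                    raise DataError(f"{col} out of [{lo}, {hi}] in trait {self.trait!r}")


def make_ld_panel(m_snps: int, shape: float = 2.0, scale: float = 10.0,
                  seed: int = 0) -> LDScorePanel:
    """Draw a synthetic LD-score panel: l_j = 1 + Gamma(shape, scale).

    Positions sit on one synthetic chromosome "1" at 1 kb spacing (1-based);
    M equals the number of SNPs. Deterministic for a fixed seed.
    """
    if m_snps < 100:
        raise ValueError("m_snps must be >= 100")
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    rng = np.random.default_rng(seed)
    ld = 1.0 + rng.gamma(shape, scale, size=m_snps)
    snp = np.array([f"rs{j + 1:08d}" for j in range(m_snps)])
    bp = 1000 * np.arange(1, m_snps + 1, dtype=np.int64)
    chrom = np.full(m_snps, "1")
    return LDScorePanel(snp_id=snp, chrom=chrom, bp=bp, ld_score=ld,
                        m_total=m_snps)


def _check_nonneg(name: str, values: Sequence[float]) -> None:
    if any(v < 0 for v in values):
        raise ValueError(f"{name} must be non-negative")


def implied_genetic_covariance(model: GenerativeModel, k: int | None = None) -> np.ndarray:
    """Model-implied k x k genetic covariance matrix.

    Factor: S[t,u] = lam_t lam_u psi + delta_tu theta_t.
    Simplex: latent variances v_1 = zeta_1, v_t = beta_t^2 v_{t-1} + zeta_t;
    cov(t, t+s) = v_t * prod(beta_{t+1}..beta_{t+s}); residuals add to the
    diagonal. Always symmetric and positive semidefinite.
    """
    if isinstance(model, FactorModel):
        lam = np.asarray(model.loadings, dtype=float)
        theta = np.asarray(model.residuals, dtype=float)
        _check_nonneg("factor variance", [model.factor_variance])
        _check_nonneg("residual variances", theta)
        if k is None:
            k = lam.size
        if lam.size != k or theta.size != k:
            raise ValueError("loadings and residuals must have length k")
        return np.outer(lam, lam) * model.factor_variance + np.diag(theta)
    if isinstance(model, SimplexModel):
        zeta = np.asarray(model.innovations, dtype=float)
        theta = np.asarray(model.residuals, dtype=float)
        beta = np.asarray(model.betas, dtype=float)
        _check_nonneg("innovation variances", zeta)
        _check_nonneg("residual variances", theta)
        if k is None:
            k = zeta.size
        if zeta.size != k or theta.size != k or beta.size != k - 1:
            raise ValueError("parameter vectors not sized to k")
        v = np.zeros(k)
        v[0] = zeta[0]
        for t in range(1, k):
            v[t] = beta[t - 1] ** 2 * v[t - 1] + zeta[t]
        S = np.diag(v).astype(float)
        for t in range(k):
            prod = 1.0
            for u in range(t + 1, k):
                prod *= beta[u - 1]
                S[t, u] = S[u, t] = v[t] * prod
        return S + np.diag(theta)
    raise TypeError(f"unknown generative model type {type(model)!r}")


def default_design() -> CohortDesign:
    """The six independent age tranches with their published sample sizes."""
    return CohortDesign(n_per_trait=TRANCHE_N, labels=TRANCHE_LABELS)


def default_factor_model() -> FactorModel:
    """Single-factor generative model calibrated to the study conditions.

    The common factor carries a standardized variance (SNP heritability) of
    0.24 with the first loading fixed at 1, so the factor variance is
    directly on the heritability scale. Later tranches put 94% of their
    published h2 on the factor and 6% in age-specific residuals, giving
    pairwise genetic correlations of 0.94-0.95. The first tranche keeps a
    small residual (0.01), so its total h2 is 0.25.
    """
    psi = 0.24
    lam = [1.0] + [float(np.sqrt(0.94 * h2 / psi)) for h2 in TRANCHE_H2[1:]]
    theta = [0.01] + [0.06 * h2 for h2 in TRANCHE_H2[1:]]
    return FactorModel(loadings=tuple(lam), factor_variance=psi,
                       residuals=tuple(theta))


def default_simplex_model() -> SimplexModel:
    """Near-stable autoregressive generative model at the same h2 scale.

    Transmission 0.95 per 5-year interval, an initial innovation of 0.22
    (all genetic variance accumulated by the first tranche) topped up by
    small innovations of 0.02 thereafter, plus residuals of 0.01; implied
    correlations decay with lag as an autoregression requires.
    """
    return SimplexModel(betas=(0.95,) * 5,
                        innovations=(0.22,) + (0.02,) * 5,
                        residuals=(0.01,) * 6)


def _draw_alleles(rng: np.random.Generator, m: int, ambiguous_frac: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw A1/A2 pairs; a configurable fraction is strand-ambiguous (A/T, C/G)."""
    # base indices in ACGT order; the complement of index i is 3 - i
    idx = rng.integers(0, 4, size=m)
    ambiguous = rng.random(m) < ambiguous_frac
    pick = rng.integers(0, 2, size=m)
    # non-ambiguous partner: one of the two bases outside {a1, complement(a1)}
    in_at = (idx == 0) | (idx == 3)          # a1 is A or T -> partner in {C,G}
    other_idx = np.where(in_at, 1 + pick, 3 * pick)
    a2_idx = np.where(ambiguous, 3 - idx, other_idx)
    return _BASES[idx], _BASES[a2_idx]


def simulate_sumstats(S_true: np.ndarray, design: CohortDesign,
                      panel: LDScorePanel,
                      cross_intercepts: np.ndarray | None = None,
                      seed: int = 0, *,
                      ambiguous_frac: float = 0.05,
                      allele_swap_frac: float = 0.05,
                      freq_low: float = 0.005,
                      info_beta: float = 40.0,
                      with_qc_columns: bool = True) -> list[SummaryStats]:
    """Simulate per-trait GWAS summary statistics from the LDSC moment model.

    Parameters
    ----------
    S_true
        Symmetric PSD generative genetic covariance (k x k).
    design
        Cohort sizes and labels; k must match S_true.
    panel
        LD-score panel supplying l_j and M.
    cross_intercepts
        The intercept matrix C (identity when None): 1 on the diagonal for
        no confounding, 0 off-diagonal for non-overlapping samples.
    ambiguous_frac, allele_swap_frac
        Fraction of SNPs given strand-ambiguous alleles, and fraction of
        SNPs in traits 2..k emitted with swapped A1/A2 (and negated Z) to
        exercise downstream harmonization.
    freq_low, info_beta
        FRQ ~ Uniform(freq_low, 1-freq_low) shared across traits; INFO ~
        1 - Beta(1, info_beta) per trait.

    Every SNP's z-vector is an independent multivariate-normal draw with
    covariance C + sqrt(N N') * S_true * l_j / M. Deterministic given seed.
    """
    S_true = np.asarray(S_true, dtype=float)
    k = design.k
    if S_true.shape != (k, k):
        raise ValueError("design.k must match dim(S_true)")
    if not np.allclose(S_true, S_true.T):
        raise ValueError("S_true must be symmetric")
    C = np.eye(k) if cross_intercepts is None else np.asarray(cross_intercepts, float)
    if C.shape != (k, k):
        raise ValueError("cross_intercepts must be k x k")

    rng = np.random.default_rng(seed)
    m = len(panel)
    n = np.asarray(design.n_per_trait, dtype=float)
    B = np.sqrt(np.outer(n, n)) * S_true
    sigma = C[None, :, :] + (panel.ld_score / panel.m_total)[:, None, None] * B[None, :, :]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        eigmin = np.linalg.eigvalsh(sigma)[:, 0]
        bad = int(np.argmax(eigmin < 0))
        raise DataError(
            f"per-SNP z covariance not positive semidefinite at SNP "
            f"{panel.snp_id[bad]} (min eigenvalue {eigmin[bad]:.3g})")
    z = np.einsum("mij,mj->mi", L, rng.standard_normal((m, k)))

    a1, a2 = _draw_alleles(rng, m, ambiguous_frac)
    freq = rng.uniform(freq_low, 1.0 - freq_low, size=m)

    out: list[SummaryStats] = []
    for t in range(k):
        zt = z[:, t].copy()
        a1t, a2t, frq = a1.copy(), a2.copy(), freq.copy()
        if t > 0 and allele_swap_frac > 0:
            swap = rng.random(m) < allele_swap_frac
            a1t[swap], a2t[swap] = a2[swap], a1[swap]
            zt[swap] = -zt[swap]
            frq[swap] = 1.0 - frq[swap]
        tab = pd.DataFrame({
            "SNP": panel.snp_id, "CHR": panel.chrom, "BP": panel.bp,
            "A1": a1t, "A2": a2t, "Z": zt,
            "N": np.full(m, design.n_per_trait[t], dtype=np.int64),
        })
        if with_qc_columns:
            tab["INFO"] = 1.0 - rng.beta(1.0, info_beta, size=m)
            tab["FRQ"] = frq
        out.append(SummaryStats(trait=design.labels[t], table=tab))
    return out


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write one trait's summary statistics as tab-separated text."""
    stats.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_ld_panel(panel: LDScorePanel, prefix: str | Path) -> None:
    """Write ``<prefix>.l2.ldscore`` (CHR SNP BP L2) and ``<prefix>.l2.M``."""
    prefix = str(prefix)
    panel.to_frame().to_csv(prefix + ".l2.ldscore", sep="\t", index=False,
                            float_format="%.6f")
    Path(prefix + ".l2.M").write_text(f"{panel.m_total}\n")


def read_ld_panel(prefix: str | Path) -> LDScorePanel:
    """Read a panel written by :func:`write_ld_panel`."""
    prefix = str(prefix)
    tab = pd.read_csv(prefix + ".l2.ldscore", sep="\t",
                      dtype={"CHR": str, "SNP": str})
    m_total = int(Path(prefix + ".l2.M").read_text().split()[0])
    return LDScorePanel(snp_id=tab["SNP"].to_numpy(),
                        chrom=tab["CHR"].to_numpy(),
                        bp=tab["BP"].to_numpy(dtype=np.int64),
                        ld_score=tab["L2"].to_numpy(dtype=float),
                        m_total=m_total)
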