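"""Multivariate LD-score regression with a joint block jackknife.

For each trait pair (t, u) the product of z-scores is regressed on the LD
score: E[z_t z_u | j] = c_tu + sqrt(N_t N_u) * sigma_tu * l_j / M, so the
fitted slope times M / sqrt(N_t N_u) estimates the genetic covariance
sigma_tu (the SNP heritability when t = u, where z_t z_t is the chi-square).
Heteroskedasticity weights follow the standard two-pass scheme; the sampling
covariance V of vech(S) comes from a delete-one block jackknife over
contiguous blocks of position-sorted SNPs, computed jointly across all
k(k+1)/2 regressions so V captures cross-estimate dependence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .linalg import vech_indices
from .simulate import LDScorePanel, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "LdscFitConfig",
    "PairFit",
    "GeneticCovariance",
    "univariate_ldsc",
    "cross_trait_ldsc",
    "multivariate_ldsc",
    "assemble_S_V",
    "smooth_to_pd",
    "genetic_correlations",
]


@dataclass(frozen=True)
class LdscFitConfig:
    """Estimation settings for the LD-score regressions.

    n_blocks
        Jackknife block count over position-sorted SNPs (default 200).
    intercept_h2 / intercept_gcov
        "free" estimates the intercept; "fixed" pins it at 1 (univariate,
        no confounding) or 0 (cross-trait, no sample overlap).
    chisq_max
        Per-trait chi-square outlier cap; None means max(80, 0.001 * Nbar).
    weight_iterations
        Number of weighted-regression passes; pass 1 uses 1/l weights, later
        passes plug the current estimates into the heteroskedasticity model.
    """

    n_blocks: int = 200
    intercept_h2: str = "free"
    intercept_gcov: str = "free"
    chisq_max: float | None = None
    weight_iterations: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ConfigurationError("n_blocks must be >= 2")
        if self.intercept_h2 not in ("free", "fixed"):
            raise ConfigurationError("intercept_h2 must be 'free' or 'fixed'")
        if self.intercept_gcov not in ("free", "fixed"):
            raise ConfigurationError("intercept_gcov must be 'free' or 'fixed'")
        if self.weight_iterations < 1:
            raise ConfigurationError("weight_iterations must be >= 1")


@dataclass
class PairFit:
    """One regression's full-sample and delete-one-block estimates."""

    estimate: float               # genetic covariance (h2 on the diagonal)
    intercept: float
    delete_one: np.ndarray        # (n_blocks,) delete-one estimates
    se: float                     # jackknife SE of `estimate`
    partition_tag: int            # fingerprint of the SNP/block partition
    n_snps: int
    intercept_se: float = 0.0     # jackknife SE of the intercept (0 if fixed)


@dataclass
class GeneticCovariance:
    """k x k genetic covariance S with its jackknife sampling covariance V.

    ``V`` is q x q with q = k(k+1)/2, the sampling covariance of vech(S)
    (lower triangle, column-major, covariance scale). ``intercepts`` holds
    univariate intercepts on the diagonal and cross-trait intercepts off it.
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    n_per_trait: tuple[int, ...]
    labels: tuple[str, ...]
    n_blocks: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.S.shape[0]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.V))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "S": self.S.tolist(), "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_per_trait": list(self.n_per_trait),
            "labels": list(self.labels), "n_blocks": self.n_blocks,
            "meta": self.meta}, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GeneticCovariance":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(S=np.asarray(d["S"]), V=np.asarray(d["V"]),
                   intercepts=np.asarray(d["intercepts"]),
                   n_per_trait=tuple(d["n_per_trait"]),
                   labels=tuple(d["labels"]), n_blocks=d.get("n_blocks", 0),
                   meta=d.get("meta", {}))


# ---------------------------------------------------------------------------
# weighted regression with delete-one block jackknife

def _block_boundaries(n: int, n_blocks: int) -> np.ndarray:
    return np.floor(np.arange(n_blocks + 1) * n / n_blocks).astype(np.int64)


def _wls_jackknife(y: np.ndarray, X: np.ndarray, w: np.ndarray,
                   bounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS solve plus delete-one-block coefficient estimates.

    Returns (coef (p,), delete_one (n_blocks, p)). SNPs must already be in
    block order (position-sorted); blocks are the contiguous slices defined
    by ``bounds``.
    """
    Xw = X * w[:, None]
    p = X.shape[1]
    n_blocks = len(bounds) - 1
    # per-block cross-products via reduceat on the contiguous layout
    xtx_terms = np.empty((X.shape[0], p, p))
    for i in range(p):
        for j in range(p):
            xtx_terms[:, i, j] = Xw[:, i] * X[:, j]
    xty_terms = Xw * y[:, None]
    starts = bounds[:-1]
    A_blocks = np.add.reduceat(xtx_terms.reshape(X.shape[0], -1), starts, axis=0)
    A_blocks = A_blocks.reshape(n_blocks, p, p)
    b_blocks = np.add.reduceat(xty_terms, starts, axis=0)
    A = A_blocks.sum(axis=0)
    b = b_blocks.sum(axis=0)
    coef = np.linalg.solve(A, b)
    delete_one = np.empty((n_blocks, p))
    for g in range(n_blocks):
        delete_one[g] = np.linalg.solve(A - A_blocks[g], b - b_blocks[g])
    return coef, delete_one


def _pair_regression(y: np.ndarray, ell: np.ndarray, scale: float, M: int,
                     w_denominator, cfg: LdscFitConfig, free_intercept: bool,
                     fixed_intercept: float, bounds: np.ndarray
                     ) -> tuple[float, float, np.ndarray]:
    """Generic LDSC pair regression of y on l with iterated weights.

    ``scale`` is sqrt(N_t N_u); ``w_denominator(est, icept)`` returns the
    per-SNP heteroskedasticity variance model evaluated at the current
    estimates. Returns (genetic covariance, intercept, delete-one covs).
    """
    x = ell * scale / M
    est, icept = 0.0, fixed_intercept
    delete_one = delete_one_icept = None
    for _ in range(cfg.weight_iterations):
        w = 1.0 / (np.maximum(ell, 1.0) * w_denominator(est, icept))
        if free_intercept:
            X = np.column_stack([x, np.ones_like(x)])
            coef, d1 = _wls_jackknife(y, X, w, bounds)
            est, icept = float(coef[0]), float(coef[1])
            delete_one, delete_one_icept = d1[:, 0], d1[:, 1]
        else:
            X = x[:, None]
            coef, d1 = _wls_jackknife(y - fixed_intercept, X, w, bounds)
            est = float(coef[0])
            delete_one = d1[:, 0]
            delete_one_icept = np.full(len(bounds) - 1, fixed_intercept)
    return est, icept, delete_one, delete_one_icept


def _jackknife_se(delete_one: np.ndarray) -> float:
    B = len(delete_one)
    dev = delete_one - delete_one.mean()
    return float(np.sqrt((B - 1) / B * np.sum(dev**2)))


def _merge_with_panel(stats: SummaryStats, panel: LDScorePanel) -> pd.DataFrame:
    tab = stats.table.merge(panel.to_frame()[["SNP", "L2"]], on="SNP", how="inner")
    if tab.empty:
        raise DataError(f"no overlap between trait {stats.trait!r} and the LD panel")
    return tab.sort_values(["CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)


def _chisq_cap(cfg: LdscFitConfig, nbar: float) -> float:
    return cfg.chisq_max if cfg.chisq_max is not None else max(80.0, 0.001 * nbar)


def univariate_ldsc(stats: SummaryStats, panel: LDScorePanel,
                    cfg: LdscFitConfig | None = None) -> PairFit:
    """SNP heritability of one trait by weighted chi-square-on-l regression.

    The slope times M / Nbar is h2; weights are 1 / [l (1 + Nbar h2 l / M)^2]
    refined over ``weight_iterations`` passes; delete-one h2 estimates over
    position-sorted blocks give the jackknife SE.
    """
    cfg = cfg or LdscFitConfig()
    tab = _merge_with_panel(stats, panel)
    ell = tab["L2"].to_numpy(dtype=float)
    if np.any(ell <= 0):
        raise DataError("non-positive LD scores")
    z = tab["Z"].to_numpy(dtype=float)
    nbar = float(tab["N"].to_numpy(dtype=float).mean())
    cap = _chisq_cap(cfg, nbar)
    keep = z**2 <= cap
    if (~keep).sum():
        logger.info("%s: capped %d SNPs with chi-square > %.1f",
                    stats.trait, int((~keep).sum()), cap)
    tab, ell, z = tab[keep], ell[keep], z[keep]
    if len(tab) < cfg.n_blocks:
        raise DataError("fewer SNPs than jackknife blocks")
    bounds = _block_boundaries(len(tab), cfg.n_blocks)
    M = panel.m_total

    def denom(h2, icept):
        return (1.0 + nbar * max(h2, 0.0) * ell / M) ** 2

    est, icept, d1, d1i = _pair_regression(
        z**2, ell, nbar, M, denom, cfg,
        free_intercept=(cfg.intercept_h2 == "free"), fixed_intercept=1.0,
        bounds=bounds)
    return PairFit(estimate=est, intercept=icept, delete_one=d1,
                   se=_jackknife_se(d1), partition_tag=hash((len(tab), cfg.n_blocks)),
                   n_snps=len(tab), intercept_se=_jackknife_se(d1i))


def cross_trait_ldsc(stats_a: SummaryStats, stats_b: SummaryStats,
                     panel: LDScorePanel, cfg: LdscFitConfig | None = None
                     ) -> PairFit:
    """Genetic covariance of two traits by z-product-on-l regression.

    When both arguments carry the same data this reproduces the univariate
    fit exactly (same weights, y = chi-square). The cross intercept is free
    by default; for non-overlapping samples its expectation is 0.
    """
    cfg = cfg or LdscFitConfig()
    same = stats_a is stats_b or (
        len(stats_a.table) == len(stats_b.table)
        and stats_a.table["SNP"].equals(stats_b.table["SNP"])
        and stats_a.table["Z"].equals(stats_b.table["Z"])
        and stats_a.table["N"].equals(stats_b.table["N"]))
    if same:
        return univariate_ldsc(stats_a, panel, cfg)
    ta = _merge_with_panel(stats_a, panel)
    tb = _merge_with_panel(stats_b, panel)
    if len(ta) != len(tb) or not ta["SNP"].equals(tb["SNP"]):
        raise DataError("SNP sets misaligned between traits; run munge first")
    ua = univariate_ldsc(stats_a, panel, cfg)
    ub = univariate_ldsc(stats_b, panel, cfg)
    ell = ta["L2"].to_numpy(dtype=float)
    za, zb = ta["Z"].to_numpy(dtype=float), tb["Z"].to_numpy(dtype=float)
    na, nb = (float(ta["N"].mean()), float(tb["N"].mean()))
    keep = (za**2 <= _chisq_cap(cfg, na)) & (zb**2 <= _chisq_cap(cfg, nb))
    ell, za, zb = ell[keep], za[keep], zb[keep]
    if len(ell) < cfg.n_blocks:
        raise DataError("fewer SNPs than jackknife blocks")
    bounds = _block_boundaries(len(ell), cfg.n_blocks)
    M = panel.m_total

    def denom(rho, icept):
        return ((1.0 + na * max(ua.estimate, 0.0) * ell / M)
                * (1.0 + nb * max(ub.estimate, 0.0) * ell / M)
                + (np.sqrt(na * nb) * rho * ell / M + icept) ** 2)

    est, icept, d1, d1i = _pair_regression(
        za * zb, ell, float(np.sqrt(na * nb)), M, denom, cfg,
        free_intercept=(cfg.intercept_gcov == "free"), fixed_intercept=0.0,
        bounds=bounds)
    return PairFit(estimate=est, intercept=icept, delete_one=d1,
                   se=_jackknife_se(d1), partition_tag=hash((len(ell), cfg.n_blocks)),
                   n_snps=len(ell), intercept_se=_jackknife_se(d1i))


def multivariate_ldsc(stats: list[SummaryStats], panel: LDScorePanel,
                      cfg: LdscFitConfig | None = None) -> GeneticCovariance:
    """All pairwise LDSC regressions on one shared SNP/block partition.

    The common SNP set (all traits x panel, chi-square cap applied jointly)
    is position-sorted and split into ``n_blocks`` contiguous blocks; every
    pair regression runs on that identical partition so the joint jackknife
    yields a coherent sampling covariance V of vech(S).
    """
    cfg = cfg or LdscFitConfig()
    k = len(stats)
    if k < 1:
        raise ConfigurationError("need at least one trait")
    tabs = [_merge_with_panel(st, panel) for st in stats]
    snps = tabs[0]["SNP"]
    for st, tab in zip(stats[1:], tabs[1:]):
        if len(tab) != len(snps) or not tab["SNP"].equals(snps):
            raise DataError(
                f"SNP sets misaligned between {stats[0].trait!r} and "
                f"{st.trait!r}; run munge first")
    Z = np.column_stack([t["Z"].to_numpy(dtype=float) for t in tabs])
    ell = tabs[0]["L2"].to_numpy(dtype=float)
    nbar = np.array([float(t["N"].mean()) for t in tabs])
    caps = np.array([_chisq_cap(cfg, nb) for nb in nbar])
    keep = np.all(Z**2 <= caps[None, :], axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("chi-square cap dropped %d SNPs across traits", n_dropped)
    Z, ell = Z[keep], ell[keep]
    m_used = len(ell)
    if m_used < cfg.n_blocks:
        raise DataError("fewer SNPs than jackknife blocks")
    bounds = _block_boundaries(m_used, cfg.n_blocks)
    M = panel.m_total

    # univariate passes first (h2 feeds the cross-trait weights)
    uni: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    for t in range(k):
        def denom_u(h2, icept, t=t):
            return (1.0 + nbar[t] * max(h2, 0.0) * ell / M) ** 2
        uni.append(_pair_regression(
            Z[:, t] ** 2, ell, nbar[t], M, denom_u, cfg,
            free_intercept=(cfg.intercept_h2 == "free"), fixed_intercept=1.0,
            bounds=bounds))

    rows, cols = vech_indices(k)
    q = len(rows)
    est_vec = np.empty(q)
    delete = np.empty((cfg.n_blocks, q))
    intercepts = np.eye(k)
    intercept_se = np.zeros((k, k))
    for pos, (t, u) in enumerate(zip(rows, cols)):
        if t == u:
            est, icept, d1, d1i = uni[t]
        else:
            h2t, h2u = max(uni[t][0], 0.0), max(uni[u][0], 0.0)
            scale = float(np.sqrt(nbar[t] * nbar[u]))

            def denom_c(rho, icept, t=t, u=u, h2t=h2t, h2u=h2u, scale=scale):
                return ((1.0 + nbar[t] * h2t * ell / M)
                        * (1.0 + nbar[u] * h2u * ell / M)
                        + (scale * rho * ell / M + icept) ** 2)

            est, icept, d1, d1i = _pair_regression(
                Z[:, t] * Z[:, u], ell, scale, M, denom_c, cfg,
                free_intercept=(cfg.intercept_gcov == "free"),
                fixed_intercept=0.0, bounds=bounds)
        est_vec[pos] = est
        delete[:, pos] = d1
        intercepts[t, u] = intercepts[u, t] = icept
        intercept_se[t, u] = intercept_se[u, t] = _jackknife_se(d1i)

    pair_fits = {
        (int(t), int(u)): PairFit(
            estimate=est_vec[pos], intercept=intercepts[t, u],
            delete_one=delete[:, pos], se=_jackknife_se(delete[:, pos]),
            partition_tag=hash((m_used, cfg.n_blocks)), n_snps=m_used)
        for pos, (t, u) in enumerate(zip(rows, cols))}
    gc = assemble_S_V(pair_fits, k, cfg)
    gc.intercepts = intercepts
    gc.n_per_trait = tuple(int(round(nb)) for nb in nbar)
    gc.labels = tuple(st.trait for st in stats)
    gc.meta = {"m_snps": m_used, "m_total": int(M),
               "chisq_cap_dropped": n_dropped,
               "intercept_se": intercept_se.tolist()}
    return gc


def assemble_S_V(pair_fits: dict[tuple[int, int], PairFit], k: int,
                 cfg: LdscFitConfig | None = None) -> GeneticCovariance:
    """Assemble S and the joint jackknife V from per-pair fits.

    All pairs must come from the same SNP partition (checked via the
    partition fingerprint). V = (B-1)/B * sum_b (theta_b - theta_bar)
    (theta_b - theta_bar)' over the q-vector of delete-one estimates.
    """
    cfg = cfg or LdscFitConfig()
    rows, cols = vech_indices(k)
    q = len(rows)
    tags = {pf.partition_tag for pf in pair_fits.values()}
    if len(tags) > 1:
        raise DataError("inconsistent block partitions across pair fits")
    S = np.zeros((k, k))
    delete = np.empty((cfg.n_blocks, q))
    for pos, (t, u) in enumerate(zip(rows, cols)):
        pf = pair_fits.get((t, u)) or pair_fits.get((u, t))
        if pf is None:
            raise DataError(f"missing pair fit for trait pair ({t}, {u})")
        if len(pf.delete_one) != cfg.n_blocks:
            raise DataError("pair fit block count does not match config")
        S[t, u] = S[u, t] = pf.estimate
        delete[:, pos] = pf.delete_one
    B = cfg.n_blocks
    dev = delete - delete.mean(axis=0, keepdims=True)
    V = (B - 1) / B * dev.T @ dev
    return GeneticCovariance(S=S, V=V, intercepts=np.eye(k),
                             n_per_trait=tuple([0] * k),
                             labels=tuple(f"trait_{i + 1}" for i in range(k)),
                             n_blocks=B)


def smooth_to_pd(S: np.ndarray, epsilon: float | None = None) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix to make it positive definite.

    Eigenvalues below epsilon (default 1e-6 times the largest eigenvalue)
    are raised to epsilon and the matrix reconstructed; already-PD input is
    returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise DataError("smooth_to_pd requires a symmetric matrix")
    evals, evecs = np.linalg.eigh(S)
    eps = epsilon if epsilon is not None else 1e-6 * float(evals[-1])
    if evals[0] >= eps:
        return S
    evals = np.maximum(evals, eps)
    out = evecs @ np.diag(evals) @ evecs.T
    return (out + out.T) / 2


def genetic_correlations(gc: GeneticCovariance | np.ndarray) -> np.ndarray:
    """Genetic correlation matrix R[t,u] = S[t,u] / sqrt(S[t,t] S[u,u])."""
    S = gc.S if isinstance(gc, GeneticCovariance) else np.asarray(gc, float)
    d = np.diag(S)
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        labels = (gc.labels if isinstance(gc, GeneticCovariance)
                  else tuple(f"trait_{i + 1}" for i in range(len(d))))
        raise DataError(f"non-positive heritability for trait {labels[bad]!r}")
    R = S / np.sqrt(np.outer(d, d))
    np.fill_diagonal(R, 1.0)
    return R
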