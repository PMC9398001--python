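"""Diagonally weighted least squares fitting and fit indices.

A model is fitted to the LDSC output (S, V) by minimizing

    F(theta) = (s - sigma(theta))' diag(V)^-1 (s - sigma(theta)),

with s = vech(S). Because diag(V)^-1 is not the full inverse sampling
covariance, the naive F is not chi-square distributed; the model test
statistic is the residual-based form

    T = r' [V^- - V^- D (D' V^- D)^- D' V^-] r,    r = s - sigma(theta_hat),

with D the Jacobian of sigma at the solution, which is asymptotically
chi-square(df) whenever the model holds, for any consistent estimator.
Parameter standard errors use the corresponding sandwich. Fit indices follow
the summary-statistic conventions: pseudoAIC = chi-square + 2 * free
parameters, CFI and TLI against the independence baseline (not capped at 1),
and SRMR over unique elements including the diagonal after standardizing
both matrices by the observed standard deviations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .exceptions import ConfigurationError, DataError
from .ldsc import GeneticCovariance, smooth_to_pd
from .linalg import vech, vech_indices
from .models import SemModel, build_baseline_model

logger = logging.getLogger(__name__)

__all__ = ["FitOptions", "FitResult", "fit_dwls", "fit_baseline",
           "fit_indices", "compare_models", "pseudo_aic"]


def pseudo_aic(chisq: float, n_free: int) -> float:
    """Summary-statistic AIC analogue: model chi-square + 2 * free parameters."""
    return float(chisq + 2 * n_free)

# variance-at-bound (Heywood-adjacent) detection: a fitted variance below
# this fraction of the largest observed variance sits above the PD-smoothing
# floor (1e-6 of the top eigenvalue) yet is negligible on the data's scale
_BOUND_FRACTION = 1e-4


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_dwls`.

    ``n_starts`` jittered restarts (the first start is unjittered) guard
    against local minima; ``seed`` makes the jitter reproducible. Variances
    are optimized on a log scale, transmission coefficients and loadings
    unconstrained. Tolerances are tight enough that just-identified models
    reach machine-precision residuals.
    """

    seed: int = 0
    n_starts: int = 5
    jitter_sd: float = 0.25
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None


@dataclass
class FitResult:
    """Estimates, test statistic and fit indices for one fitted model."""

    model_name: str
    k: int
    n_free: int
    df: int
    estimates: dict
    se: dict
    chisq: float
    p: float
    pseudo_aic: float
    srmr: float
    implied: np.ndarray
    converged: bool
    fmin: float
    cfi: float | None = None
    tli: float | None = None
    at_bound: list = field(default_factory=list)
    gc_tag: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "model": self.model_name, "k": self.k, "n_free": self.n_free,
            "df": self.df, "estimates": self.estimates, "se": self.se,
            "chisq": self.chisq, "p": self.p, "pseudo_aic": self.pseudo_aic,
            "cfi": self.cfi, "tli": self.tli, "srmr": self.srmr,
            "converged": self.converged, "fmin": self.fmin,
            "at_bound": self.at_bound,
            "implied": np.asarray(self.implied).tolist()}, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _gc_tag(gc: GeneticCovariance) -> int:
    return hash((gc.S.round(12).tobytes(), gc.V.round(14).tobytes()))


def _start_values(model: SemModel, S: np.ndarray) -> np.ndarray:
    """Start vector on the optimization scale (log for variances)."""
    diag = np.diag(S)
    mean_var = float(np.mean(diag))
    u0 = np.empty(model.n_free)
    for i, (slot, members, positive) in enumerate(model.free_slots()):
        if positive:
            # variances start from the observed diagonal (halved so that
            # variance pairs sharing a diagonal entry do not overshoot)
            vals = []
            for name in members:
                idx = name.rsplit("_", 1)[-1]
                if idx.isdigit() and 1 <= int(idx) <= model.k:
                    vals.append(0.5 * diag[int(idx) - 1])
                else:
                    vals.append(0.5 * mean_var)
            start = max(float(np.mean(vals)), 1e-6 * max(mean_var, 1e-12))
            u0[i] = np.log(start)
        else:
            u0[i] = 0.5  # loadings / transmission coefficients
    return u0


def _to_natural(model: SemModel, u: np.ndarray) -> dict[str, float]:
    vals = {}
    for (slot, members, positive), ui in zip(model.free_slots(), u):
        vals[slot] = float(np.exp(ui)) if positive else float(ui)
    return vals


def _sigma_vec(model: SemModel, free_values: dict[str, float]) -> np.ndarray:
    return vech(model.implied(model.parameter_values(free_values)))


def _jacobian_natural(model: SemModel, free_values: dict[str, float]
                      ) -> np.ndarray:
    """d vech(sigma) / d theta at the natural-scale free-slot values."""
    slots = model.free_slots()
    q = model.k * (model.k + 1) // 2
    D = np.empty((q, len(slots)))
    for j, (slot, _, positive) in enumerate(slots):
        v = free_values[slot]
        h = 1e-6 * (abs(v) + 1e-4)
        lo = {**free_values, slot: v - h}
        hi = {**free_values, slot: v + h}
        if positive and v - h < 0:
            lo, h_eff = free_values, h
            D[:, j] = (_sigma_vec(model, hi) - _sigma_vec(model, lo)) / h_eff
        else:
            D[:, j] = (_sigma_vec(model, hi) - _sigma_vec(model, lo)) / (2 * h)
    return D


def _residual_chisq(r: np.ndarray, D: np.ndarray, V: np.ndarray,
                    df: int, n_blocks: int = 0) -> float:
    if df <= 0:
        return 0.0
    Vi = np.linalg.pinv(V, rcond=1e-12, hermitian=True)
    A = D.T @ Vi @ D
    U = Vi - Vi @ D @ np.linalg.pinv(A, rcond=1e-10) @ D.T @ Vi
    stat = float(max(r @ U @ r, 0.0))
    # V estimated from a finite number of jackknife blocks: plugging V-hat
    # into the quadratic form inflates it by ~(B-1)/(B-q-2) (inverse-Wishart
    # first moment); undo that so the statistic is chi-square(df) calibrated
    q = V.shape[0]
    if n_blocks > q + 2:
        stat *= (n_blocks - q - 2) / (n_blocks - 1)
    return stat


def _srmr(S: np.ndarray, implied: np.ndarray) -> float:
    sd = np.sqrt(np.diag(S))
    denom = np.outer(sd, sd)
    resid = (S - implied) / denom
    return float(np.sqrt(np.mean(vech(resid) ** 2)))


def fit_dwls(model: SemModel, gc: GeneticCovariance,
             options: FitOptions | None = None) -> FitResult:
    """Fit a structural model to (S, V) by DWLS.

    S is PD-smoothed first; the weight is the inverse diagonal of V; the
    chi-square is the residual-based statistic using the full V (see module
    docstring). Non-convergence is flagged on the result, never silent;
    variance estimates at the zero bound raise a Heywood-adjacent warning.
    """
    options = options or FitOptions()
    if model.k != gc.S.shape[0]:
        raise ConfigurationError("model.k does not match dim(S)")
    S = smooth_to_pd(gc.S)
    s = vech(S)
    d = np.diag(gc.V).copy()
    if np.any(d <= 0):
        raise DataError("diag(V) must be positive to form DWLS weights")
    sqrt_w = 1.0 / np.sqrt(d)
    n_free, df = model.n_free, model.df
    if df < 0:
        raise ConfigurationError("negative degrees of freedom")

    if model.kind == "saturated":
        # closed form: every moment free, implied == S
        est = {f"s_{r + 1}_{c + 1}": float(S[r, c])
               for r, c in zip(*vech_indices(model.k))}
        return FitResult(model_name=model.name, k=model.k, n_free=n_free,
                         df=0, estimates=est, se={}, chisq=0.0, p=1.0,
                         pseudo_aic=pseudo_aic(0.0, n_free), srmr=0.0, implied=S,
                         converged=True, fmin=0.0, gc_tag=_gc_tag(gc))

    def resid(u: np.ndarray) -> np.ndarray:
        return sqrt_w * (s - _sigma_vec(model, _to_natural(model, u)))

    rng = np.random.default_rng(options.seed)
    u0 = _start_values(model, S)
    best = None
    for start in range(options.n_starts):
        u_init = u0 if start == 0 else u0 + rng.normal(0.0, options.jitter_sd,
                                                       size=u0.size)
        try:
            sol = optimize.least_squares(
                resid, u_init, method="trf", ftol=options.ftol,
                xtol=options.xtol, gtol=options.gtol,
                max_nfev=options.max_nfev)
        except Exception as exc:  # optimizer blow-up on a bad start
            logger.debug("start %d failed: %s", start, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DataError(f"all optimizer starts failed for model {model.name!r}")
    converged = bool(best.status > 0)
    if not converged:
        logger.warning("model %s: optimizer did not converge (status %d)",
                       model.name, best.status)

    free_values = _to_natural(model, best.x)
    full_values = model.parameter_values(free_values)
    implied = model.implied(full_values)
    r = s - vech(implied)
    fmin = float(2.0 * best.cost)  # cost is 0.5 * sum of squared residuals

    at_bound = []
    scale = float(np.max(np.diag(S)))
    for slot, members, positive in model.free_slots():
        if positive and free_values[slot] < _BOUND_FRACTION * scale:
            at_bound.append(slot)
    if at_bound:
        warnings.warn(f"model {model.name!r}: variance parameter(s) at zero "
                      f"bound (Heywood-adjacent): {at_bound}", stacklevel=2)

    D = _jacobian_natural(model, free_values)
    W = np.diag(1.0 / d)
    G = D.T @ W @ D
    Gi = np.linalg.pinv(G, rcond=1e-10)
    cov = Gi @ D.T @ W @ gc.V @ W @ D @ Gi
    se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = {slot: float(sv) for (slot, _, _), sv in zip(model.free_slots(), se_vec)}

    chisq = _residual_chisq(r, D, gc.V, df, n_blocks=gc.n_blocks)
    p = float(sps.chi2.sf(chisq, df)) if df > 0 else 1.0
    return FitResult(model_name=model.name, k=model.k, n_free=n_free, df=df,
                     estimates={k_: float(v) for k_, v in full_values.items()},
                     se=se, chisq=chisq, p=p,
                     pseudo_aic=pseudo_aic(chisq, n_free),
                     srmr=_srmr(S, implied), implied=implied,
                     converged=converged, fmin=fmin, at_bound=at_bound,
                     gc_tag=_gc_tag(gc))


def fit_baseline(gc: GeneticCovariance, options: FitOptions | None = None
                 ) -> FitResult:
    """Fit the independence baseline used by the incremental fit indices."""
    return fit_dwls(build_baseline_model(gc.S.shape[0]), gc, options)


def fit_indices(fit: FitResult, baseline: FitResult) -> FitResult:
    """Augment a fit with CFI and TLI computed against the independence
    baseline on the same (S, V).

    CFI = 1 - (chi2_m - df_m) / (chi2_b - df_b), not capped at 1;
    TLI = [(chi2_b/df_b) - (chi2_m/df_m)] / [(chi2_b/df_b) - 1]. When the
    baseline chi-square does not exceed its df the indices are undefined
    and reported as None.
    """
    if baseline.gc_tag != fit.gc_tag:
        raise DataError("baseline was fitted to a different (S, V)")
    if baseline.chisq <= baseline.df or baseline.df == 0:
        logger.warning("baseline chi-square <= df: CFI/TLI undefined")
        return replace(fit, cfi=None, tli=None)
    cfi = 1.0 - (fit.chisq - fit.df) / (baseline.chisq - baseline.df)
    if fit.df > 0:
        ratio_b = baseline.chisq / baseline.df
        ratio_m = fit.chisq / fit.df
        tli = (ratio_b - ratio_m) / (ratio_b - 1.0)
    else:
        tli = None
    return replace(fit, cfi=float(cfi), tli=None if tli is None else float(tli))


def compare_models(fits: list[FitResult], labels: list[str] | None = None
                   ) -> pd.DataFrame:
    """Model-comparison table: chi-square(df), p, pseudoAIC, CFI, TLI, SRMR.

    All fits must come from the same (S, V). The winner (lowest pseudoAIC,
    ties broken by fewer free parameters, remaining ties reported) is stored
    in ``table.attrs['winner']`` / ``attrs['tied']``.
    """
    if not fits:
        raise ConfigurationError("no fits to compare")
    tags = {f.gc_tag for f in fits}
    if len(tags) > 1:
        raise DataError("fits come from different (S, V) inputs")
    labels = labels or [f.model_name for f in fits]
    if len(labels) != len(fits):
        raise ConfigurationError("labels length must match fits")
    tab = pd.DataFrame({
        "model": labels,
        "chisq": [f.chisq for f in fits],
        "df": [f.df for f in fits],
        "p": [f.p for f in fits],
        "pseudoAIC": [f.pseudo_aic for f in fits],
        "CFI": [f.cfi for f in fits],
        "TLI": [f.tli for f in fits],
        "SRMR": [f.srmr for f in fits],
    })
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].pseudo_aic, fits[i].n_free))
    winner = order[0]
    tied = [labels[i] for i in order
            if np.isclose(fits[i].pseudo_aic, fits[winner].pseudo_aic)
            and fits[i].n_free == fits[winner].n_free]
    tab.attrs["winner"] = labels[winner]
    tab.attrs["tied"] = tied if len(tied) > 1 else []
    return tab
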