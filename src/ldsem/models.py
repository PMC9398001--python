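"""Structural models of genetic stability as declarative parameter maps.

Two substantive structures compete. The common-factor model loads every
age tranche's genetic component on one latent factor (first loading fixed
at 1 for identification), implying lag-invariant genetic correlations. The
simplex (first-order autoregression) model carries genetic level forward
through transmission coefficients beta_t with age-specific innovation
variances zeta_t, implying correlations that decay with lag; residual
variances theta_t sit on the observed diagonal in both. Saturated and
independence models anchor the chi-square and the incremental fit indices.

Each model is a list of named parameters with status free / fixed(value),
optionally tied into equality groups, plus the model-implied covariance
function sigma(theta); degrees of freedom are k(k+1)/2 minus the number of
free parameter slots (equality groups count once).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigurationError
from .linalg import vech_indices

__all__ = [
    "Parameter",
    "SemModel",
    "build_factor_model",
    "build_simplex_model",
    "build_baseline_model",
    "build_saturated_model",
    "count_df",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class Parameter:
    """One named model parameter.

    ``status`` is "free" or "fixed"; fixed parameters carry their value.
    Free parameters sharing a ``group`` label are constrained equal and
    occupy one optimization slot. ``positive`` marks variances, which the
    optimizer handles on a log scale to enforce non-negativity.
    """

    name: str
    status: str = "free"
    value: float = 0.0
    group: str | None = None
    positive: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("free", "fixed"):
            raise ConfigurationError(f"bad parameter status {self.status!r}")


@dataclass(frozen=True)
class SemModel:
    """A declarative model: parameters plus implied-covariance structure."""

    name: str
    k: int
    kind: str                       # factor | simplex | saturated | independence
    params: tuple[Parameter, ...]

    def free_slots(self) -> list[tuple[str, list[str], bool]]:
        """Ordered free slots: (slot name, member parameter names, positive)."""
        slots: dict[str, tuple[list[str], bool]] = {}
        for p in self.params:
            if p.status != "free":
                continue
            key = p.group or p.name
            if key not in slots:
                slots[key] = ([], p.positive)
            slots[key][0].append(p.name)
        return [(key, members, pos) for key, (members, pos) in slots.items()]

    @property
    def n_free(self) -> int:
        return len(self.free_slots())

    @property
    def df(self) -> int:
        q = self.k * (self.k + 1) // 2
        return q - self.n_free

    def parameter_values(self, free_values: Mapping[str, float]) -> dict[str, float]:
        """Full parameter-name -> value map from free-slot values."""
        out = {p.name: p.value for p in self.params if p.status == "fixed"}
        for key, members, _ in self.free_slots():
            for name in members:
                out[name] = float(free_values[key])
        return out

    def implied(self, values: Mapping[str, float]) -> np.ndarray:
        """Model-implied covariance sigma(theta) from a full value map."""
        k = self.k
        if self.kind == "factor":
            lam = np.array([values[f"lambda_{t}"] for t in range(1, k + 1)])
            theta = np.array([values[f"theta_{t}"] for t in range(1, k + 1)])
            return np.outer(lam, lam) * values["psi"] + np.diag(theta)
        if self.kind == "simplex":
            zeta = np.array([values[f"zeta_{t}"] for t in range(1, k + 1)])
            beta = np.array([values[f"beta_{t}"] for t in range(2, k + 1)])
            theta = np.array([values[f"theta_{t}"] for t in range(1, k + 1)])
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
        if self.kind == "saturated":
            S = np.zeros((k, k))
            for r, c in zip(*vech_indices(k)):
                S[r, c] = S[c, r] = values[f"s_{r + 1}_{c + 1}"]
            return S
        if self.kind == "independence":
            return np.diag([values[f"v_{t}"] for t in range(1, k + 1)])
        raise ConfigurationError(f"unknown model kind {self.kind!r}")


def build_factor_model(k: int) -> SemModel:
    """Single common factor: lambda_1 fixed at 1, free loadings 2..k, free
    factor variance psi and residuals theta; 2k free parameters."""
    if k < 3:
        raise ConfigurationError("factor model under-identified for k < 3")
    params = [Parameter("lambda_1", "fixed", 1.0)]
    params += [Parameter(f"lambda_{t}") for t in range(2, k + 1)]
    params += [Parameter("psi", positive=True)]
    params += [Parameter(f"theta_{t}", positive=True) for t in range(1, k + 1)]
    return SemModel(name="factor", k=k, kind="factor", params=tuple(params))


def build_simplex_model(k: int, drop: Iterable[int] = (),
                        equal_betas: bool = False,
                        equal_thetas: bool = False) -> SemModel:
    """Autoregression with innovations; ``drop`` fixes those innovation
    variances (1-based time indices) to zero.

    The full model frees zeta_1..k, beta_2..k and theta_1..k (3k - 1 free);
    ``drop={2..k}`` is the single-innovation model in which all genetic
    variance traces back to the first tranche. ``equal_betas`` /
    ``equal_thetas`` tie those sets to one slot each.
    """
    if k < 4:
        raise ConfigurationError("simplex model requires k >= 4 for identification")
    drop = frozenset(int(d) for d in drop)
    if not drop <= set(range(1, k + 1)):
        raise ConfigurationError(f"drop indices must lie in 1..{k}")
    if 1 in drop:
        warnings.warn("dropping only the first innovation removes the variance "
                      "source at the origin of the chain", stacklevel=2)
    params: list[Parameter] = []
    for t in range(1, k + 1):
        if t in drop:
            params.append(Parameter(f"zeta_{t}", "fixed", 0.0, positive=True))
        else:
            params.append(Parameter(f"zeta_{t}", positive=True))
    for t in range(2, k + 1):
        params.append(Parameter(f"beta_{t}",
                                group="beta" if equal_betas else None))
    for t in range(1, k + 1):
        params.append(Parameter(f"theta_{t}", positive=True,
                                group="theta" if equal_thetas else None))
    tag = ""
    if drop:
        tag += "_drop" + "_".join(str(d) for d in sorted(drop))
    if equal_betas or equal_thetas:
        tag += "_eq"
    return SemModel(name=f"simplex{tag}", k=k, kind="simplex", params=tuple(params))


def build_baseline_model(k: int) -> SemModel:
    """Independence model: free diagonal, off-diagonal fixed at 0 (df = k(k-1)/2)."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    params = tuple(Parameter(f"v_{t}", positive=True) for t in range(1, k + 1))
    return SemModel(name="independence", k=k, kind="independence", params=params)


def build_saturated_model(k: int) -> SemModel:
    """Saturated model: every moment free (df = 0)."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    params = []
    for r, c in zip(*vech_indices(k)):
        params.append(Parameter(f"s_{r + 1}_{c + 1}", positive=bool(r == c)))
    return SemModel(name="saturated", k=k, kind="saturated", params=tuple(params))


def count_df(model: SemModel) -> tuple[int, int]:
    """(free parameter count, degrees of freedom); equality groups count once."""
    free = model.n_free
    df = model.k * (model.k + 1) // 2 - free
    if df < 0:
        raise ConfigurationError(
            f"model {model.name!r} is over-parameterized (df = {df})")
    return free, df


def model_to_json(model: SemModel, path: str | Path | None = None) -> str:
    payload = json.dumps({
        "name": model.name, "k": model.k, "kind": model.kind,
        "params": [{"name": p.name, "status": p.status, "value": p.value,
                    "group": p.group, "positive": p.positive}
                   for p in model.params]}, indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def model_from_json(source: str | Path) -> SemModel:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    d = json.loads(text)
    params = tuple(Parameter(**p) for p in d["params"])
    return SemModel(name=d["name"], k=d["k"], kind=d["kind"], params=params)
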