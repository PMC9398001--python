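"""Plain-text report rendering: correlation matrix and model-comparison tables.

Mirrors the conventional presentation: the genetic-correlation matrix with
"h2 (SE)" cells on the diagonal (two decimals, so a correlation of 0.996
displays as 1.00), optionally a second group's correlations above the
diagonal, and the model-comparison table with chi-square(df), p, pseudoAIC,
CFI, TLI and SRMR columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ldsc import GeneticCovariance, genetic_correlations
from .linalg import vech_indices

__all__ = ["correlation_table", "comparison_table", "render_report"]


def _h2_cell(h2: float, se: float) -> str:
    return f"{h2:.2f} ({se:.2f})"


def correlation_table(gc: GeneticCovariance,
                      gc_upper: GeneticCovariance | None = None) -> str:
    """Correlations below the diagonal (and a second group above it when
    given), heritabilities with SEs on the diagonal."""
    k = gc.k
    R = genetic_correlations(gc)
    rows, cols = vech_indices(k)
    se_mat = np.zeros((k, k))
    se_flat = gc.se
    for pos, (r, c) in enumerate(zip(rows, cols)):
        se_mat[r, c] = se_mat[c, r] = se_flat[pos]
    upper = genetic_correlations(gc_upper) if gc_upper is not None else None

    cells = [["" for _ in range(k + 1)] for _ in range(k)]
    for t in range(k):
        cells[t][0] = f"{t + 1}. {gc.labels[t]}"
        for u in range(k):
            if u < t:
                cells[t][u + 1] = f"{R[t, u]:.2f}"
            elif u == t:
                cells[t][u + 1] = (_h2_cell(gc.S[t, t], se_mat[t, t])
                                   if upper is None else "1")
            elif upper is not None:
                cells[t][u + 1] = f"{upper[t, u]:.2f}"
    header = [""] + [f"{u + 1}." for u in range(k)]
    frame = pd.DataFrame(cells, columns=header)
    return frame.to_string(index=False)


def comparison_table(table: pd.DataFrame) -> str:
    """Format a compare_models table the way fit tables are printed."""
    out = pd.DataFrame({
        "Model": table["model"],
        "Chi-square(df)": [f"{c:.3f} ({d})" for c, d in
                           zip(table["chisq"], table["df"])],
        "p": [f"{p:.3f}" for p in table["p"]],
        "pseudoAIC": [f"{a:.3f}" for a in table["pseudoAIC"]],
        "CFI": [("" if c is None or pd.isna(c) else f"{c:.3f}") for c in table["CFI"]],
        "TLI": [("" if t is None or pd.isna(t) else f"{t:.3f}") for t in table["TLI"]],
        "SRMR": [f"{s:.3f}" for s in table["SRMR"]],
    })
    return out.to_string(index=False)


def render_report(gc: GeneticCovariance | None = None,
                  comparison: pd.DataFrame | None = None,
                  gc_upper: GeneticCovariance | None = None,
                  title: str = "Pseudo-longitudinal genomic SEM report") -> str:
    """One document from whatever artifacts exist; missing pieces become
    explicit gaps rather than failures."""
    parts = [f"# {title}", ""]
    if gc is not None:
        parts += ["## Heritabilities (diagonal) and genetic correlations", "",
                  correlation_table(gc, gc_upper), ""]
    else:
        parts += ["## Heritabilities and genetic correlations", "",
                  "(no genetic covariance artifact available)", ""]
    if comparison is not None and len(comparison):
        parts += ["## Model comparison", "", comparison_table(comparison), ""]
        if comparison.attrs.get("winner"):
            parts.append(f"Best-fitting model by pseudoAIC: "
                         f"{comparison.attrs['winner']}")
            if comparison.attrs.get("tied"):
                parts.append(f"(tied with: {', '.join(comparison.attrs['tied'])})")
        parts.append("")
    return "\n".join(parts)
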