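"""Half-vectorization helpers shared by the LDSC and SEM layers.

The q = k(k+1)/2 half-vectorization order is column-major over the lower
triangle: (1,1),(2,1),...,(k,1),(2,2),(3,2),...,(k,k). Every q-vector in the
package (vech(S), rows/columns of V, DWLS residuals) uses this order.
"""

from __future__ import annotations

import numpy as np


def vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the lower triangle in column-major order."""
    cols, rows = np.triu_indices(k)  # upper triangle row-major == lower col-major
    return rows, cols


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (lower triangle, column-major)."""
    mat = np.asarray(mat, dtype=float)
    r, c = vech_indices(mat.shape[0])
    return mat[r, c]


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    """Rebuild the symmetric k x k matrix from its half-vectorization."""
    out = np.zeros((k, k))
    r, c = vech_indices(k)
    out[r, c] = v
    out[c, r] = v
    return out
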