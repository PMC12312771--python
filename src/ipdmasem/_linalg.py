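"""Small matrix utilities shared across estimators.

Half-vectorization is fixed project-wide as column-major over the lower
triangle of a matrix ordered by the canonical variable order.
"""

from __future__ import annotations

import numpy as np


def vech_indices(p: int, strict: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the (strict) lower triangle, column-major."""
    rows, cols = [], []
    for j in range(p):
        for i in range(j + 1 if strict else j, p):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows), np.asarray(cols)


def vech(m: np.ndarray) -> np.ndarray:
    """Stack the lower triangle (including diagonal), column-major."""
    r, c = vech_indices(m.shape[0])
    return m[r, c]


def vechs(m: np.ndarray) -> np.ndarray:
    """Strict half-vectorization: below-diagonal elements, column-major."""
    r, c = vech_indices(m.shape[0], strict=True)
    return m[r, c]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    m = np.zeros((p, p))
    r, c = vech_indices(p)
    m[r, c] = v
    m[c, r] = v
    return m


def duplication_matrix(p: int) -> np.ndarray:
    """D such that vec(M) = D @ vech(M) for symmetric M."""
    nv = p * (p + 1) // 2
    d = np.zeros((p * p, nv))
    r, c = vech_indices(p)
    for k, (i, j) in enumerate(zip(r, c)):
        d[j * p + i, k] = 1.0
        d[i * p + j, k] = 1.0
    return d


def is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def nearest_psd(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues from below; used only for start values."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    return (v * np.maximum(w, floor)) @ v.T


def chol_to_sigma(l_flat: np.ndarray, p: int) -> np.ndarray:
    """Build L L' from a packed lower-triangular factor with log-diagonal."""
    L = np.zeros((p, p))
    r, c = vech_indices(p)
    L[r, c] = l_flat
    L[np.diag_indices(p)] = np.exp(np.diag(L))
    return L @ L.T


def sigma_to_chol(sigma: np.ndarray) -> np.ndarray:
    """Inverse of :func:`chol_to_sigma` (log-diagonal packing)."""
    L = np.linalg.cholesky(sigma)
    M = L.copy()
    M[np.diag_indices(sigma.shape[0])] = np.log(np.diag(L))
    return vech(M)


def chol_grad(grad_sigma: np.ndarray, l_flat: np.ndarray, p: int) -> np.ndarray:
    """Chain rule through Sigma = L L' with log-diagonal packing.

    ``grad_sigma`` is the symmetric full-matrix gradient P with
    dF = sum(P * dSigma); returns gradient w.r.t. the packed factor.
    """
    L = np.zeros((p, p))
    r, c = vech_indices(p)
    L[r, c] = l_flat
    diag = np.exp(np.diag(L))
    L[np.diag_indices(p)] = diag
    G = 2.0 * grad_sigma @ L
    G[np.diag_indices(p)] *= diag  # d/d(log diag)
    return G[r, c]
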