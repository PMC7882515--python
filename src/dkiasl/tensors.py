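"""Symmetric diffusion (rank-2) and kurtosis (rank-4) tensor bookkeeping.

The diffusion tensor D is stored as its 6 unique components in the order
(xx, yy, zz, xy, xz, yz), units mm^2/s.  The kurtosis tensor W is fully
symmetric under any permutation of its four indices and is stored as its
15 unique components (dimensionless), ordered by the sorted index tuples
in :data:`W_INDEX_TUPLES`.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = [
    "D_INDEX_TUPLES",
    "W_INDEX_TUPLES",
    "D_MULTIPLICITY",
    "W_MULTIPLICITY",
    "d_from_vec",
    "d_to_vec",
    "w_from_vec",
    "w_to_vec",
    "apparent_diffusivity",
    "apparent_kurtosis",
    "w_projection",
    "tensor_metrics",
    "rotate_d",
    "rotate_w",
    "isotropic_w",
    "kurtosis_tensor_for_constant_k",
]

D_INDEX_TUPLES: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2),
)

# All sorted 4-index tuples over {0,1,2}: 15 unique components.
W_INDEX_TUPLES: tuple[tuple[int, int, int, int], ...] = tuple(
    sorted(
        {tuple(sorted((i, j, k, l)))
         for i in range(3) for j in range(3)
         for k in range(3) for l in range(3)}
    )
)


def _multiplicity(idx: tuple[int, ...]) -> int:
    counts = [idx.count(v) for v in set(idx)]
    m = factorial(len(idx))
    for c in counts:
        m //= factorial(c)
    return m


D_MULTIPLICITY = np.array([_multiplicity(t) for t in D_INDEX_TUPLES])
W_MULTIPLICITY = np.array([_multiplicity(t) for t in W_INDEX_TUPLES])


def d_from_vec(d6: np.ndarray) -> np.ndarray:
    """Expand the 6-vector (xx, yy, zz, xy, xz, yz) to a symmetric 3x3 matrix."""
    d6 = np.asarray(d6, dtype=float)
    if d6.shape != (6,):
        raise ValueError(f"expected 6 diffusion components, got shape {d6.shape}")
    xx, yy, zz, xy, xz, yz = d6
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def d_to_vec(d_mat: np.ndarray) -> np.ndarray:
    d_mat = np.asarray(d_mat, dtype=float)
    return np.array([d_mat[i, j] for i, j in D_INDEX_TUPLES])


def w_from_vec(w15: np.ndarray) -> np.ndarray:
    """Expand 15 unique components to the full symmetric 3x3x3x3 array."""
    w15 = np.asarray(w15, dtype=float)
    if w15.shape != (15,):
        raise ValueError(f"expected 15 kurtosis components, got shape {w15.shape}")
    full = np.zeros((3, 3, 3, 3))
    for value, idx in zip(w15, W_INDEX_TUPLES):
        i, j, k, l = idx
        # assign every permutation; repeated assignment is harmless
        for perm in {(i, j, k, l), (i, j, l, k), (i, k, j, l), (i, k, l, j),
                     (i, l, j, k), (i, l, k, j), (j, i, k, l), (j, i, l, k),
                     (j, k, i, l), (j, k, l, i), (j, l, i, k), (j, l, k, i),
                     (k, i, j, l), (k, i, l, j), (k, j, i, l), (k, j, l, i),
                     (k, l, i, j), (k, l, j, i), (l, i, j, k), (l, i, k, j),
                     (l, j, i, k), (l, j, k, i), (l, k, i, j), (l, k, j, i)}:
            full[perm] = value
    return full


def w_to_vec(w_full: np.ndarray) -> np.ndarray:
    w_full = np.asarray(w_full, dtype=float)
    return np.array([w_full[t] for t in W_INDEX_TUPLES])


def apparent_diffusivity(d_mat: np.ndarray, n: np.ndarray) -> float:
    """D(n) = n^T D n for a unit direction n (mm^2/s)."""
    n = np.asarray(n, dtype=float)
    return float(n @ np.asarray(d_mat, dtype=float) @ n)


def w_projection(w_full: np.ndarray, n: np.ndarray) -> float:
    """W(n) = sum_ijkl n_i n_j n_k n_l W_ijkl (dimensionless)."""
    n = np.asarray(n, dtype=float)
    return float(np.einsum("i,j,k,l,ijkl->", n, n, n, n, w_full))


def apparent_kurtosis(d_mat: np.ndarray, w_full: np.ndarray, n: np.ndarray) -> float:
    """Directional apparent kurtosis K(n) = (MD/D(n))^2 * W(n).

    Raises ``ValueError`` when the apparent diffusivity along ``n`` is not
    positive (the ratio is then undefined).
    """
    d_n = apparent_diffusivity(d_mat, n)
    if d_n <= 0:
        raise ValueError(f"apparent diffusivity along {n} is non-positive: {d_n}")
    md = float(np.trace(d_mat)) / 3.0
    return (md / d_n) ** 2 * w_projection(w_full, n)


def tensor_metrics(d_mat: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Return (MD, FA, eigenvalues sorted descending) of a symmetric tensor.

    MD = trace/3.  FA = sqrt(3/2) * ||lam - mean||  / ||lam||, defined as 0
    for the all-zero tensor.
    """
    d_mat = np.asarray(d_mat, dtype=float)
    scale = float(np.max(np.abs(d_mat))) or 1.0
    if not np.allclose(d_mat, d_mat.T, rtol=0.0, atol=1e-9 * scale):
        raise ValueError("diffusion tensor must be symmetric")
    lam = np.linalg.eigvalsh(d_mat)[::-1]
    md = float(lam.mean())
    denom = float(np.sqrt(np.sum(lam**2)))
    if denom == 0.0:
        return md, 0.0, lam
    fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2)) / denom)
    return md, min(fa, 1.0), lam


def rotate_d(d_mat: np.ndarray, rot: np.ndarray) -> np.ndarray:
    return rot @ d_mat @ rot.T


def rotate_w(w_full: np.ndarray, rot: np.ndarray) -> np.ndarray:
    return np.einsum("ai,bj,ck,dl,ijkl->abcd", rot, rot, rot, rot, w_full)


def isotropic_w(level: float) -> np.ndarray:
    """Fully symmetric isotropic kurtosis tensor with W(n) = level for all unit n."""
    eye = np.eye(3)
    sym = (np.einsum("ij,kl->ijkl", eye, eye)
           + np.einsum("ik,jl->ijkl", eye, eye)
           + np.einsum("il,jk->ijkl", eye, eye))
    return (level / 3.0) * sym


def kurtosis_tensor_for_constant_k(d_mat: np.ndarray, k: float) -> np.ndarray:
    """Kurtosis tensor giving apparent kurtosis K(n) = k along every direction.

    Built as k * sym(D (x) D) / MD^2; the symmetrized outer product contracts
    with n^(x)4 to D(n)^2, cancelling the (MD/D(n))^2 prefactor of K(n).
    """
    d_mat = np.asarray(d_mat, dtype=float)
    md = float(np.trace(d_mat)) / 3.0
    if md <= 0:
        raise ValueError("mean diffusivity must be positive")
    outer = (np.einsum("ij,kl->ijkl", d_mat, d_mat)
             + np.einsum("ik,jl->ijkl", d_mat, d_mat)
             + np.einsum("il,jk->ijkl", d_mat, d_mat)) / 3.0
    return k * outer / md**2
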