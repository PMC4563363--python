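"""Condition a raw similarity matrix into a valid kernel.

A similarity source (chemical-structure, ATC-taxonomy, or sequence-alignment
similarity) arrives as a square matrix that may be slightly asymmetric and is
not guaranteed positive semi-definite.  Kernel methods need a symmetric PSD
matrix, and the spectral filters downstream additionally want the spectrum
bounded by 1.  The pipeline is:

1. ``symmetrize``      S <- (S + S')/2
2. ``psd_shift``       S <- S + cI, c = |lambda_min| + eps when indefinite
3. ``normalize``       K <- D^{-1/2} S D^{-1/2},  D_ii = row sum of S

Degree normalization of a nonnegative matrix bounds the spectral radius by 1
(it is a congruence of the row-stochastic matrix D^{-1}S), which keeps the
label-propagation filter denominator strictly positive for every pair
eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SimilarityMatrix

DEFAULT_EPSILON = 1e-6
SYMMETRY_RTOL = 1e-10
# relative threshold below which a negative eigenvalue is round-off, not
# genuine indefiniteness; a PSD matrix must not be shifted because eigvalsh
# reported -1e-16
PSD_RTOL = 1e-12


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric PSD, degree-normalized, labeled kernel matrix."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"kernel shape {vals.shape} does not match {n} IDs")
        scale = max(np.abs(vals).max(), 1.0)
        if np.abs(vals - vals.T).max() > SYMMETRY_RTOL * scale:
            raise ValueError("kernel matrix is not symmetric")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.ids)


def symmetrize(S: SimilarityMatrix) -> SimilarityMatrix:
    """Replace S by (S + S')/2; exact fixed point on symmetric input."""
    sym = 0.5 * (S.values + S.values.T)
    # enforce bitwise symmetry despite float non-associativity
    sym = np.triu(sym) + np.triu(sym, 1).T
    return SimilarityMatrix(ids=S.ids, values=sym)


def psd_shift(S: SimilarityMatrix, epsilon: float = DEFAULT_EPSILON) -> SimilarityMatrix:
    """Shift an indefinite symmetric matrix onto the PSD cone.

    Adds ``(|lambda_min| + epsilon) I`` when the minimum eigenvalue is
    materially negative; an already-PSD matrix (up to eigensolver round-off)
    is returned unchanged, which makes the operation idempotent.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    vals = S.values
    scale = max(np.abs(vals).max(), 1.0)
    if np.abs(vals - vals.T).max() > SYMMETRY_RTOL * scale:
        raise ValueError("psd_shift requires a symmetric matrix; symmetrize first")
    lam_min = float(np.linalg.eigvalsh(vals)[0])
    if lam_min >= -PSD_RTOL * scale:
        return S
    return SimilarityMatrix(ids=S.ids, values=vals + (-lam_min + epsilon) * np.eye(S.n))


def normalize(S: SimilarityMatrix) -> KernelMatrix:
    """Degree-normalize: K_ij = S_ij / sqrt(rowsum_i * rowsum_j).

    Requires strictly positive row sums; a nonpositive row sum indicates a
    disconnected or invalid similarity source and is reported by entity ID.
    """
    row_sums = S.values.sum(axis=1)
    bad = np.nonzero(row_sums <= 0)[0]
    if bad.size:
        names = [S.ids[i] for i in bad[:10]]
        raise ValueError(f"nonpositive row sum for entities: {names}")
    d = 1.0 / np.sqrt(row_sums)
    K = S.values * np.outer(d, d)
    K = 0.5 * (K + K.T)
    return KernelMatrix(ids=S.ids, values=K)


def prepare_kernel(S: SimilarityMatrix,
                   epsilon: float = DEFAULT_EPSILON) -> KernelMatrix:
    """Full conditioning pipeline: symmetrize, PSD-shift, degree-normalize."""
    return normalize(psd_shift(symmetrize(S), epsilon))
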