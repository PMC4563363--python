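"""Eigendecomposition, the extended matrix power, and spectral filters.

The central object is the extended kernel power ``K^alpha = V U^alpha V'``
for real alpha >= 0, defined through the symmetric eigendecomposition
``K = V U V'``.  For integer alpha it coincides with the ordinary matrix
power; for fractional alpha it rescales the kernel's eigenvalue profile while
keeping the eigenvectors, which is exactly the eigenvalue transformation the
predictors apply.  Every closed-form predictor is a spectral filter: a scalar
function of the (pair-)kernel eigenvalues applied as a diagonal in the
eigenbasis.

Convention: ``0**alpha := 0`` for *all* alpha >= 0, including alpha = 0.  The
tuning grid contains alpha = 0 and the kernel's null space must stay null, so
entities with zero similarity mass never acquire score mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import InteractionMatrix, ScoreMatrix
from .kernel_prep import KernelMatrix

DEFAULT_CLIP_TOL = 1e-8


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenpairs of a kernel: descending nonnegative eigenvalues, orthonormal V."""

    ids: tuple[str, ...]
    eigenvalues: np.ndarray  # shape (n,), descending, >= 0
    eigenvectors: np.ndarray  # shape (n, n), column i pairs with eigenvalues[i]

    @property
    def n(self) -> int:
        return len(self.ids)

    def reconstruct(self) -> np.ndarray:
        V = self.eigenvectors
        return (V * self.eigenvalues) @ V.T


@dataclass(frozen=True)
class SpectralFilter:
    """Scalar eigenvalue map of one predictor family.

    family='rls'   lambda -> lambda^alpha / (lambda^alpha + sigma)
    family='slp'   lambda -> 1 / (1 + sigma (1 - lambda^alpha))
    family='power' lambda -> lambda^alpha
    """

    family: str
    alpha: float
    sigma: float = 1.0

    def __post_init__(self):
        if self.family not in ("rls", "slp", "power"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def decompose(K: KernelMatrix, clip_tol: float = DEFAULT_CLIP_TOL) -> SpectralDecomposition:
    """Symmetric eigendecomposition with round-off clipping.

    Eigenvalues in ``[-clip_tol * lambda_max, 0)`` are clipped to zero;
    anything more negative means the matrix was never properly conditioned
    and raises instead of being silently patched.
    """
    lam, V = np.linalg.eigh(K.values)
    lam_max = max(float(lam[-1]), 0.0)
    floor = -clip_tol * max(lam_max, 1e-300)
    if lam[0] < floor:
        raise ValueError(
            f"kernel is materially indefinite (lambda_min={lam[0]:.3e}); "
            "run kernel conditioning first"
        )
    lam = np.clip(lam, 0.0, None)
    order = np.argsort(lam)[::-1]  # descending
    return SpectralDecomposition(
        ids=K.ids, eigenvalues=lam[order], eigenvectors=V[:, order]
    )


def apply_power(lam, alpha: float):
    """Elementwise lambda^alpha with the convention 0^alpha := 0 for alpha >= 0."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    lam = np.asarray(lam, dtype=float)
    if (lam < 0).any():
        raise ValueError("eigenvalues must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lam > 0, lam ** alpha, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def matrix_power_ext(decomp: SpectralDecomposition, alpha: float) -> KernelMatrix:
    """Extended matrix power K^alpha = V diag(lambda^alpha) V'."""
    lam_a = apply_power(decomp.eigenvalues, alpha)
    V = decomp.eigenvectors
    M = (V * lam_a) @ V.T
    M = 0.5 * (M + M.T)
    return KernelMatrix(ids=decomp.ids, values=M)


def filter_values(filt: SpectralFilter, lam) -> np.ndarray:
    """Apply a filter family's eigenvalue map elementwise."""
    lam = np.asarray(lam, dtype=float)
    lam_a = apply_power(lam, filt.alpha)
    if filt.family == "power":
        return lam_a
    if filt.family == "rls":
        return lam_a / (lam_a + filt.sigma)
    denom = 1.0 + filt.sigma * (1.0 - lam_a)
    if (denom <= 0).any():
        raise ValueError(
            "label-propagation filter denominator <= 0; the kernel spectrum "
            "must lie in [0, 1] (degree-normalize the kernel first)"
        )
    return 1.0 / denom


def weight_profile(
    drug_eigen: SpectralDecomposition,
    target_eigen: SpectralDecomposition,
    Y: InteractionMatrix,
    filt: SpectralFilter,
    combine: str = "product",
) -> pd.DataFrame:
    """Spectral diagnostic: how each pair eigendirection contributes to scores.

    The prediction is the weighted sum ``sum_i w_i (v_i' vec(Y)) v_i`` over
    pair-kernel eigendirections; this tabulates, per direction, the pair
    eigenvalue, filter weight w_i, projection coefficient of the label matrix,
    and the contribution magnitude ``|w_i * projection|``.  The pair
    eigenvectors are Kronecker products of factor columns, so the projections
    are the entries of ``V_d' Y V_t`` and the big pair matrix never needs to
    be formed.
    """
    if drug_eigen.n != Y.n_drugs or target_eigen.n != Y.n_targets:
        raise ValueError("decomposition dimensions do not match interaction matrix")
    lam_d = drug_eigen.eigenvalues
    lam_t = target_eigen.eigenvalues
    if combine == "product":
        mu = np.outer(lam_d, lam_t)
    elif combine == "half_sum":
        mu = 0.5 * np.add.outer(lam_d, lam_t)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    W = filter_values(filt, mu.ravel()).reshape(mu.shape)
    C = drug_eigen.eigenvectors.T @ Y.values @ target_eigen.eigenvectors
    df = pd.DataFrame(
        {
            "lambda": mu.ravel(),
            "weight": W.ravel(),
            "projection": C.ravel(),
            "contribution_norm": np.abs(W.ravel() * C.ravel()),
        }
    )
    return df.sort_values("lambda", ascending=False, kind="stable").reset_index(
        drop=True
    )


def write_weight_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.15g")


def normalized_score(scores: ScoreMatrix) -> ScoreMatrix:
    """Scale scores to unit Euclidean norm of the flattened matrix.

    A positive rescaling preserves every ranking-based metric; the normalized
    form is only needed to compare weight profiles across exponents.
    """
    norm = float(np.linalg.norm(scores.values))
    if norm == 0:
        raise ValueError("cannot normalize an all-zero score matrix")
    return ScoreMatrix(
        drug_ids=scores.drug_ids,
        target_ids=scores.target_ids,
        values=scores.values / norm,
    )
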