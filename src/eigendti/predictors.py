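"""Closed-form link predictors on the drug x target pair space.

Two algorithm families, each a linear spectral smoother of the label matrix:

* **RLS** (regularized least squares): ``vec(F) = K (K + sigma I)^-1 vec(Y)``
  on the pair kernel K, i.e. eigenvalue weight ``lambda / (lambda + sigma)``.
* **SLP** (semi-supervised link propagation): ``vec(F) = (I + sigma L)^-1
  vec(Y)`` with pair Laplacian ``L = I - K``, i.e. weight
  ``1 / (1 + sigma (1 - lambda))``.

The eigenvalue transformation replaces each pair eigenvalue ``mu`` by
``mu^alpha`` before filtering; ``alpha = 1`` recovers the original algorithm
exactly.  Three pair-kernel variants share the factor eigenbases:

* ``kp`` — Kronecker product, pair eigenvalue ``mu_ab = lam_d,a * lam_t,b``;
* ``ks`` — half Kronecker sum, ``mu_ab = (lam_d,a + lam_t,b) / 2`` (the half
  keeps the pair spectrum in [0, 1] like the product's);
* ``avg`` — mean of the drug-side smoother (pair kernel ``K_d (x) I``, acting
  on rows of Y) and the target-side smoother (``I (x) K_t``, on columns).

Because pair eigenvectors are Kronecker products of factor eigenvectors, the
efficient path works entirely with ``V_d' Y V_t`` and never materializes an
``(n_d n_t)^2`` matrix.  ``naive_predict`` deliberately does materialize it
(dense Kronecker assembly plus a Cholesky solve) and serves as the testing
oracle; ``untransformed_predict`` is a third, power-free code path for the
``alpha = 1`` reduction check.

vec convention: row-major (drug-major), so ``kron(K_d, K_t) vec(Y)`` equals
``vec(K_d Y K_t')``; all constructions here use that convention consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data_io import InteractionMatrix, ScoreMatrix
from .kernel_prep import KernelMatrix
from .spectral import (
    SpectralDecomposition,
    SpectralFilter,
    decompose,
    filter_values,
    matrix_power_ext,
)

RLS_SIGMA_DEFAULT = 0.05
SLP_SIGMA_DEFAULT = 0.01

NAIVE_PAIR_LIMIT = 5000

_ALGORITHMS = ("rls", "slp")
_VARIANTS = ("kp", "ks", "avg")


def default_sigma(algorithm: str) -> float:
    return RLS_SIGMA_DEFAULT if algorithm == "rls" else SLP_SIGMA_DEFAULT


@dataclass(frozen=True)
class PredictorSpec:
    """Algorithm family, pair-kernel variant, exponent and regularization."""

    algorithm: str
    variant: str
    alpha: float = 1.0
    sigma: float | None = None

    def __post_init__(self):
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma is None:
            object.__setattr__(self, "sigma", default_sigma(self.algorithm))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def with_alpha(self, alpha: float) -> "PredictorSpec":
        return PredictorSpec(self.algorithm, self.variant, alpha, self.sigma)

    @property
    def filter(self) -> SpectralFilter:
        return SpectralFilter(family=self.algorithm, alpha=self.alpha,
                              sigma=self.sigma)

    @property
    def name(self) -> str:
        return f"{self.algorithm}-{self.variant}"


@dataclass(frozen=True)
class PairSpectrum:
    """Factor eigendecompositions plus the rule combining their eigenvalues."""

    drug_eigen: SpectralDecomposition
    target_eigen: SpectralDecomposition
    combine: str  # 'product' (KP) or 'half_sum' (KS)

    def pair_eigenvalues(self) -> np.ndarray:
        lam_d = self.drug_eigen.eigenvalues
        lam_t = self.target_eigen.eigenvalues
        if self.combine == "product":
            return np.outer(lam_d, lam_t)
        if self.combine == "half_sum":
            return 0.5 * np.add.outer(lam_d, lam_t)
        raise ValueError(f"unknown combine rule {self.combine!r}")


def _check_alignment(spec: PredictorSpec, K_d: KernelMatrix, K_t: KernelMatrix,
                     Y: InteractionMatrix) -> None:
    if K_d.ids != Y.drug_ids:
        raise ValueError("drug kernel IDs do not match interaction drug IDs")
    if K_t.ids != Y.target_ids:
        raise ValueError("target kernel IDs do not match interaction target IDs")


def predict(
    spec: PredictorSpec,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y: InteractionMatrix,
    *,
    drug_eigen: SpectralDecomposition | None = None,
    target_eigen: SpectralDecomposition | None = None,
) -> ScoreMatrix:
    """Factorized closed-form prediction.

    Pass precomputed ``drug_eigen`` / ``target_eigen`` to amortize the factor
    eigendecompositions across many (alpha, Y) evaluations, as the
    cross-validation harness does.
    """
    _check_alignment(spec, K_d, K_t, Y)
    if drug_eigen is None:
        drug_eigen = decompose(K_d)
    if target_eigen is None:
        target_eigen = decompose(K_t)
    F = _predict_values(spec, drug_eigen, target_eigen, Y.values)
    return ScoreMatrix(drug_ids=Y.drug_ids, target_ids=Y.target_ids, values=F)


def _predict_values(
    spec: PredictorSpec,
    drug_eigen: SpectralDecomposition,
    target_eigen: SpectralDecomposition,
    Y: np.ndarray,
) -> np.ndarray:
    filt = spec.filter
    V_d = drug_eigen.eigenvectors
    V_t = target_eigen.eigenvectors
    if spec.variant in ("kp", "ks"):
        combine = "product" if spec.variant == "kp" else "half_sum"
        pair = PairSpectrum(drug_eigen, target_eigen, combine)
        mu = pair.pair_eigenvalues()
        H = filter_values(filt, mu.ravel()).reshape(mu.shape)
        C = V_d.T @ Y @ V_t
        return V_d @ (H * C) @ V_t.T
    # avg: mean of the two single-side smoothers
    g_d = filter_values(filt, drug_eigen.eigenvalues)
    g_t = filter_values(filt, target_eigen.eigenvalues)
    F_drug = (V_d * g_d) @ (V_d.T @ Y)
    F_target = (Y @ V_t) * g_t @ V_t.T
    return 0.5 * (F_drug + F_target)


# ---------------------------------------------------------------------------
# dense oracle paths


def _pair_ids(Y: InteractionMatrix) -> tuple[str, ...]:
    return tuple(f"{d}|{t}" for d in Y.drug_ids for t in Y.target_ids)


def _pair_kernels(variant: str, K_d: np.ndarray, K_t: np.ndarray) -> list[np.ndarray]:
    """Dense pair kernel(s) for a variant; avg returns both single sides."""
    n_d, n_t = K_d.shape[0], K_t.shape[0]
    if variant == "kp":
        return [np.kron(K_d, K_t)]
    if variant == "ks":
        return [0.5 * (np.kron(K_d, np.eye(n_t)) + np.kron(np.eye(n_d), K_t))]
    return [np.kron(K_d, np.eye(n_t)), np.kron(np.eye(n_d), K_t)]


def _dense_solve(algorithm: str, K_pair: np.ndarray, y: np.ndarray,
                 sigma: float) -> np.ndarray:
    n = K_pair.shape[0]
    if algorithm == "rls":
        A = K_pair + sigma * np.eye(n)
        c, low = scipy.linalg.cho_factor(A)
        return K_pair @ scipy.linalg.cho_solve((c, low), y)
    L = np.eye(n) - K_pair
    A = np.eye(n) + sigma * L
    # I + sigma*L can be semidefinite-borderline only if an eigenvalue of
    # K_pair exceeds 1 + 1/sigma, impossible for normalized kernels
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), y)


def naive_predict(
    spec: PredictorSpec,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y: InteractionMatrix,
    *,
    apply_transform: bool = True,
) -> ScoreMatrix:
    """Dense testing oracle: explicit pair kernel, explicit linear solve.

    Builds the Kronecker pair kernel(s), raises them to ``alpha`` via the
    extended matrix power of the full pair matrix, and solves the predictor's
    linear system directly.  Guarded to small problems.
    """
    _check_alignment(spec, K_d, K_t, Y)
    n_pair = Y.n_drugs * Y.n_targets
    if n_pair > NAIVE_PAIR_LIMIT:
        raise ValueError(
            f"naive oracle limited to {NAIVE_PAIR_LIMIT} pairs; got {n_pair}"
        )
    pair_ids = _pair_ids(Y)
    y = Y.values.ravel()  # row-major matches kron(K_d, K_t)
    outs = []
    for K_pair in _pair_kernels(spec.variant, K_d.values, K_t.values):
        if apply_transform:
            km = KernelMatrix(ids=pair_ids, values=0.5 * (K_pair + K_pair.T))
            K_pair = matrix_power_ext(decompose(km), spec.alpha).values
        outs.append(_dense_solve(spec.algorithm, K_pair, y, spec.sigma))
    f = np.mean(outs, axis=0)
    return ScoreMatrix(
        drug_ids=Y.drug_ids,
        target_ids=Y.target_ids,
        values=f.reshape(Y.n_drugs, Y.n_targets),
    )


def untransformed_predict(
    algorithm: str,
    variant: str,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y: InteractionMatrix,
    sigma: float | None = None,
) -> ScoreMatrix:
    """Original (no eigenvalue transformation) predictor, dense and power-free.

    A separately coded reference for the alpha = 1 reduction: it never touches
    an eigendecomposition, so agreement with ``predict(alpha=1)`` is a real
    cross-check rather than a tautology.
    """
    spec = PredictorSpec(algorithm, variant, alpha=1.0, sigma=sigma)
    _check_alignment(spec, K_d, K_t, Y)
    n_pair = Y.n_drugs * Y.n_targets
    if n_pair > NAIVE_PAIR_LIMIT:
        raise ValueError(
            f"dense reference limited to {NAIVE_PAIR_LIMIT} pairs; got {n_pair}"
        )
    y = Y.values.ravel()
    outs = [
        _dense_solve(algorithm, K_pair, y, spec.sigma)
        for K_pair in _pair_kernels(variant, K_d.values, K_t.values)
    ]
    f = np.mean(outs, axis=0)
    return ScoreMatrix(
        drug_ids=Y.drug_ids,
        target_ids=Y.target_ids,
        values=f.reshape(Y.n_drugs, Y.n_targets),
    )


# ---------------------------------------------------------------------------
# training objective at the closed-form optimum


def _objective_from_spectrum(algorithm: str, mu_alpha: np.ndarray,
                             c: np.ndarray, sigma: float) -> float:
    """Optimal objective value from pair eigenvalues and label projections.

    RLS: min_c ||y - K c||^2 + sigma c' K c  =  sum sigma c_i^2 / (mu_i + sigma)
    SLP: min_f ||f - y||^2 + sigma f' L f    =  sum sigma l_i c_i^2 / (1 + sigma l_i)
    with l_i = 1 - mu_i, both evaluated at the transformed eigenvalue
    mu_i = (pair eigenvalue)^alpha.
    """
    c2 = c ** 2
    if algorithm == "rls":
        return float(np.sum(sigma * c2 / (mu_alpha + sigma)))
    ell = 1.0 - mu_alpha
    return float(np.sum(sigma * ell * c2 / (1.0 + sigma * ell)))


def training_objective(
    spec: PredictorSpec,
    K_d: KernelMatrix,
    K_t: KernelMatrix,
    Y: InteractionMatrix,
    *,
    drug_eigen: SpectralDecomposition | None = None,
    target_eigen: SpectralDecomposition | None = None,
) -> float:
    """Value of the algorithm's objective at its closed-form optimum.

    For kernels with spectrum in [0, 1] this is minimized over alpha at
    alpha = 0 (where every positive transformed eigenvalue saturates at 1),
    which is why alpha cannot be tuned on the training objective alone.
    For the avg variant the reported value is the mean of the two single-side
    objectives.
    """
    _check_alignment(spec, K_d, K_t, Y)
    if drug_eigen is None:
        drug_eigen = decompose(K_d)
    if target_eigen is None:
        target_eigen = decompose(K_t)
    from .spectral import apply_power

    C = drug_eigen.eigenvectors.T @ Y.values @ target_eigen.eigenvectors
    if spec.variant in ("kp", "ks"):
        combine = "product" if spec.variant == "kp" else "half_sum"
        mu = PairSpectrum(drug_eigen, target_eigen, combine).pair_eigenvalues()
        mu_a = apply_power(mu.ravel(), spec.alpha)
        return _objective_from_spectrum(spec.algorithm, mu_a, C.ravel(), spec.sigma)
    lam_d_a = apply_power(drug_eigen.eigenvalues, spec.alpha)
    lam_t_a = apply_power(target_eigen.eigenvalues, spec.alpha)
    mu_drug = np.repeat(lam_d_a, target_eigen.n)
    mu_target = np.tile(lam_t_a, drug_eigen.n)
    j_d = _objective_from_spectrum(spec.algorithm, mu_drug, C.ravel(), spec.sigma)
    j_t = _objective_from_spectrum(spec.algorithm, mu_target, C.ravel(), spec.sigma)
    return 0.5 * (j_d + j_t)
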