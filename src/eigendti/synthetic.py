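"""Synthetic similarity matrices and interaction networks.

The generator encodes the modeling premise that similar drugs tend to hit
similar targets.  Drugs and targets get latent feature vectors; similarity is
a squared-exponential decay of latent distance (positive definite by
construction, entries in (0, 1], so kernel conditioning needs no PSD shift
and spectral effects are not confounded with conditioning effects); the true
interaction propensity is a bilinear form of the latent features; the binary
network thresholds that propensity at the quantile giving the requested
density and then flips labels symmetrically with a small probability.

Everything is a pure function of the config, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import InteractionMatrix, ScoreMatrix, SimilarityMatrix


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    gamma is the similarity length-scale: with standard-normal latent vectors
    the mean squared distance between two entities is ``2 * latent_dim``, so
    the default ``gamma = 1 / (2 * latent_dim)`` puts typical similarities
    near exp(-1) ~ 0.37 — informative but far from saturated.
    """

    n_d: int = 60
    n_t: int = 60
    latent_dim: int = 4
    gamma: float | None = None
    density: float = 0.08
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_d < 2 or self.n_t < 2:
            raise ValueError("need at least 2 drugs and 2 targets")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.gamma is None:
            object.__setattr__(self, "gamma", 1.0 / (2.0 * self.latent_dim))
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def _rbf_similarity(X: np.ndarray, gamma: float, prefix: str) -> SimilarityMatrix:
    D2 = cdist(X, X, metric="sqeuclidean")
    S = np.exp(-gamma * D2)
    S = 0.5 * (S + S.T)
    ids = tuple(f"{prefix}{i + 1:03d}" for i in range(X.shape[0]))
    return SimilarityMatrix(ids=ids, values=S)


def simulate(
    config: SimConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix, InteractionMatrix, ScoreMatrix]:
    """Draw (S_d, S_t, Y, F_true) from the latent-feature model."""
    rng = np.random.default_rng(config.seed)
    X_d = rng.standard_normal((config.n_d, config.latent_dim))
    X_t = rng.standard_normal((config.n_t, config.latent_dim))
    S_d = _rbf_similarity(X_d, config.gamma, "D")
    S_t = _rbf_similarity(X_t, config.gamma, "T")

    W = rng.standard_normal((config.latent_dim, config.latent_dim))
    F = X_d @ W @ X_t.T
    F_true = ScoreMatrix(drug_ids=S_d.ids, target_ids=S_t.ids, values=F)

    threshold = np.quantile(F, 1.0 - config.density)
    Y_vals = (F > threshold).astype(float)
    if config.label_noise > 0:
        flips = rng.random(Y_vals.shape) < config.label_noise
        Y_vals = np.where(flips, 1.0 - Y_vals, Y_vals)
    Y = InteractionMatrix(drug_ids=S_d.ids, target_ids=S_t.ids, values=Y_vals)
    return S_d, S_t, Y, F_true


def permute_interactions(Y: InteractionMatrix, seed: int) -> InteractionMatrix:
    """Shuffle the adjacency entries over all pairs, destroying any
    association with the similarity structure while keeping the density."""
    rng = np.random.default_rng(seed)
    flat = rng.permutation(Y.values.ravel())
    return InteractionMatrix(
        drug_ids=Y.drug_ids,
        target_ids=Y.target_ids,
        values=flat.reshape(Y.values.shape),
    )


_WORKED_2X2 = (
    SimilarityMatrix(("d1", "d2"), np.array([[1.0, 0.5], [0.5, 1.0]])),
    SimilarityMatrix(("t1", "t2"), np.array([[1.0, 0.5], [0.5, 1.0]])),
    InteractionMatrix(("d1", "d2"), ("t1", "t2"), np.array([[1.0, 0.0], [0.0, 0.0]])),
)

_WORKED_3X2 = (
    SimilarityMatrix(
        ("d1", "d2", "d3"),
        np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]]),
    ),
    SimilarityMatrix(("t1", "t2"), np.array([[1.0, 0.3], [0.3, 1.0]])),
    InteractionMatrix(
        ("d1", "d2", "d3"),
        ("t1", "t2"),
        np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
    ),
)

_FIXTURES = {"worked_2x2": _WORKED_2X2, "worked_3x2": _WORKED_3X2}


def toy_fixture(
    name: str,
) -> tuple[SimilarityMatrix, SimilarityMatrix, InteractionMatrix]:
    """Hard-coded small instances for worked examples and oracle tests.

    Both fixtures' similarity matrices are already symmetric positive
    definite, so kernel conditioning reduces to degree normalization alone.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_FIXTURES)}")
    S_d, S_t, Y = _FIXTURES[name]
    # return copies so callers cannot mutate the module-level fixtures
    return (
        SimilarityMatrix(S_d.ids, S_d.values.copy()),
        SimilarityMatrix(S_t.ids, S_t.values.copy()),
        InteractionMatrix(Y.drug_ids, Y.target_ids, Y.values.copy()),
    )
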