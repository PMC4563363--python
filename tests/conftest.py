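import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eigendti import (
    InteractionMatrix,
    SimilarityMatrix,
    prepare_kernel,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_similarity(n: int, rng: np.random.Generator,
                    prefix: str = "e") -> SimilarityMatrix:
    """Random asymmetric nonnegative similarity with unit diagonal."""
    A = rng.random((n, n))
    np.fill_diagonal(A, 1.0)
    ids = tuple(f"{prefix}{i}" for i in range(n))
    return SimilarityMatrix(ids=ids, values=A)


def make_kernel(n: int, rng: np.random.Generator, prefix: str = "e"):
    """Conditioned kernel from a random similarity (spectrum in [0, 1])."""
    return prepare_kernel(make_similarity(n, rng, prefix))


def make_instance(n_d: int, n_t: int, rng: np.random.Generator,
                  density: float = 0.4):
    """Random (K_d, K_t, Y) with both classes guaranteed present in Y."""
    K_d = make_kernel(n_d, rng, "d")
    K_t = make_kernel(n_t, rng, "t")
    while True:
        Y_vals = (rng.random((n_d, n_t)) < density).astype(float)
        if 0 < Y_vals.sum() < Y_vals.size:
            break
    Y = InteractionMatrix(K_d.ids, K_t.ids, Y_vals)
    return K_d, K_t, Y


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
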