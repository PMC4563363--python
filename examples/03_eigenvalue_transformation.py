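"""The eigenvalue transformation and how the exponent reshapes predictions.

Raising a kernel to a real power alpha rescales its eigenvalue profile while
keeping eigenvectors.  In the predictors this reweights how much each pair
eigendirection contributes to the scores: alpha > 1 concentrates mass on the
leading directions, alpha < 1 spreads it toward the tail.
"""

import numpy as np

from eigendti import (
    PredictorSpec,
    decompose,
    matrix_power_ext,
    prepare_kernel,
    toy_fixture,
    weight_profile,
)

S_d, S_t, Y = toy_fixture("worked_2x2")
K_d, K_t = prepare_kernel(S_d), prepare_kernel(S_t)
d_d, d_t = decompose(K_d), decompose(K_t)

print("drug kernel eigenvalues:", np.round(d_d.eigenvalues, 4))
half = matrix_power_ext(d_d, 0.5)
print("K^0.5 eigenvalues:      ",
      np.round(np.linalg.eigvalsh(half.values)[::-1], 4),
      "(square roots, same eigenvectors)")
print("K^2 equals K@K:",
      np.allclose(matrix_power_ext(d_d, 2.0).values, K_d.values @ K_d.values))

print("\nRLS filter weight per pair eigendirection (weight = mu^a/(mu^a+sigma)):")
print(f"{'mu':>8} {'a=0.3':>8} {'a=1.0':>8} {'a=2.0':>8}")
mus = np.outer(d_d.eigenvalues, d_t.eigenvalues).ravel()
from eigendti import SpectralFilter, filter_values

rows = {a: filter_values(SpectralFilter("rls", a, 0.05), mus) for a in (0.3, 1.0, 2.0)}
for k in np.argsort(-mus):
    print(f"{mus[k]:8.4f} {rows[0.3][k]:8.4f} {rows[1.0][k]:8.4f} {rows[2.0][k]:8.4f}")
# Small eigenvalues keep much more weight at alpha=0.3 than at alpha=2:
# the exponent is a knob on how aggressively the kernel's tail is damped.

spec = PredictorSpec("rls", "kp", alpha=0.3)
prof = weight_profile(d_d, d_t, Y, spec.filter)
print("\nweight profile at alpha=0.3 (lambda, weight, label projection, |contribution|):")
print(prof.round(4).to_string(index=False))
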