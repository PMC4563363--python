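# Methods

## Model and assumptions

The package predicts links in a bipartite drug–target network from two
similarity sources. Both predictors are linear spectral smoothers of the
label matrix: writing the pair kernel's eigendecomposition K = V U Vᵀ, the
score vector is `vec(F̂) = V g(U) Vᵀ vec(Y)` with a scalar filter g applied
to the eigenvalues,

* RLS: g(λ) = λ/(λ+σ) — shrinkage of each eigendirection toward zero,
  strongest on the small eigenvalues;
* SLP: g(λ) = 1/(1+σ(1−λ)) — Laplacian label propagation; the direction with
  λ = 1 (the stationary direction of the normalized kernel) passes through
  unchanged.

The eigenvalue transformation substitutes λ^α for λ inside g. Since the
pair-kernel spectrum lies in [0, 1] after conditioning, α acts as a
contrast knob on the eigenvalue profile: α > 1 suppresses the tail, α < 1
flattens the profile toward uniform weighting. α = 1 is exactly the original
algorithm; that reduction is asserted in tests against a separately coded,
eigendecomposition-free dense solver.

Model assumptions: interactions are exchangeable given the kernels (no
cold-start handling — an entity present in the kernels but without known
interactions simply gets an all-zero label row and is still scored); the
label matrix is treated as complete, with 0 meaning "unknown", which is why
evaluation masks both known and unknown pairs symmetrically.

## Pair-kernel variants

Only factor decompositions are ever computed. The Kronecker-product variant
(`kp`) uses pair eigenvalues λ_d·λ_t. The Kronecker-sum variant (`ks`) uses
(λ_d+λ_t)/2; the ½ is a deliberate normalization so the KS spectrum also
lives in [0, 1], keeping one filter domain for both variants and keeping the
SLP denominator 1+σ(1−μ^α) strictly positive. The `avg` variant averages the
two single-side predictions (drug-side smoother K_d⊗I acting on rows of Y,
target-side I⊗K_t acting on columns) rather than averaging kernels —
averaging predictions keeps each side's filter exact and is the construction
used in the kernel DTI literature this family of methods comes from. Both
choices are isolated behind `PairSpectrum` and can be swapped without
touching solvers.

vec-ordering is row-major (drug-major) throughout, matching
`kron(K_d, K_t) vec(Y) = vec(K_d Y K_tᵀ)`; the convention is internal and
invisible at the API.

## Kernel conditioning

`prepare_kernel` = degree-normalize ∘ PSD-shift ∘ symmetrize, in that order
(row sums are taken on the *shifted* matrix). The shift adds
(|λ_min| + ε)·I with ε = 10⁻⁶ — the smallest identity multiple guaranteeing
PSD with a numerical margin. Two numerical guards matter:

* the shift triggers only when λ_min < −10⁻¹²·‖S‖_max: an eigensolver
  reporting −10⁻¹⁶ for a genuinely PSD matrix must not provoke a 10⁻⁶ shift,
  which would otherwise dominate the near-zero part of the spectrum after
  fractional powering;
* at decomposition time, eigenvalues in [−clip_tol·λ_max, 0) with
  clip_tol = 10⁻⁸ are clipped to 0 (λ^α needs λ ≥ 0); anything more negative
  raises, since it means conditioning was skipped.

Zero or negative row sums are an error naming the entity: they indicate a
disconnected or invalid similarity source, and silently patching them would
hide upstream data problems.

`0^α := 0` for all α ≥ 0, including α = 0. The tuning grid contains α = 0,
and the kernel's null space must stay null there: entities with zero
similarity mass should never receive score mass, and the filter stays
continuous in λ on the closed grid.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| σ (RLS) | 0.05 | regularization; fixed, not tuned |
| σ (SLP) | 0.01 | regularization; fixed, not tuned |
| α grid | 0, 0.1, …, 2 | candidate exponents (21 values, endpoints included) |
| w₁, w₂ | 0.5, 0.5 | Q = w₁·AUC + w₂·AUPR; constraint w₂ ≥ w₁ enforced |
| folds | 10 outer, 10 inner | pair-level, stratified by label |
| n_boot | 1000 | bootstrap replicates per fold |
| ε (shift) | 10⁻⁶ | identity-shift margin |
| clip_tol | 10⁻⁸ | relative eigenvalue clipping threshold |

σ is deliberately fixed in a non-informative way; tuning it jointly with α
would confound the two regularizers. AUPR is weighted at least as much as
AUC because true interactions are rare, making precision–recall the more
informative curve; the symmetric default is the least-committed admissible
choice.

The training objective at the closed-form optimum is available
(`training_objective`; RLS: Σ σc²/(μ^α+σ), SLP: Σ σ(1−μ^α)c²/(1+σ(1−μ^α)),
with c the label projections) chiefly to demonstrate *why* α must be tuned
by validation: with spectra in [0, 1] the objective is minimized at α = 0
for every instance, where the model memorizes the training labels.

Grid-search ties break toward the α closest to 1, then the smaller α, so "no
measurable improvement" collapses gracefully onto the original algorithm.

## Evaluation design

AUC is the rank-based (Mann–Whitney) statistic with ties counted one half;
AUPR is average precision (the step-curve sum), not trapezoidal
interpolation, which overestimates PR area. Both are delegated to
scikit-learn and locked against hand-coded pair-counting and step-sum
oracles in the test suite.

The bootstrap p-value is the add-one estimator
p = (1 + #{Q_a ≤ Q_b})/(n_boot+1) for the one-sided comparison
tuned-vs-original, replicates drawn by resampling test pairs with
replacement; single-class replicates are redrawn. The inner CV re-applies
the same stratified pair masking as the outer loop, so inner models train on
~81 % of known pairs (0.9²).

All randomness (folds, per-fold inner-CV seeds, bootstrap) derives from one
user seed through named `SeedSequence` substreams; reports are reproducible
bit-for-bit.

## Synthetic data

The generator draws latent vectors x ∈ ℝ^latent_dim (standard normal) per
drug and target, builds similarities exp(−γ‖x−x′‖²) — positive definite by
construction, so conditioning applies *no* shift and spectral effects are not
confounded with conditioning artifacts — and a true interaction propensity
X_d W X_tᵀ with a random mixing matrix W. Labels threshold the propensity at
the quantile matching the requested density, then flip with probability
`label_noise` in both directions (the simplest symmetric misspecification).
Default γ = 1/(2·latent_dim): the mean squared latent distance is
2·latent_dim, so typical similarities sit near e⁻¹ ≈ 0.37, informative but
not saturated.

What it does *not* emulate: the heavy-tailed degree distributions of real
interaction databases, block structure from target families, missing-not-at-
random annotation bias, or similarity matrices that disagree with each other.
Passing tests on this generator therefore demonstrate correctness of the
machinery and recoverability of smooth bilinear signal — not performance on
any real pharmacological dataset.

Standard study conditions used by the acceptance script and the headline
recovery test: 60 drugs × 60 targets, latent_dim 4, density 0.08, label
noise 0.05. Problem sizes throughout the suite (n ≤ 60 factors, ≤ 3600
pairs) were chosen so the full double-CV grid runs in seconds while leaving
the factorized solver's complexity regime (factor eigendecomposition plus
per-α dense products) representative of larger inputs.

## Known limitations

* Full symmetric eigendecomposition of each factor kernel: fine to a few
  thousand entities per axis, no iterative or randomized solvers.
* Pair-level CV only; no leave-one-drug-out / cold-start schemes.
* The KS scaling and the `avg` construction are documented package choices
  among several admissible readings of the algorithm family (see
  Pair-kernel variants above).
* `naive_predict` is guarded to 5000 pairs; it exists as an oracle, not a
  production path.
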