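"""Score unknown drug-target pairs and rank candidate new interactions.

Uses the small worked fixture: three drugs, two targets, two known
interactions.  The predictor propagates the known links through the drug and
target kernels; the highest-scoring zero cells are the candidate discoveries.
"""

from eigendti import (
    PredictorSpec,
    predict,
    prepare_kernel,
    rank_new_interactions,
    toy_fixture,
)

S_d, S_t, Y = toy_fixture("worked_3x2")
K_d, K_t = prepare_kernel(S_d), prepare_kernel(S_t)

print("known interactions (1 = interacts):")
for i, d in enumerate(Y.drug_ids):
    print(" ", d, Y.values[i].astype(int))

spec = PredictorSpec("rls", "kp", alpha=0.5)  # RLS, Kronecker product kernel
F = predict(spec, K_d, K_t, Y)
print(f"\nprediction scores ({spec.name}, alpha={spec.alpha}, sigma={spec.sigma}):")
for i, d in enumerate(F.drug_ids):
    print(" ", d, [round(float(v), 4) for v in F.values[i]])

print("\ncandidate new interactions (unknown pairs, best first):")
for rank, drug, target, score in rank_new_interactions(F, Y, top_n=4):
    print(f"  {rank}. {drug} -> {target}  score={score:.4f}")
# d2->t1 ranks first: d2 is similar to d1 (0.6), which is known to bind t1,
# and d2's own known target t2 is similar to t1 (0.3).
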