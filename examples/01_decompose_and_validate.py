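"""ANOVA partition of a designed experiment and permutation validation.

Simulates the reference two-factor experiment (4 x 3 levels, 8 replicates,
50 variables, two planted 5-variable groups), decomposes it into effect
matrices and tests each effect's multivariate significance.
"""

import gasca

dataset, truth = gasca.simulate_planted(gasca.SimulationSpec(seed=0))
print(f"dataset: {dataset.n_obs} observations x {dataset.n_vars} variables, "
      f"R={dataset.replicates} replicates per cell")

decomp = gasca.decompose(dataset)
print("\nSum-of-squares fractions per model term:")
print(gasca.ssq_table(decomp).to_string(float_format="%.4f"))

print("\nPermutation tests (999 permutations):")
for effect in decomp.effect_names:
    res = gasca.permutation_test(dataset, effect, n_perm=999, seed=1)
    print(f"  {effect:18s} p = {res.p_value:.4f}")

# Both planted factors are overwhelmingly significant (p at the 1/(1+n_perm)
# floor); the interaction, which was not planted, is not — so only the two
# main effects deserve a component model.
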