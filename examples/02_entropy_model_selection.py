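"""Step 1: entropy-based selection of the incompatibility model.

The information-gain ratio R = 1 - H(D|MFGI)/H(D) measures the fraction of
phenotype entropy explained by a model's high/low-risk split.  The model
with maximal R becomes the analysis model only if B phenotype permutations
show such a maximum is unlikely by chance (empirical p < tau); otherwise the
full model (Model 11) is used.
"""

import numpy as np

from mfgi import (
    SelectionConfig,
    classify_pairs,
    compute_all_ratios,
    permutation_select,
)
from mfgi.simulation import PopulationConfig, ScenarioConfig, draw_sample, simulate_population

# A population where Model 5 ({M1, M2}: the pair carries 3 copies of A)
# drives disease, then one study sample of 1000 mother-offspring pairs.
scenario = ScenarioConfig("demo", alpha_m=0.0, alpha_o=0.0, alpha_ic=1.2,
                          generating_model_id=5)
pop = simulate_population(PopulationConfig(100_000, maf=0.2), scenario,
                          rng=np.random.default_rng(7))
sample = draw_sample(pop, 1000, np.random.default_rng(8))

ratios = compute_all_ratios(sample.y, sample.classifications)
print("Information-gain ratios R_1..R_11:")
for i, r in enumerate(ratios, start=1):
    print(f"  Model {i:>2}: {r:.5f}")

config = SelectionConfig(n_permutations=2000, tau=0.001, seed=9)
res = permutation_select(sample.y, sample.classifications, config)
print(f"\nCandidate model: {res.candidate_id} (R_max = {res.r_max:.5f})")
print(f"Permutation p-value over B={config.n_permutations}: {res.p_empirical}")
print(f"Final analysis model: {res.final_model_id} (defaulted: {res.defaulted})")
# With a true Model-5 effect the candidate is Model 5 and the permutation
# guard confirms it; under a null locus the procedure would fall back to 11.
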