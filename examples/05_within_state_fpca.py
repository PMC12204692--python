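"""Functional PCA on the curves decoded into one latent state.

Splits a simulated dataset by decoded state, fits FPCA to the state-1
subset, applies the >70% retention rule, and prints the variance
profile and a per-individual score table ready for regression.
"""

import numpy as np

import statefda as sf
from statefda.fpca import scree_data

grid = sf.default_grid()
truth = sf.make_initial_model(sf.make_psd_centroids(grid, 4), self_transition=0.9)
data, _ = sf.simulate_fhmm_dataset(truth, 30, 60, noise_sd=0.1, seed=31)
paths = [sf.viterbi(s, truth) for s in data]

state1 = sf.subset_by_state(data, paths, state=1)
model = sf.fit_fpca(state1, state_label=1)
C = sf.choose_n_components(model.variance_fractions, threshold=0.70)

print(f"state 1: {len(state1)} curves")
print(scree_data(model.variance_fractions).head(6).to_string(index=False))
print(f"retained C = {C} components "
      f"({100 * np.cumsum(model.variance_fractions)[C - 1]:.1f}% of variance)")

scores = sf.individual_mean_scores(model, n_components=C)
print("\nper-individual mean scores (first rows):")
print(scores.head(4).round(4).to_string())
# Each row is one individual's average coordinates along the leading
# modes of within-state spectral variation.
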