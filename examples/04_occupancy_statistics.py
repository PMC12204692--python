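"""Per-individual latent-state dynamics from decoded paths.

Decodes simulated sequences under the true model and summarises each
individual: states visited, transitions, time shares, dominant-state
groups at the 80% threshold, and the visited-state combination counts
behind a Venn diagram.
"""

from collections import Counter

import statefda as sf
from statefda.occupancy import combinations_to_frame

grid = sf.default_grid()
truth = sf.make_initial_model(sf.make_psd_centroids(grid, 4), self_transition=0.95)
data, _ = sf.simulate_fhmm_dataset(truth, 40, 60, noise_sd=0.1, seed=23)

paths = [sf.viterbi(s, truth) for s in data]
summaries = [sf.summarise_path(p, n_states=4) for p in paths]

groups = sf.dominant_state_groups(summaries, threshold=0.8)
sizes = Counter(groups.values())
print("dominant-state group sizes (>=80% of time in one state):")
for label in sorted(sizes, key=str):
    print(f"  {label}: {sizes[label]}")

combos = sf.visited_combinations(summaries, n_states=4)
table = combinations_to_frame(combos)
print("\nmost common visited-state combinations:")
print(table.sort_values('count', ascending=False).head(5).to_string(index=False))
# Counts over all combinations sum to the number of individuals:
print("\ntotal individuals accounted for:", table['count'].sum())
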