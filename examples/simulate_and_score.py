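"""Simulate an ensemble-docking campaign and inspect per-residue binding scores.

Generates triplicate docking tables for an IDP ensemble and its random-coil
control (2400 runs each, the default study design), computes affinity-weighted
contact scores, and prints the top-scoring residues of each ensemble.
"""

import numpy as np

from dibs import SimulationConfig, replicate_profiles, simulate_replicates

config = SimulationConfig(seed=1)
tables = simulate_replicates(config)
profiles = replicate_profiles(tables)

print(f"{len(tables)} tables of {len(tables[0])} docking runs each")
for label in ("idp", "random_coil"):
    reps = [p for p in profiles if p.ensemble_label == label]
    mean_scores = np.mean([p.scores.values for p in reps], axis=0)
    top = np.argsort(mean_scores)[::-1][:5]
    listing = ", ".join(f"{r + 1}: {mean_scores[r]:.3f}" for r in sorted(top.tolist()))
    print(f"{label:>12}: top residue scores -> {listing}")

# Residues near the planted hot spots (10, 53, 66) dominate the IDP ensemble's
# scores; the random-coil control has only dispersed background contacts.
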