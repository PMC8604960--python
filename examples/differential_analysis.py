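"""Differential binding score (DIBS) between IDP and random-coil ensembles.

Runs the full pipeline on synthetic data with planted hot spots at residues
10, 53 and 66, then prints the per-residue classification: a residue is
"significant" when its log2 fold change exceeds 2 (>4-fold preference for
the IDP ensemble) at p < 0.05.
"""

from dibs import SimulationConfig, dibs_table, replicate_profiles, simulate_replicates
from dibs.differential import volcano_data

config = SimulationConfig(seed=1)
profiles = replicate_profiles(simulate_replicates(config))
idp = [p for p in profiles if p.ensemble_label == "idp"]
rc = [p for p in profiles if p.ensemble_label == "random_coil"]

table = dibs_table(idp, rc)
significant = table[table["class"] == "significant"]
print(f"{len(significant)} of {len(table)} residues significant:")
print(significant[["log2_fc", "p_value"]].round(3))

volcano = volcano_data(table)
print("\nvolcano classes:", volcano["class"].value_counts().to_dict())
# The significant set is the planted hot spots plus their +/-2 flanking
# patches; fold changes near 2.5-3 mean an ~6-8x score preference for the
# IDP ensemble at those positions.
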