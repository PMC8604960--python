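# dibs — differential binding scores for IDP ligand-site discovery

Intrinsically disordered proteins (IDPs) have no single binding pocket to
dock a ligand into: they exist as broad conformational ensembles.  `dibs`
post-processes *ensemble docking* campaigns — one ligand docked repeatedly
against many sampled receptor conformations — to find the residues a ligand
prefers on an IDP ensemble **relative to a random-coil control ensemble** of
the same sequence.  It is aimed at computational structural biologists who
already have docking output (or want to prototype against the built-in
synthetic generator) and need a statistically defensible per-residue answer
rather than a single best pose.

## The score and the statistic

For each docking run *i* of a replicate table (N runs: sampled conformers ×
independent docking routines), let *n\_i(k)* ∈ {0, 1} indicate whether residue
*k* contacts the ligand and *K\_d,i* the run's dissociation constant.  The
per-residue **probability score** is the affinity-weighted contact frequency

```
PS_k = (1/N) Σ_i n_i(k) · w_i ,   w_i = (1/K_d,i) / [ (1/N) Σ_j (1/K_d,j) ]
```

Inverse-*K\_d* weights are normalised to unit mean, so PS\_k = 0 for a residue
that never contacts the ligand and PS\_k = 1 for one that contacts in every
run, with tight-binding runs counting more in between.  Binding energies and
dissociation constants are interconverted via ΔG = −RT ln K\_d (R = 1.9872 ×
10⁻³ kcal mol⁻¹ K⁻¹, T = 298 K by default).

The sampling protocol is repeated in triplicate for each ensemble (default:
100 conformers drawn from a pool of 1000, 24 runs each → 2400 runs per
table).  The **differential binding score (DIBS)** then tests each residue
between the two ensembles: log2 fold change of mean PS (IDP over random
coil) and a p-value from a two-group linear model on log2(PS + ε), with
limma-style empirical-Bayes variance moderation to stabilise the 3-vs-3
design (the plain pooled t-test is available as the moderation-off switch).
A residue is *significant* when log2 FC > 2 and p < 0.05 — the upper-right
corner of the volcano plot.

For validation against experiment, per-residue ¹⁵N/¹³CO chemical-shift
changes are combined as Δδ = √(½((α\_n δ\_n)² + (α\_c δ\_c)²)) (α\_n = 0.6,
α\_c = 0.4) and CSP hot spots are matched to DIBS hot spots within a sequence
window.  Ensemble-characterisation utilities (Rg, backbone RMSD, per-residue
RMSF, PCA variance fractions of CA coordinates) round out the pipeline.

## Worked example

```bash
python examples/differential_analysis.py
```

prints (seed 1, default study design):

```
15 of 93 residues significant:
         log2_fc  p_value
residue
8          2.674      0.0
9          2.749      0.0
10         2.685      0.0
...
68         2.817      0.0

volcano classes: {'not_significant': 70, 'significant': 15, 'p_only': 8}
```

The synthetic campaign plants ligand hot spots at residues 10, 53 and 66,
each contact dragging a ±2-residue flanking patch along; the significant set
is exactly those three 5-residue patches, with log2 fold changes of ~2.5–2.8
(a six- to seven-fold score preference for the IDP ensemble).  The other
examples cover scoring (`simulate_and_score.py`), CSP comparison
(`csp_comparison.py`, matching CSP hot spots to DIBS hot spots within ±2
residues), contact detection and 5 Å pose clustering
(`contacts_and_clustering.py`), and ensemble metrics
(`characterize_ensemble.py`).

The same pipeline is scriptable from the shell:

```bash
dibs simulate --seed 1 --out run/sim
dibs score run/sim/docking_*.tsv --fasta protein.fasta --out run/profiles
dibs dibs run/profiles/profile_*.csv --out run/dibs --figure
dibs csp shifts.csv run/dibs/dibs.csv --out run/compare
```

Docking results produced by an actual engine can replace the `simulate`
stage at any point: the TSV dialect (one row per run: conformer id, binding
energy in kcal/mol, dissociation constant with units column, comma-separated
contact residues) is documented in `dibs.core.read_docking_table`, and
contact sets can alternatively be derived from receptor/pose PDB coordinates
with `dibs.contacts`.

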