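# Methods

## The model

`dibs` treats an ensemble docking campaign as a two-condition, replicated
experiment.  The unit of observation is a *docking run*: one ligand docked
once against one receptor conformer, yielding a binding energy (kcal/mol,
stored as a positive magnitude — larger is tighter), a dissociation constant
(molar), and the set of receptor residues in contact with the ligand.  A
*replicate table* collects all runs of one random subsample of conformers; a
*condition* is the ensemble the conformers came from, either the IDP
ensemble under study or a random-coil control of the same sequence.

ΔG and K_d are interconverted with ΔG = −RT ln K_d using
R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ and T = 298 K.  These constants reproduce
typical docking-engine report pairs (817.24 nM ↔ 8.30 kcal/mol,
766.47 nM ↔ 8.34 kcal/mol) to the printed 2 decimal places; the temperature
is configurable everywhere the conversion appears.  When a table supplies
both quantities they are cross-checked on read within 0.02 kcal/mol
(generous against 2-d.p. rounding of either field; `consistency_tol=None`
disables the check for engines with other conventions).

### Probability score

For residue k over a table of N runs,

    PS_k = (1/N) Σ_i n_i(k) · w_i,   w_i = (1/K_d,i) / mean_j(1/K_d,j)

with n_i(k) a 0/1 contact indicator.  Two choices here are deliberate:

* **Unit-mean weight normalisation.**  A raw sum of n_i/K_d,i has units of
  1/concentration and is unbounded; normalising the inverse-K_d weights to
  unit mean makes PS a weighted contact *frequency* that is exactly 0 for a
  never-contacting residue and exactly 1 for an always-contacting one, while
  preserving "tighter runs count more".  PS is invariant to rescaling all
  K_d by a common factor (so the unit the engine reports in — pM, nM — is
  immaterial).  The raw sum is kept as `raw_scores` for diagnostics.
* **Indicator, not count.**  n_i(k) records whether the residue participates
  in the run's interface, not how many of its atoms do; this is what keeps
  PS within [0, 1].

### Differential test

Each residue is tested between conditions on y = log2(PS + ε), ε = 10⁻⁶.
The pseudocount is fixed rather than data-dependent so scores are comparable
across runs; at typical PS values (≥ 10⁻³ for anything contacted at all) it
is negligible, and for all-zero residues it pins the fold change to 0.

With variance moderation **off**, the statistic is the pooled two-sample
t-test with df = n₁ + n₂ − 2.  With moderation **on** (default), per-residue
pooled variances s²_k are shrunk toward a prior estimated across residues by
empirical Bayes: log s² is moment-matched to a scaled-F model, giving prior
df d₀ (via a Newton inversion of the trigamma function) and prior variance
s₀²; the posterior variance (d₀s₀² + df·s²)/(d₀ + df) enters a t statistic
with df + d₀ degrees of freedom.  When the observed spread of variances does
not exceed chi-square sampling noise, d₀ = ∞ and all residues share the mean
variance (normal reference distribution).  The moderated path agrees with
the Bioconductor limma implementation to ~10⁻¹⁰ in p-value (checked in the
test suite by running limma through Rscript); the unmoderated path agrees
with an independent pooled t-test to 10⁻¹⁰ over 1000 random inputs.
Moderation matters in this design because each condition has only three
replicates: per-residue variance estimates at df = 4 are unstable, and
sharing information across the 93 residues both stabilises them and, in the
null calibration below, keeps the test's size at its nominal level where the
plain t-test at df = 4 runs conservative (~0.03 observed at α = 0.05).

A residue is classified `significant` if log2 FC > 2 (i.e. > 4-fold) *and*
raw p < 0.05; `p_only` if only the p criterion holds.  Benjamini–Hochberg
adjusted p-values are reported alongside for transparency but do not drive
the classification.  Volcano output floors p at 10⁻³⁰⁰ before taking
−log10.

### Chemical-shift comparison

Δδ = sqrt(½((α_n δ_n)² + (α_c δ_c)²)) combines ¹⁵N and ¹³CO shift changes;
squaring removes the (often opposite) signs.  Defaults α_n = 0.6,
α_c = 0.4.  The conventional derivation of such weights from the backbone
shift ranges of the two nuclei (~22 ppm for ¹⁵N, ~32.5 ppm for ¹³CO) would
put the larger weight on the *smaller*-range nucleus's ratio — the two
published forms of this weighting disagree, so the decimal values are taken
as authoritative and both weights are configurable.  Missing residues
(prolines, overlapped resonances) carry explicit flags, are excluded from
hot-spot statistics, and are never imputed.

CSP hot spots are residues with Δδ above mean + level·sd (level 1 by
default) or above a quantile.  Agreement with the DIBS-significant set is
quantified by one-to-one matching within a ± window of sequence positions
(two-pointer greedy on the sorted sets, which attains maximum cardinality
for a threshold criterion on a line) and summarised as m/(|A| + |B| − m),
which reduces to the Jaccard index at window 0.

### Geometry

Contacts: residue k contacts a pose when the minimum heavy-atom distance is
≤ 5.0 Å (KD-tree query; cutoff configurable; hydrogens excluded by
default).  Pose RMSD is computed in the shared receptor frame without
superposition, since docked poses already live in one coordinate system;
pose clustering is greedy energy-ordered leader clustering, which guarantees
every retained pair differs by at least the requested separation (5 Å
default).  Superposition for ensemble metrics uses the Kabsch SVD solution
with reflection correction; RMSF and PCA operate on CA coordinates after
(optional) superposition to the first model — for strongly disordered
ensembles a global fit is questionable, hence the no-fit switch.  PCA
variance fractions are covariance eigenvalues over their trace.

## The synthetic generator

The generator emulates the *statistical* footprint of an ensemble docking
campaign, not its physics.  Defaults mirror the study design: a 93-residue
chain, a pool of 1000 conformers subsampled to 100 per replicate, 24 runs
per conformer (2400 rows per table), 3 replicates per condition.

* Planted hot spots (default residues 10, 53, 66) seed contacts with
  per-run probability 0.6 in the IDP condition; every firing seed drags a
  ±2-residue flanking patch into the footprint, because real interfaces are
  contiguous in sequence.  All residues also carry an independent 0.05
  background contact probability.  The random-coil condition runs the *same*
  mechanism with the hot-spot probability set to the background value — this
  symmetry is what makes the exchangeable null (equal probabilities, no
  affinity boost) exactly exchangeable, at the cost of a mild patchiness
  (~0.10 contact rate) near hot-spot positions in the control.
* K_d is log-normal: log10 K_d ~ N(−6, 0.5) (micromolar centre, half-decade
  spread).  In the IDP condition, runs contacting ≥ 1 hot spot have K_d
  multiplied by 0.25 (four-fold tighter) — the coupling between specific
  contacts and affinity that inverse-K_d weighting is designed to detect.
  The control has no such coupling: it is defined as non-specific, and
  chance hot-spot contacts there do not bind tighter.  (Applying the boost
  in both conditions would up-weight the control's chance hot-spot contacts
  ~4-fold and drive the planted fold change below the log2 FC = 2
  threshold, making the planted signal undetectable by construction.)
* Because flanking residues fire whenever their seed does, the *planted
  region* is hot spots ± halfwidth (`planted_region`); "background" in all
  recovery statements means residues outside that region.

Every draw is a pure function of (seed, condition, replicate) through
`numpy.random.default_rng` seeded with that tuple, so simulated tables
serialise byte-identically across processes and replicates are individually
reproducible.

**What passing tests show — and don't.**  The generator plants exactly the
structure the statistic looks for: contiguous, affinity-coupled contact
enrichment against a uniform control.  Recovery and calibration results
therefore validate the *pipeline* (scoring, weighting, moderated testing,
classification), not the docking or MD stages: real ensembles have
correlated conformer geometry, non-uniform coil contacts, pose-clustering
artefacts and engine-specific K_d noise that the synthetic model does not
attempt.  Headline biological findings on any real system must come from
real docking tables fed through the same interfaces.

## Numerical and interface choices

* Residue numbering is 1-based, owned by the FASTA-derived protein
  definition; PDB resSeq must match exactly (no renumbering heuristics).
* Missing ranks in a docking table are assigned by descending binding
  energy, ties broken by ascending run id.
* TSV serialisation writes floats at full `repr` precision and contact sets
  sorted ascending, making output byte-stable for equal inputs.
* The trigamma inversion uses Newton iteration from x₀ = 0.5 + 1/y with
  asymptotic guards at y > 10⁷ and y < 10⁻⁶; variance shrinkage excludes
  non-finite or zero variances from prior estimation but still shrinks those
  residues.
* Degenerate inputs: a residue with zero variance in both groups and equal
  means gets p = 1; p-values are floored at 10⁻³⁰⁰; PCA rejects ensembles
  with no coordinate variance; an empty pose or model is an error, an empty
  pose list clusters to an empty representative list.
* Problem sizes in the validation suite (3 null datasets for calibration,
  5 seeds for planted recovery, 1000 vectors for the t-test oracle) were
  chosen to give stable statistics at interactive runtimes; all scale
  linearly if larger audits are wanted.

## Known limitations

* The contact criterion of any specific docking engine (distance, surface,
  or energy based) is not reproduced; the 5 Å minimum-distance rule is a
  conventional stand-in, and pre-computed contact tables bypass it entirely.
* Pose RMSD is not symmetry-corrected (equivalent ligand atom orderings are
  treated as distinct) and assumes a common receptor frame.
* The moderated test assumes approximately log-normal PS noise across
  replicates; with only three replicates per condition this is untestable
  per residue and is instead supported by the global null calibration.
* CSP comparison is positional only; it does not model shift magnitudes
  against score magnitudes.
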