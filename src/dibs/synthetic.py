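"""Synthetic docking tables, toy structures and CSP tables.

The generator emulates the statistical structure of an ensemble-docking
campaign on a disordered protein without running MD or docking:

* **Contact footprints.**  In the "idp" ensemble a small set of planted
  hot-spot residues contacts the ligand with high per-run probability
  (default 0.6); every contacted hot spot drags a flanking sequence patch
  (default +/-2 residues) into the footprint, because real ligand contacts
  are contiguous stretches of sequence.  All residues additionally carry a
  uniform background contact probability (default 0.05).  The "random_coil"
  control draws every residue at the background rate only — dispersed,
  non-specific contacts.
* **Affinities.**  Dissociation constants are log-normal on the log10 scale
  (default mean 1 uM, sd 0.5 decades).  In the "idp" ensemble, runs that
  contact at least one hot spot have their Kd multiplied by a boost factor
  (default 0.25, i.e. four-fold tighter) — the coupling between specific
  contacts and tight binding that gives inverse-Kd weighting something to
  detect.  The random-coil control has no such coupling: chance hot-spot
  contacts in a non-specific ensemble do not bind tighter, so its Kd draws
  are pure background.  Binding energies follow from Kd thermodynamically.
* **Determinism.**  Every draw is a pure function of (seed, ensemble label,
  replicate), so tables serialise byte-identically across runs.

Setting the hot-spot contact probability equal to the background one and the
boost to 1 yields an exchangeable null in which "idp" and "random_coil"
tables are identically distributed — the calibration condition for the
differential test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ConformerEnsemble,
    DockingRun,
    EnsembleDockingTable,
    LigandPose,
    ProteinDefinition,
    StructureModel,
    delta_g_from_kd,
)
from .csp import CSPTable, CSPWeights
from .scoring import SamplingPlan, subsample_conformers
from .scoring import _stream as _rng_stream

__all__ = [
    "SimulationConfig",
    "null_config",
    "planted_region",
    "simulate_docking_table",
    "simulate_replicates",
    "simulate_toy_complex",
    "simulate_csp_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic ensemble-docking generator."""

    n_residues: int = 93
    hotspot_residues: frozenset[int] = frozenset({10, 53, 66})
    hotspot_contact_prob: float = 0.6
    background_contact_prob: float = 0.05
    contact_patch_halfwidth: int = 2
    kd_log10_mean: float = -6.0  # micromolar scale
    kd_log10_sd: float = 0.5
    hotspot_affinity_boost: float = 0.25  # idp-ensemble Kd multiplier on hot-spot contact
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "hotspot_residues", frozenset(int(r) for r in self.hotspot_residues))
        for p in (self.hotspot_contact_prob, self.background_contact_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contact probabilities must be in [0, 1], got {p}")
        if not self.hotspot_residues <= set(range(1, self.n_residues + 1)):
            raise ValueError("hotspot residues must lie within 1..n_residues")
        if self.contact_patch_halfwidth < 0:
            raise ValueError("contact_patch_halfwidth must be >= 0")
        if self.hotspot_affinity_boost <= 0:
            raise ValueError("hotspot_affinity_boost must be positive")

    @property
    def protein(self) -> ProteinDefinition:
        return ProteinDefinition("A" * self.n_residues, name="synthetic")


def null_config(base: SimulationConfig = SimulationConfig()) -> SimulationConfig:
    """The exchangeable-null variant: no planted signal, no affinity coupling."""
    return replace(
        base,
        hotspot_contact_prob=base.background_contact_prob,
        hotspot_affinity_boost=1.0,
    )


def planted_region(config: SimulationConfig) -> frozenset[int]:
    """Residues carrying planted signal: hot spots plus their flanking patches.

    Flank residues are contacted whenever their seed hot spot is, so they are
    signal by construction; "background" means everything outside this set.
    """
    region = set()
    for h in config.hotspot_residues:
        for r in range(h - config.contact_patch_halfwidth, h + config.contact_patch_halfwidth + 1):
            if 1 <= r <= config.n_residues:
                region.add(r)
    return frozenset(region)


def _contact_footprints(config: SimulationConfig, ensemble_label: str,
                        n_runs: int, rng: np.random.Generator) -> np.ndarray:
    """(n_runs, n_residues) boolean contact matrix (column j = residue j+1)."""
    L = config.n_residues
    contacts = rng.random((n_runs, L)) < config.background_contact_prob
    hot_prob = (
        config.hotspot_contact_prob if ensemble_label == "idp" else config.background_contact_prob
    )
    hw = config.contact_patch_halfwidth
    for h in sorted(config.hotspot_residues):
        seed_on = rng.random(n_runs) < hot_prob
        lo = max(h - hw, 1) - 1
        hi = min(h + hw, L)  # slice end, inclusive residue h + hw
        contacts[seed_on, lo:hi] = True
    return contacts


def simulate_docking_table(
    config: SimulationConfig,
    ensemble_label: str,
    replicate: int,
) -> EnsembleDockingTable:
    """One replicate's full docking table (sample_size x runs_per_conformer runs)."""
    plan = replace(config.plan, seed=config.seed)
    pool = np.arange(1, plan.pool_size + 1)
    sample = subsample_conformers(pool, plan, replicate, ensemble_label)
    n_runs = plan.runs_per_table
    rng = _rng_stream(config.seed ^ 0x5D1B5, ensemble_label, replicate)

    contacts = _contact_footprints(config, ensemble_label, n_runs, rng)
    hot_idx = np.array(sorted(config.hotspot_residues)) - 1
    hot_contacted = contacts[:, hot_idx].any(axis=1) if hot_idx.size else np.zeros(n_runs, dtype=bool)

    kd = 10.0 ** rng.normal(config.kd_log10_mean, config.kd_log10_sd, size=n_runs)
    if ensemble_label == "idp":
        kd[hot_contacted] *= config.hotspot_affinity_boost
    energy = delta_g_from_kd(kd)

    conformer_ids = np.repeat(sample, plan.runs_per_conformer)
    runs = [
        DockingRun(
            run_id=i + 1,
            conformer_id=int(conformer_ids[i]),
            binding_energy=float(energy[i]),
            dissociation_constant=float(kd[i]),
            contact_residues=frozenset((np.nonzero(contacts[i])[0] + 1).tolist()),
        )
        for i in range(n_runs)
    ]
    table = EnsembleDockingTable(runs, ensemble_label, replicate, config.protein)
    return table.ranked()


def simulate_replicates(config: SimulationConfig) -> list[EnsembleDockingTable]:
    """All tables of the design: every ensemble label x every replicate."""
    return [
        simulate_docking_table(config, label, rep)
        for label in ("idp", "random_coil")
        for rep in range(1, config.plan.n_replicates + 1)
    ]


def simulate_toy_complex(
    n_residues: int = 10,
    pose_offset: float = 3.0,
    target_residue: int | None = None,
    n_ligand_atoms: int = 5,
    seed: int = 0,
) -> tuple[StructureModel, LigandPose, ProteinDefinition]:
    """A toy CA+CB chain with a ligand at a known distance from one residue.

    The chain zig-zags in the xy plane with 3.8 A CA spacing; the ligand's
    nearest atom sits exactly ``pose_offset`` A above the target residue's CA
    (default: the middle residue), the remaining atoms strictly further away,
    so the expected contact set at any cutoff is computable in advance.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    target = target_residue if target_residue is not None else (n_residues // 2) + 1
    if not 1 <= target <= n_residues:
        raise ValueError("target residue outside the chain")

    resnums, names, elems, coords = [], [], [], []
    for i in range(n_residues):
        ca = np.array([3.8 * i, 1.5 * (i % 2), 0.0])
        cb = ca + np.array([0.0, -1.5 if i % 2 else 1.5, 0.0])
        for name, xyz in (("CA", ca), ("CB", cb)):
            resnums.append(i + 1)
            names.append(name)
            elems.append("C")
            coords.append(xyz)
    model = StructureModel(np.array(resnums), tuple(names), tuple(elems), np.array(coords))

    target_ca = np.array([3.8 * (target - 1), 1.5 * ((target - 1) % 2), 0.0])
    anchor = target_ca + np.array([0.0, 0.0, pose_offset])
    lig = [anchor]
    for k in range(1, n_ligand_atoms):
        # stack remaining atoms higher, with small lateral jitter
        lig.append(anchor + np.array([0.0, 0.0, 1.5 * k]) + rng.normal(0, 0.2, 3) * [1, 1, 0])
    pose = LigandPose(0, tuple(f"C{k + 1}" for k in range(n_ligand_atoms)), np.array(lig))
    protein = ProteinDefinition("A" * n_residues, name="toy")
    return model, pose, protein


def simulate_csp_table(
    n_residues: int = 93,
    hotspot_residues: frozenset[int] = frozenset({10, 53, 66}),
    effect_size: float = 1.0,
    noise_sd: float = 0.05,
    missing_frac: float = 0.15,
    seed: int = 0,
    weights: CSPWeights = CSPWeights(),
) -> CSPTable:
    """Per-residue shift-change table with planted hot spots.

    Hot-spot residues receive 15N/13CO changes of magnitude ``effect_size``
    ppm with opposite signs (as binding-induced shifts often are) plus
    Gaussian noise; other residues receive noise only.  A ``missing_frac``
    fraction of residues is flagged missing, mimicking unassignable
    resonances.
    """
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    hot = np.isin(residues, sorted(hotspot_residues))
    delta_n = np.where(hot, effect_size, 0.0) + rng.normal(0, noise_sd, n_residues)
    delta_c = np.where(hot, -effect_size, 0.0) + rng.normal(0, noise_sd, n_residues)
    n_missing = int(round(missing_frac * n_residues))
    missing = np.zeros(n_residues, dtype=bool)
    if n_missing:
        missing[rng.choice(n_residues, size=n_missing, replace=False)] = True
    return CSPTable.from_shifts(residues, delta_n, delta_c, missing, weights)
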