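"""Ligand-contact detection and pose clustering.

A residue is in contact with a ligand pose when the minimum heavy-atom
distance between any of its atoms and any ligand atom is within a cutoff
(default 5.0 A, a conventional contact definition; docking engines do not all
publish their criterion, so the cutoff is configurable and pre-computed
contact tables can be used instead).

Pose RMSD is computed in the shared receptor frame without superposition:
docked poses live in the same coordinate system, so displacement is
meaningful as-is.  Clustering follows a greedy, energy-ordered leader scheme
that guarantees every pair of retained representatives differs by at least
the requested separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import LigandPose, StructureModel

__all__ = ["ContactParameters", "contact_residues", "pose_rmsd", "cluster_poses"]


@dataclass(frozen=True)
class ContactParameters:
    """Distance criterion for protein-ligand contacts."""

    cutoff: float = 5.0  # Angstrom, minimum heavy-atom distance
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


def contact_residues(
    model: StructureModel,
    pose: LigandPose,
    params: ContactParameters = ContactParameters(),
) -> set[int]:
    """Residues whose minimum atom distance to the ligand is <= cutoff."""
    if len(model) == 0 or len(pose) == 0:
        raise ValueError("model and pose must both contain atoms")
    atoms = model if params.include_hydrogens else model.heavy_atoms()
    if len(atoms) == 0:
        raise ValueError("model has no heavy atoms")
    tree = cKDTree(pose.coordinates)
    dmin, _ = tree.query(atoms.coordinates, k=1)
    hit = dmin <= params.cutoff
    return {int(r) for r in np.unique(atoms.residue_numbers[hit])}


def pose_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Heavy-atom RMSD between two poses in the common receptor frame."""
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    if a.atom_names != b.atom_names:
        raise ValueError("atom name order differs between poses")
    d = a.coordinates - b.coordinates
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def cluster_poses(
    poses: Sequence[LigandPose],
    energies: Sequence[float],
    min_separation: float = 5.0,
) -> list[int]:
    """Greedy leader clustering of poses by heavy-atom RMSD.

    Poses are visited in descending binding-energy order (ties broken by
    input position); a pose becomes a new representative iff its RMSD to
    every representative accepted so far is >= ``min_separation``.

    Returns indices into ``poses`` of the representatives, in acceptance
    order, so ``[poses[i] for i in result]`` are the cluster leaders.
    """
    if len(poses) != len(energies):
        raise ValueError("poses and energies must be parallel")
    if not poses:
        return []
    order = sorted(range(len(poses)), key=lambda i: (-float(energies[i]), i))
    reps: list[int] = []
    for i in order:
        if all(pose_rmsd(poses[i], poses[j]) >= min_separation for j in reps):
            reps.append(i)
    return reps
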