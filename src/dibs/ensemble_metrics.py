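"""Geometric characterisation of conformer ensembles.

Disordered-protein ensembles are summarised by per-model radius of gyration
and backbone RMSD to a reference, per-residue CA fluctuation (RMSF), and the
variance fractions of a principal-component analysis of CA Cartesian
coordinates.  Superposition uses the Kabsch algorithm (optimal rigid-body
fit).  For strongly disordered ensembles a global superposition is
questionable — all fitting steps can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConformerEnsemble, StructureModel

__all__ = [
    "ATOMIC_MASSES",
    "BACKBONE_ATOMS",
    "EnsembleSummary",
    "kabsch_superpose",
    "radius_of_gyration",
    "backbone_rmsd",
    "residue_rmsf",
    "pca_variance",
    "summarize_ensemble",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Both are (n, 3) arrays of paired coordinates; returns the transformed
    mobile coordinates.  Standard SVD solution with a determinant correction
    to exclude reflections.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate arrays must have identical shape")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return (mobile - mc) @ rot + rc


def radius_of_gyration(model: StructureModel, mass_weighted: bool = False) -> float:
    """Rg in Angstrom; unweighted mode treats every atom as unit mass."""
    coords = model.coordinates
    if mass_weighted:
        masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in model.elements])
    else:
        masses = np.ones(len(model))
    center = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def _matched_backbone(model: StructureModel, reference: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    def keyed(m):
        sel = m.select(BACKBONE_ATOMS)
        return {
            (int(r), n): sel.coordinates[i]
            for i, (r, n) in enumerate(zip(sel.residue_numbers, sel.atom_names))
        }

    a, b = keyed(model), keyed(reference)
    if set(a) != set(b):
        raise ValueError("backbone atom sets differ between model and reference")
    keys = sorted(a)
    return np.array([a[k] for k in keys]), np.array([b[k] for k in keys])


def backbone_rmsd(model: StructureModel, reference: StructureModel, superpose: bool = True) -> float:
    """Backbone (N, CA, C, O) RMSD to a reference, optionally after Kabsch fit."""
    x, y = _matched_backbone(model, reference)
    if superpose:
        x = kabsch_superpose(x, y)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def residue_rmsf(ensemble: ConformerEnsemble, superpose: bool = True) -> pd.Series:
    """Per-residue CA fluctuation about the ensemble-mean position (Angstrom).

    Models are (optionally) superposed onto the first model on CA atoms
    before the mean structure and deviations are taken.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 models")
    order = list(ensemble.protein.residue_numbers)
    coords = np.array([m.ca_coordinates(order) for m in ensemble.models])  # (M, L, 3)
    if superpose:
        ref = coords[0]
        coords = np.array([kabsch_superpose(c, ref) for c in coords])
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return pd.Series(rmsf, index=pd.Index(order, name="residue"), name="rmsf")


def pca_variance(ensemble: ConformerEnsemble, superpose: bool = True) -> np.ndarray:
    """Ordered variance fractions of a PCA on flattened CA coordinates.

    Eigenvalues of the coordinate covariance matrix divided by its trace;
    non-increasing and summing to 1.  An ensemble with no coordinate
    variation is degenerate and rejected.
    """
    if len(ensemble) < 3:
        raise ValueError("PCA needs at least 3 models")
    order = list(ensemble.protein.residue_numbers)
    coords = np.array([m.ca_coordinates(order) for m in ensemble.models])
    if superpose:
        ref = coords[0]
        coords = np.array([kabsch_superpose(c, ref) for c in coords])
    flat = coords.reshape(len(ensemble), -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / (len(ensemble) - 1)
    trace = np.trace(cov)
    if trace <= 1e-12:
        raise ValueError("degenerate ensemble: no coordinate variance")
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()


@dataclass
class EnsembleSummary:
    """Per-model, per-residue and PCA summaries of one ensemble."""

    per_model: pd.DataFrame  # columns: model, rg, rmsd_to_reference
    per_residue: pd.Series  # rmsf
    pc_variance_fractions: np.ndarray


def summarize_ensemble(
    ensemble: ConformerEnsemble,
    reference: StructureModel | None = None,
    superpose: bool = True,
    mass_weighted_rg: bool = False,
) -> EnsembleSummary:
    """Full characterisation against a reference (default: first model)."""
    ref = reference if reference is not None else ensemble.models[0]
    per_model = pd.DataFrame(
        {
            "model": np.arange(1, len(ensemble) + 1),
            "rg": [radius_of_gyration(m, mass_weighted_rg) for m in ensemble.models],
            "rmsd_to_reference": [backbone_rmsd(m, ref, superpose) for m in ensemble.models],
        }
    )
    return EnsembleSummary(
        per_model=per_model,
        per_residue=residue_rmsf(ensemble, superpose) if len(ensemble) >= 2 else pd.Series(dtype=float),
        pc_variance_fractions=pca_variance(ensemble, superpose) if len(ensemble) >= 3 else np.array([]),
    )
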