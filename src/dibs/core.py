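"""Domain types, thermodynamic conversions, and file I/O.

The central objects are :class:`ProteinDefinition` (sequence + residue
numbering), :class:`DockingRun` / :class:`EnsembleDockingTable` (one ensemble
docking campaign: many independent docking runs against sampled receptor
conformers, each with a binding energy, a dissociation constant and the set of
receptor residues contacting the ligand), and :class:`ConformerEnsemble` /
:class:`LigandPose` for coordinate-level work.

Conventions
-----------
* Binding energies are stored as *positive* magnitudes in kcal/mol (larger =
  tighter binding), the sign convention used when reporting docking "binding
  constants".  Docking engines that print negative free energies must be
  negated on import.
* Dissociation constants are stored internally in molar.  The TSV dialect
  carries an optional ``kd_units`` column (M, mM, uM, nM, pM) converted on
  read; files without it are taken to be molar.
* Residue numbering is 1-based and owned by the FASTA-derived
  ``ProteinDefinition``; PDB ``resSeq`` values must match it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "ProteinDefinition",
    "DockingRun",
    "EnsembleDockingTable",
    "LigandPose",
    "StructureModel",
    "ConformerEnsemble",
    "delta_g_from_kd",
    "kd_from_delta_g",
    "read_fasta_protein",
    "read_docking_table",
    "write_docking_table",
    "read_ensemble_pdb",
    "read_pose_pdb",
    "write_ensemble_pdb",
    "write_pose_pdb",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default absolute temperature (K) for DeltaG <-> Kd conversions.  298 K
#: with the gas constant above reproduces typical docking-engine output
#: (e.g. Kd = 817.24 nM <-> 8.30 kcal/mol) to the printed 2 decimal places.
DEFAULT_TEMPERATURE = 298.0

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_KD_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

ENSEMBLE_LABELS = ("idp", "random_coil")


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def delta_g_from_kd(kd, temperature: float = DEFAULT_TEMPERATURE):
    """Binding free-energy magnitude (kcal/mol) from a dissociation constant.

    Computes ``-RT ln(Kd)`` with Kd in molar; positive for sub-molar Kd.
    Accepts scalars or arrays.
    """
    kd = np.asarray(kd, dtype=float)
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if np.any(kd <= 0):
        raise ValueError("dissociation constant must be strictly positive")
    out = -GAS_CONSTANT_KCAL * temperature * np.log(kd)
    return float(out) if out.ndim == 0 else out


def kd_from_delta_g(dg, temperature: float = DEFAULT_TEMPERATURE):
    """Inverse of :func:`delta_g_from_kd`: ``Kd = exp(-dG / RT)`` in molar."""
    dg = np.asarray(dg, dtype=float)
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if np.any(np.abs(dg) > 100):
        raise ValueError("binding energy magnitude > 100 kcal/mol is unphysical")
    out = np.exp(-dg / (GAS_CONSTANT_KCAL * temperature))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinDefinition:
    """A protein sequence with explicit 1-based residue numbering."""

    sequence: str
    residue_numbers: tuple[int, ...] = ()
    name: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non amino-acid characters in sequence: {sorted(bad)}")
        numbers = self.residue_numbers
        if not numbers:
            numbers = tuple(range(1, len(self.sequence) + 1))
            object.__setattr__(self, "residue_numbers", numbers)
        else:
            object.__setattr__(self, "residue_numbers", tuple(int(n) for n in numbers))
            numbers = self.residue_numbers
        if len(numbers) != len(self.sequence):
            raise ValueError("residue_numbers length must match sequence length")
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(self.residue_numbers)


def read_fasta_protein(path, name: str | None = None) -> ProteinDefinition:
    """Read the first record of a FASTA file as a ProteinDefinition."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return ProteinDefinition(sequence=str(rec.seq).upper(), name=name or rec.id)


@dataclass(frozen=True)
class DockingRun:
    """One docking result against one receptor conformer."""

    run_id: int
    conformer_id: int
    binding_energy: float  # kcal/mol, positive magnitude
    dissociation_constant: float  # molar
    contact_residues: frozenset[int] = frozenset()
    rank: int | None = None

    def __post_init__(self):
        if self.dissociation_constant <= 0:
            raise ValueError(
                f"run {self.run_id}: dissociation constant must be > 0, "
                f"got {self.dissociation_constant}"
            )
        object.__setattr__(self, "contact_residues", frozenset(int(r) for r in self.contact_residues))
        if self.rank is not None and self.rank < 1:
            raise ValueError(f"run {self.run_id}: rank must be >= 1")


@dataclass
class EnsembleDockingTable:
    """All docking runs of one replicate against one sampled ensemble."""

    runs: list[DockingRun]
    ensemble_label: str
    replicate_id: int
    protein: ProteinDefinition

    def __post_init__(self):
        if self.ensemble_label not in ENSEMBLE_LABELS:
            raise ValueError(
                f"ensemble_label must be one of {ENSEMBLE_LABELS}, got {self.ensemble_label!r}"
            )
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be >= 1")
        ids = [r.run_id for r in self.runs]
        if len(ids) != len(set(ids)):
            raise ValueError("run_ids must be unique within a table")
        allowed = self.protein.residue_set
        for r in self.runs:
            extra = r.contact_residues - allowed
            if extra:
                raise ValueError(
                    f"run {r.run_id}: contact residues {sorted(extra)} not in protein "
                    f"{self.protein.name or '<unnamed>'}"
                )

    def __len__(self) -> int:
        return len(self.runs)

    def ranked(self) -> "EnsembleDockingTable":
        """Return a copy with ranks assigned by descending binding energy.

        Ties on energy are broken by ascending run_id, so rank 1 is the
        tightest binder.
        """
        order = sorted(self.runs, key=lambda r: (-r.binding_energy, r.run_id))
        ranked = [replace(r, rank=i + 1) for i, r in enumerate(order)]
        ranked.sort(key=lambda r: r.run_id)
        return EnsembleDockingTable(ranked, self.ensemble_label, self.replicate_id, self.protein)

    def contact_matrix(self) -> np.ndarray:
        """Boolean (n_runs, n_residues) contact indicator matrix."""
        residues = self.protein.residue_numbers
        index = {r: i for i, r in enumerate(residues)}
        mat = np.zeros((len(self.runs), len(residues)), dtype=bool)
        for i, run in enumerate(self.runs):
            for res in run.contact_residues:
                mat[i, index[res]] = True
        return mat

    def dissociation_constants(self) -> np.ndarray:
        return np.array([r.dissociation_constant for r in self.runs], dtype=float)


@dataclass(frozen=True)
class LigandPose:
    """Heavy-atom coordinates of one docked ligand pose (receptor frame)."""

    pose_id: int
    atom_names: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coordinates must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("pose coordinates must be finite")
        if len(self.atom_names) != coords.shape[0]:
            raise ValueError("atom_names and coordinates lengths differ")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))

    def __len__(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class StructureModel:
    """Flat per-atom record of one conformer (numpy-backed)."""

    residue_numbers: np.ndarray  # (n_atoms,), int
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.residue_numbers.shape[0]
        if not (len(self.atom_names) == len(self.elements) == self.coordinates.shape[0] == n):
            raise ValueError("per-atom arrays must have equal length")
        self.atom_names = tuple(self.atom_names)
        self.elements = tuple(e.upper() for e in self.elements)

    def __len__(self) -> int:
        return self.residue_numbers.shape[0]

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(int(r) for r in np.unique(self.residue_numbers))

    def heavy_atoms(self) -> "StructureModel":
        keep = np.array([e != "H" for e in self.elements], dtype=bool)
        return StructureModel(
            self.residue_numbers[keep],
            tuple(n for n, k in zip(self.atom_names, keep) if k),
            tuple(e for e, k in zip(self.elements, keep) if k),
            self.coordinates[keep],
        )

    def select(self, atom_names: Iterable[str]) -> "StructureModel":
        wanted = set(atom_names)
        keep = np.array([n in wanted for n in self.atom_names], dtype=bool)
        return StructureModel(
            self.residue_numbers[keep],
            tuple(n for n, k in zip(self.atom_names, keep) if k),
            tuple(e for e, k in zip(self.elements, keep) if k),
            self.coordinates[keep],
        )

    def ca_coordinates(self, residue_order: Sequence[int]) -> np.ndarray:
        """CA coordinates in the given residue order; error on missing CA."""
        ca = self.select(["CA"])
        index = {int(r): i for i, r in enumerate(ca.residue_numbers)}
        missing = [r for r in residue_order if r not in index]
        if missing:
            raise ValueError(f"residues without CA atom: {missing}")
        return ca.coordinates[[index[r] for r in residue_order]]


@dataclass
class ConformerEnsemble:
    """A multi-model conformational ensemble of one protein."""

    models: list[StructureModel]
    protein: ProteinDefinition

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0].residue_set
        for i, m in enumerate(self.models[1:], start=2):
            if m.residue_set != ref:
                raise ValueError(f"model {i} residue set differs from model 1")

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# docking-table TSV I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("run_id", "conformer_id", "binding_energy",
                  "dissociation_constant", "contact_residues")


def read_docking_table(
    path,
    protein: ProteinDefinition,
    ensemble_label: str | None = None,
    replicate_id: int | None = None,
    consistency_tol: float | None = 0.02,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnsembleDockingTable:
    """Read an ensemble-docking result table from TSV.

    Required columns: run_id, conformer_id, binding_energy,
    dissociation_constant, contact_residues (comma-separated residue
    numbers; empty = no contacts).  Optional columns: kd_units, rank.
    Lines starting with ``#`` are comments; ``# key=value`` comments carry
    table metadata (ensemble_label, replicate_id) which explicit arguments
    override.

    When both binding energy and Kd come from the file they are checked for
    thermodynamic consistency within ``consistency_tol`` kcal/mol (pass
    ``None`` to skip).  Missing ranks are assigned by descending binding
    energy with run_id tie-break.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append((lineno, line.split("\t")))
    if header is None:
        raise ValueError(f"{path}: empty docking table (no header)")
    col = {name: i for i, name in enumerate(header)}
    missing_cols = [c for c in _TABLE_COLUMNS if c not in col]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    runs: list[DockingRun] = []
    any_rank_missing = False
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")

        def _num(name, conv):
            raw = fields[col[name]]
            try:
                return conv(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed {name} value {raw!r}") from None

        run_id = _num("run_id", int)
        conformer_id = _num("conformer_id", int)
        energy = _num("binding_energy", float)
        kd = _num("dissociation_constant", float)
        unit = fields[col["kd_units"]] if "kd_units" in col else "M"
        if unit not in _KD_UNIT_FACTORS:
            raise ValueError(f"{path}:{lineno}: unknown kd unit {unit!r}")
        kd *= _KD_UNIT_FACTORS[unit]
        raw_contacts = fields[col["contact_residues"]].strip()
        try:
            contacts = frozenset(int(t) for t in raw_contacts.split(",") if t.strip()) if raw_contacts else frozenset()
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed contact_residues {raw_contacts!r}") from None
        bad = contacts - protein.residue_set
        if bad:
            raise ValueError(
                f"{path}:{lineno}: contact residues {sorted(bad)} outside protein numbering"
            )
        rank = None
        if "rank" in col and fields[col["rank"]].strip():
            rank = _num("rank", int)
        else:
            any_rank_missing = True
        if kd <= 0:
            raise ValueError(f"{path}:{lineno}: dissociation constant must be > 0")
        if consistency_tol is not None:
            implied = delta_g_from_kd(kd, temperature)
            if abs(implied - energy) > consistency_tol:
                raise ValueError(
                    f"{path}:{lineno}: binding energy {energy} inconsistent with Kd "
                    f"(implies {implied:.4f} kcal/mol at {temperature} K)"
                )
        runs.append(DockingRun(run_id, conformer_id, energy, kd, contacts, rank))

    label = ensemble_label or meta.get("ensemble_label")
    if label is None:
        raise ValueError(f"{path}: ensemble_label not given and absent from file metadata")
    rep = replicate_id if replicate_id is not None else int(meta.get("replicate_id", 1))
    table = EnsembleDockingTable(runs, label, rep, protein)
    if any_rank_missing:
        table = table.ranked()
    return table


def write_docking_table(table: EnsembleDockingTable, path) -> Path:
    """Write a docking table in the TSV dialect of :func:`read_docking_table`.

    Kd is written in molar at full float precision; contact residue sets are
    serialised sorted ascending, so equal tables produce byte-identical files.
    """
    path = Path(path)
    lines = [
        f"# ensemble_label={table.ensemble_label}",
        f"# replicate_id={table.replicate_id}",
        "\t".join(_TABLE_COLUMNS + ("kd_units", "rank")),
    ]
    for r in table.runs:
        contacts = ",".join(str(x) for x in sorted(r.contact_residues))
        rank = "" if r.rank is None else str(r.rank)
        lines.append(
            f"{r.run_id}\t{r.conformer_id}\t{float(r.binding_energy)!r}\t"
            f"{float(r.dissociation_constant)!r}\t{contacts}\tM\t{rank}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _element_of(atom) -> str:
    elem = (atom.element or "").strip().upper()
    if not elem:
        # fall back to the first alphabetic character of the atom name
        elem = next((c for c in atom.get_name() if c.isalpha()), "C").upper()
    return elem


def read_ensemble_pdb(path, protein: ProteinDefinition, drop_hydrogens: bool = True) -> ConformerEnsemble:
    """Read a multi-model PDB as a ConformerEnsemble.

    Only ATOM records of standard residues are used; every model must cover
    exactly the residue numbers of ``protein`` (no renumbering heuristics).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ensemble", str(path))
    models: list[StructureModel] = []
    for pdb_model in structure:
        resnums, names, elems, coords = [], [], [], []
        for chain in pdb_model:
            for residue in chain:
                if residue.id[0] != " ":  # skip heteroatoms/waters
                    continue
                for atom in residue:
                    elem = _element_of(atom)
                    if drop_hydrogens and elem == "H":
                        continue
                    resnums.append(residue.id[1])
                    names.append(atom.get_name())
                    elems.append(elem)
                    coords.append(atom.coord)
        if not resnums:
            raise ValueError(f"{path}: model without protein ATOM records")
        model = StructureModel(np.array(resnums), tuple(names), tuple(elems), np.array(coords))
        got, want = model.residue_set, protein.residue_set
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ValueError(
                f"{path}: model {len(models) + 1} residue mismatch "
                f"(missing {missing}, unexpected {extra})"
            )
        models.append(model)
    return ConformerEnsemble(models, protein)


def read_pose_pdb(path, pose_id: int = 0, heavy_only: bool = True) -> LigandPose:
    """Read ligand pose coordinates from a PDB file (ATOM + HETATM records)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("pose", str(path))
    names, coords = [], []
    for atom in next(iter(structure)).get_atoms():
        if heavy_only and _element_of(atom) == "H":
            continue
        names.append(atom.get_name())
        coords.append(atom.coord)
    if not names:
        raise ValueError(f"{path}: no ligand atoms found")
    return LigandPose(pose_id, tuple(names), np.array(coords))


def _pdb_atom_line(serial, name, resname, resseq, xyz, element, record="ATOM  ") -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record}{serial:>5d} {name_f} {resname:<3s} A{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_ensemble_pdb(ensemble: ConformerEnsemble, path) -> Path:
    """Write a ConformerEnsemble as a multi-model PDB file."""
    path = Path(path)
    lines: list[str] = []
    for imodel, model in enumerate(ensemble.models, start=1):
        lines.append(f"MODEL     {imodel:>4d}")
        for serial, (resnum, name, elem, xyz) in enumerate(
            zip(model.residue_numbers, model.atom_names, model.elements, model.coordinates),
            start=1,
        ):
            lines.append(_pdb_atom_line(serial, name, "GLY", int(resnum), xyz, elem))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pose_pdb(pose: LigandPose, path, resname: str = "LIG") -> Path:
    path = Path(path)
    lines = [
        _pdb_atom_line(i + 1, name, resname, 1, xyz,
                       next((c for c in name if c.isalpha()), "C"), record="HETATM")
        for i, (name, xyz) in enumerate(zip(pose.atom_names, pose.coordinates))
    ]
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
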