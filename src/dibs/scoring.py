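"""Per-residue probability scores over an ensemble docking table.

The probability score of residue *k* aggregates, over all N docking runs of
one replicate, whether the residue contacted the ligand, weighting each run
by the tightness of its predicted binding::

    PS_k = (1/N) * sum_i n_i * w_i,      w_i = (1/Kd_i) / mean_j(1/Kd_j)

where ``n_i`` is the 0/1 contact indicator of residue *k* in run *i* and
``Kd_i`` the run's dissociation constant.  The inverse-Kd weights are
normalised to unit mean so the score is a weighted contact *frequency*:
exactly 0 for a residue that never contacts the ligand and exactly 1 for a
residue contacting in every run, with tighter-binding runs counting more in
between.  The raw weighted sum ``(1/N) sum_i n_i / Kd_i`` (units 1/M) is kept
alongside for diagnostics.

Sampling protocol: from a pool of conformers (default 1000), each replicate
draws a random subset (default 100) without replacement; each sampled
conformer receives a fixed number of independent docking runs (default 24),
giving 2400 runs per replicate table; the draw is repeated independently per
replicate (default 3) for each ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ENSEMBLE_LABELS, EnsembleDockingTable

__all__ = [
    "SamplingPlan",
    "ResidueScoreProfile",
    "probability_score",
    "subsample_conformers",
    "replicate_profiles",
    "write_profiles_csv",
    "read_profiles_csv",
]


@dataclass(frozen=True)
class SamplingPlan:
    """Subsampled ensemble-docking design."""

    pool_size: int = 1000
    sample_size: int = 100
    runs_per_conformer: int = 24
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.pool_size, self.sample_size, self.runs_per_conformer, self.n_replicates) < 1:
            raise ValueError("all sampling-plan sizes must be positive")
        if self.sample_size > self.pool_size:
            raise ValueError("sample_size cannot exceed pool_size")

    @property
    def runs_per_table(self) -> int:
        return self.sample_size * self.runs_per_conformer


@dataclass
class ResidueScoreProfile:
    """PS_k for every residue of one replicate of one ensemble."""

    scores: pd.Series  # index: residue number, values in [0, 1]
    ensemble_label: str
    replicate_id: int
    n_runs: int
    raw_scores: pd.Series | None = None  # unnormalised (1/N) sum n_i/Kd_i, 1/M

    def __post_init__(self):
        self.scores = pd.Series(self.scores, dtype=float)
        self.scores.index = self.scores.index.astype(int)
        self.scores.index.name = "residue"

    def __getitem__(self, residue: int) -> float:
        return float(self.scores.loc[residue])


def probability_score(table: EnsembleDockingTable) -> ResidueScoreProfile:
    """Affinity-weighted per-residue contact frequency of one table."""
    if len(table) == 0:
        raise ValueError("cannot score an empty docking table")
    kd = table.dissociation_constants()
    if np.any(kd <= 0):
        raise ValueError("all dissociation constants must be positive")
    contacts = table.contact_matrix()  # (N, L)
    inv = 1.0 / kd
    weights = inv / inv.mean()
    scores = contacts.T @ weights / len(table)
    raw = contacts.T @ inv / len(table)
    residues = list(table.protein.residue_numbers)
    return ResidueScoreProfile(
        scores=pd.Series(scores, index=residues),
        ensemble_label=table.ensemble_label,
        replicate_id=table.replicate_id,
        n_runs=len(table),
        raw_scores=pd.Series(raw, index=residues),
    )


_LABEL_CODES = {label: i for i, label in enumerate(ENSEMBLE_LABELS)}


def _stream(seed: int, ensemble_label: str, replicate: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, ensemble, replicate)
    return np.random.default_rng([int(seed), _LABEL_CODES[ensemble_label], int(replicate)])


def subsample_conformers(
    pool: "list[int] | np.ndarray",
    plan: SamplingPlan,
    replicate: int,
    ensemble_label: str = "idp",
) -> np.ndarray:
    """Draw one replicate's conformer sample, without replacement.

    The draw is fully determined by ``(plan.seed, ensemble_label,
    replicate)``; different replicates use independent streams, so samples
    may overlap across replicates but never repeat a conformer within one.
    """
    pool = np.asarray(pool)
    if not 1 <= replicate <= plan.n_replicates:
        raise ValueError(f"replicate must be in 1..{plan.n_replicates}")
    if plan.sample_size > pool.size:
        raise ValueError("sample_size exceeds pool size")
    rng = _stream(plan.seed, ensemble_label, replicate)
    return rng.choice(pool, size=plan.sample_size, replace=False)


def replicate_profiles(tables: list[EnsembleDockingTable]) -> list[ResidueScoreProfile]:
    """Score every table; output sorted by (ensemble_label, replicate_id)."""
    seen = set()
    for t in tables:
        key = (t.ensemble_label, t.replicate_id)
        if key in seen:
            raise ValueError(f"duplicate table for {key}")
        seen.add(key)
    ordered = sorted(tables, key=lambda t: (t.ensemble_label, t.replicate_id))
    return [probability_score(t) for t in ordered]


def write_profiles_csv(profiles: list[ResidueScoreProfile], path) -> Path:
    """Serialise profiles as long-format CSV: residue, score, ensemble, replicate."""
    frames = [
        pd.DataFrame(
            {
                "residue": p.scores.index,
                "score": p.scores.values,
                "ensemble": p.ensemble_label,
                "replicate": p.replicate_id,
            }
        )
        for p in profiles
    ]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_profiles_csv(path) -> list[ResidueScoreProfile]:
    df = pd.read_csv(path)
    profiles = []
    for (label, rep), grp in df.groupby(["ensemble", "replicate"], sort=True):
        profiles.append(
            ResidueScoreProfile(
                scores=pd.Series(grp["score"].values, index=grp["residue"].values),
                ensemble_label=str(label),
                replicate_id=int(rep),
                n_runs=0,
            )
        )
    return profiles
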