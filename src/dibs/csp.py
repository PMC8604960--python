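"""Chemical-shift-perturbation tables and comparison with binding scores.

Per-residue 15N and 13CO chemical-shift changes on ligand binding are
combined into a single weighted Euclidean magnitude::

    combined = sqrt( 0.5 * ( (alpha_n * delta_n)^2 + (alpha_c * delta_c)^2 ) )

with dimensionless weights alpha_n = 0.6 and alpha_c = 0.4 by default,
reflecting the relative backbone chemical-shift ranges of the two nuclei.
Squaring makes the combination insensitive to the sign of the individual
changes (15N and 13CO shifts often move in opposite directions on binding).

Residues without experimental data (prolines lacking an amide proton,
overlapped or broadened resonances) are carried as explicit missing flags:
they are excluded from hotspot statistics and never imputed.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CSPWeights",
    "CSPTable",
    "combined_shift",
    "read_csp_csv",
    "write_csp_csv",
    "csp_hotspots",
    "overlap_report",
    "OverlapReport",
]


@dataclass(frozen=True)
class CSPWeights:
    alpha_n: float = 0.6
    alpha_c: float = 0.4

    def __post_init__(self):
        if not (0 < self.alpha_n <= 1 and 0 < self.alpha_c <= 1):
            raise ValueError("weights must lie in (0, 1]")


def combined_shift(delta_n, delta_c, weights: CSPWeights = CSPWeights()):
    """Weighted Euclidean combination of 15N and 13CO shift changes (ppm)."""
    dn = np.asarray(delta_n, dtype=float)
    dc = np.asarray(delta_c, dtype=float)
    out = np.sqrt(0.5 * ((weights.alpha_n * dn) ** 2 + (weights.alpha_c * dc) ** 2))
    return float(out) if out.ndim == 0 else out


@dataclass
class CSPTable:
    """Per-residue shift changes with a combined magnitude and missing flags."""

    data: pd.DataFrame  # index residue; columns delta_n, delta_c, combined, missing

    def __post_init__(self):
        required = {"delta_n", "delta_c", "combined", "missing"}
        if not required <= set(self.data.columns):
            raise ValueError(f"CSPTable requires columns {sorted(required)}")
        present = self.data.loc[~self.data["missing"], "combined"]
        if (present < 0).any():
            raise ValueError("combined shifts must be non-negative")

    @classmethod
    def from_shifts(cls, residues, delta_n, delta_c, missing=None,
                    weights: CSPWeights = CSPWeights()) -> "CSPTable":
        residues = np.asarray(residues, dtype=int)
        dn = np.asarray(delta_n, dtype=float)
        dc = np.asarray(delta_c, dtype=float)
        miss = np.zeros(residues.size, dtype=bool) if missing is None else np.asarray(missing, dtype=bool)
        combined = combined_shift(np.where(miss, 0.0, dn), np.where(miss, 0.0, dc), weights)
        df = pd.DataFrame(
            {"delta_n": dn, "delta_c": dc, "combined": combined, "missing": miss},
            index=pd.Index(residues, name="residue"),
        )
        df.loc[df["missing"], ["delta_n", "delta_c", "combined"]] = np.nan
        return cls(df)

    def present(self) -> pd.DataFrame:
        return self.data.loc[~self.data["missing"]]


def read_csp_csv(path, weights: CSPWeights = CSPWeights()) -> CSPTable:
    """Read residue, delta_n, delta_c from CSV; blank shifts mean missing."""
    df = pd.read_csv(path)
    for c in ("residue", "delta_n", "delta_c"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    missing = df["delta_n"].isna() | df["delta_c"].isna()
    return CSPTable.from_shifts(
        df["residue"].values,
        df["delta_n"].fillna(0.0).values,
        df["delta_c"].fillna(0.0).values,
        missing.values,
        weights,
    )


def write_csp_csv(table: CSPTable, path, hotspots: set[int] | None = None) -> Path:
    """Write the table with combined shifts; missing residues stay blank."""
    out = table.data.reset_index()
    if hotspots is not None:
        out["hotspot"] = out["residue"].isin(hotspots)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def csp_hotspots(
    table: CSPTable,
    method: str = "mean_plus_sd",
    level: float = 1.0,
) -> set[int]:
    """Residues whose combined shift stands above the bulk of the table.

    ``mean_plus_sd``: combined > mean + level * sd (population sd over
    non-missing residues).  ``quantile``: combined > the level-quantile.
    """
    present = table.present()
    if len(present) == 0:
        raise ValueError("all residues are missing")
    if len(present) < 3:
        raise ValueError("need at least 3 non-missing residues")
    vals = present["combined"].values
    if method == "mean_plus_sd":
        threshold = vals.mean() + level * vals.std(ddof=0)
    elif method == "quantile":
        threshold = np.quantile(vals, level)
    else:
        raise ValueError(f"unknown hotspot method {method!r}")
    return set(int(r) for r in present.index[vals > threshold])


@dataclass(frozen=True)
class OverlapReport:
    """Windowed agreement between two residue hot-spot sets."""

    matched_pairs: tuple[tuple[int, int], ...]
    n_a: int
    n_b: int
    window: int

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    @property
    def jaccard(self) -> float:
        """m / (|A| + |B| - m); reduces to the Jaccard index at window 0."""
        denom = self.n_a + self.n_b - self.n_matched
        return self.n_matched / denom if denom else 1.0


def overlap_report(csp_hot: set[int], dibs_significant: set[int], window: int = 0) -> OverlapReport:
    """Match residues of two hot-spot sets within +/- ``window`` positions.

    Uses maximum one-to-one matching (two-pointer greedy on the sorted sets,
    which is optimal for threshold matching on a line); symmetric at window 0.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    a = sorted(csp_hot)
    b = sorted(dibs_significant)
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= window:
            pairs.append((a[i], b[j]))
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return OverlapReport(tuple(pairs), len(a), len(b), window)
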