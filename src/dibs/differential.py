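"""Differential binding score: per-residue fold change and significance.

Given triplicate probability-score profiles for the IDP ensemble and the
random-coil control, each residue gets

* a log2 fold change ``log2((mean(idp)+eps) / (mean(rc)+eps))`` with a small
  pseudocount ``eps`` guarding zero scores, and
* a p-value from a two-group linear model on ``log2(PS + eps)``.

With variance moderation off the test is exactly the pooled-variance
two-sample t-test (df = n1 + n2 - 2).  With moderation on (the default) the
per-residue residual variances are shrunk toward a common prior estimated
across all residues by empirical Bayes — the moderated t-statistic of the
limma lineage — which stabilises the tiny-replicate (n = 3 vs 3) design.
The prior (d0, s0^2) is fit by matching moments of log residual variances to
a scaled inverse-chi-square distribution.

A residue is classified ``significant`` when log2 fold change exceeds the
threshold (default 2.0, i.e. >4-fold) AND raw p < 0.05; ``p_only`` when only
the p-value criterion holds.  Benjamini-Hochberg adjusted p-values are
reported for transparency but do not drive the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .scoring import ResidueScoreProfile

__all__ = [
    "DifferentialConfig",
    "log2_fold_change",
    "residue_p_value",
    "moderated_variance_prior",
    "dibs_table",
    "volcano_data",
    "plot_volcano",
    "CLASS_SIGNIFICANT",
    "CLASS_P_ONLY",
    "CLASS_NOT_SIGNIFICANT",
]

CLASS_SIGNIFICANT = "significant"
CLASS_P_ONLY = "p_only"
CLASS_NOT_SIGNIFICANT = "not_significant"

#: Volcano-plot colour convention: red = significant (both criteria),
#: blue = p-value only, black = neither.
CLASS_COLORS = {
    CLASS_SIGNIFICANT: "red",
    CLASS_P_ONLY: "blue",
    CLASS_NOT_SIGNIFICANT: "black",
}

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class DifferentialConfig:
    fc_threshold: float = 2.0  # on the log2 scale (>4-fold)
    p_threshold: float = 0.05
    pseudocount: float = 1e-6
    variance_moderation: bool = True

    def __post_init__(self):
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def log2_fold_change(idp_scores, rc_scores, pseudocount: float = 1e-6) -> float:
    """log2 ratio of group means, pseudocount-guarded; antisymmetric in groups."""
    idp = np.asarray(idp_scores, dtype=float)
    rc = np.asarray(rc_scores, dtype=float)
    if idp.size < 2 or rc.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    return float(np.log2((idp.mean() + pseudocount) / (rc.mean() + pseudocount)))


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def moderated_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2): prior degrees of freedom and variance for shrinkage.

    Moment-matches ``log(s2)`` against the log of a scaled F/inverse-chi-square
    prior: with ``z = log(s2)``, ``E[z] = log(s0^2) + digamma(df/2) -
    log(df/2)`` shifted by the prior, and ``Var[z]`` exceeds
    ``trigamma(df/2)`` by ``trigamma(d0/2)``.  Returns ``d0 = inf`` (complete
    shrinkage to a single common variance) when the observed spread of
    variances does not exceed the chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # spread of variances within chi-square sampling noise: shrink fully
        d0 = np.inf
        s0_sq = float(s2.mean())
    return d0, s0_sq


def _pooled_stats(idp: np.ndarray, rc: np.ndarray) -> tuple[float, float, float]:
    """(mean difference, pooled variance, residual df) of two groups."""
    n1, n2 = idp.size, rc.size
    df = n1 + n2 - 2
    ss = idp.var(ddof=1) * (n1 - 1) + rc.var(ddof=1) * (n2 - 1)
    return float(idp.mean() - rc.mean()), float(ss / df), float(df)


def residue_p_value(
    idp_scores,
    rc_scores,
    config: DifferentialConfig = DifferentialConfig(),
    variance_prior: tuple[float, float] | None = None,
) -> float:
    """Two-sided p-value for one residue's IDP-vs-random-coil contrast.

    Operates on log2(PS + pseudocount).  With ``variance_moderation`` off, or
    without a ``variance_prior`` (there is nothing to share information with
    for a single residue), this is the pooled two-sample t-test; with a prior
    ``(d0, s0_sq)`` — normally supplied by :func:`dibs_table`, which fits it
    across all residues — the moderated t with df + d0 degrees of freedom.
    """
    idp = np.log2(np.asarray(idp_scores, dtype=float) + config.pseudocount)
    rc = np.log2(np.asarray(rc_scores, dtype=float) + config.pseudocount)
    if idp.size < 2 or rc.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    diff, s2, df = _pooled_stats(idp, rc)
    if config.variance_moderation and variance_prior is not None:
        d0, s0_sq = variance_prior
        if np.isinf(d0):
            s2_post, df_total = s0_sq, np.inf
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = df + d0
    else:
        s2_post, df_total = s2, df
    if s2_post == 0:
        return 1.0 if diff == 0 else _P_FLOOR
    se = np.sqrt(s2_post * (1.0 / idp.size + 1.0 / rc.size))
    t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df_total)
    return float(max(p, _P_FLOOR))


def _group_matrix(profiles: list[ResidueScoreProfile]) -> pd.DataFrame:
    """Residues x replicates matrix from a list of profiles (one ensemble)."""
    cols = {p.replicate_id: p.scores for p in profiles}
    return pd.DataFrame(cols).sort_index()


def dibs_table(
    idp_profiles: list[ResidueScoreProfile],
    rc_profiles: list[ResidueScoreProfile],
    config: DifferentialConfig = DifferentialConfig(),
) -> pd.DataFrame:
    """Per-residue differential table: log2_fc, p_value, adjusted_p, class.

    Requires matching residue sets across all profiles.  Deterministic given
    its inputs; the empirical-Bayes prior, when moderation is on, is fit once
    across all residues and shared.
    """
    if len(idp_profiles) < 2 or len(rc_profiles) < 2:
        raise ValueError("need at least 2 replicates per ensemble")
    idp = _group_matrix(idp_profiles)
    rc = _group_matrix(rc_profiles)
    if not idp.index.equals(rc.index):
        raise ValueError("residue sets differ between IDP and random-coil profiles")

    idp_log = np.log2(idp.values + config.pseudocount)
    rc_log = np.log2(rc.values + config.pseudocount)

    prior = None
    if config.variance_moderation:
        n1, n2 = idp_log.shape[1], rc_log.shape[1]
        df = n1 + n2 - 2
        ss = idp_log.var(axis=1, ddof=1) * (n1 - 1) + rc_log.var(axis=1, ddof=1) * (n2 - 1)
        prior = moderated_variance_prior(ss / df, df)

    records = []
    for i, residue in enumerate(idp.index):
        fc = log2_fold_change(idp.values[i], rc.values[i], config.pseudocount)
        p = residue_p_value(idp.values[i], rc.values[i], config, variance_prior=prior)
        records.append((int(residue), fc, p))
    table = pd.DataFrame(records, columns=["residue", "log2_fc", "p_value"]).set_index("residue")
    table["adjusted_p"] = multipletests(table["p_value"].values, method="fdr_bh")[1]
    sig = (table["log2_fc"] > config.fc_threshold) & (table["p_value"] < config.p_threshold)
    p_only = (table["p_value"] < config.p_threshold) & ~sig
    table["class"] = CLASS_NOT_SIGNIFICANT
    table.loc[p_only, "class"] = CLASS_P_ONLY
    table.loc[sig, "class"] = CLASS_SIGNIFICANT
    return table


def volcano_data(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano records: x = log2_fc, y = -log10 p, class, color."""
    out = pd.DataFrame(
        {
            "residue": table.index,
            "x": table["log2_fc"].values,
            "y": -np.log10(np.maximum(table["p_value"].values, _P_FLOOR)),
            "class": table["class"].values,
        }
    )
    out["color"] = out["class"].map(CLASS_COLORS)
    return out


def plot_volcano(table: pd.DataFrame, config: DifferentialConfig = DifferentialConfig(), ax=None):
    """Volcano plot with the significance thresholds as dashed lines."""
    import matplotlib.pyplot as plt

    data = volcano_data(table)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for klass, grp in data.groupby("class"):
        ax.scatter(grp["x"], grp["y"], s=12, c=CLASS_COLORS[klass], label=klass)
    ax.axvline(config.fc_threshold, ls="--", c="grey", lw=0.8)
    ax.axhline(-np.log10(config.p_threshold), ls="--", c="grey", lw=0.8)
    ax.set_xlabel("log2 fold change (IDP / random coil)")
    ax.set_ylabel("-log10 p-value")
    ax.legend(frameon=False, fontsize=8)
    return ax
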