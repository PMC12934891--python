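"""Clonal diversity, top-clone composition, public-TCR matching and
somatic-hypermutation comparison.

Diversity follows the Hill-number family D_q = (sum_i p_i^q)^(1/(1-q)) over
clone proportions p_i, with the Shannon limit exp(-sum p_i ln p_i) at
q = 1; q tunes the weight of rare versus abundant clones (q = 0 is clone
richness, q -> inf the reciprocal of the largest clone's share).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import EmptyRepertoireError

__all__ = ["hill_diversity", "diversity_curve", "top_expanded_clones",
           "match_public_tcrs", "shm_cumulative_compare", "DEFAULT_Q_GRID"]

#: Default q grid: 0 to 4 in steps of 0.25 (both the richness end and the
#: abundance-dominated end are included for the zoom views).
DEFAULT_Q_GRID = tuple(np.arange(0.0, 4.25, 0.25))


def hill_diversity(clone_counts, q: float) -> float:
    """Hill diversity of order q for a vector of clone counts.

    Proportions are computed over clones with positive counts, so the
    value is invariant to rescaling of counts. q = 1 is handled by the
    Shannon limit, making the diversity profile continuous in q.
    """
    counts = np.asarray(clone_counts, dtype=float)
    if q < 0:
        raise ValueError("q must be nonnegative")
    counts = counts[counts > 0]
    if counts.size == 0:
        raise EmptyRepertoireError("all clone counts are zero")
    p = counts / counts.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def diversity_curve(clonotypes: pd.DataFrame, meta: pd.DataFrame,
                    q_grid=DEFAULT_Q_GRID, by=("group", "visit"),
                    mode: str = "pooled") -> pd.DataFrame:
    """Diversity profiles D(q) per grouping key.

    ``meta`` supplies per-cell grouping labels (merged on cell_id);
    ``mode='pooled'`` computes D on cells pooled within each key (the
    default), ``mode='per_sample'`` computes D per sample and averages.
    """
    if mode not in ("pooled", "per_sample"):
        raise ValueError("mode must be 'pooled' or 'per_sample'")
    df = clonotypes.merge(meta, on="cell_id", how="inner")
    rows = []
    for key, sub in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        for q in q_grid:
            if mode == "pooled":
                d = hill_diversity(sub["clone_id"].value_counts().values, q)
            else:
                vals = [hill_diversity(s["clone_id"].value_counts().values, q)
                        for _, s in sub.groupby("sample_id")]
                d = float(np.mean(vals))
            rows.append((*key, float(q), d))
    return pd.DataFrame(rows, columns=[*by, "q", "d"])


def top_expanded_clones(clonotypes: pd.DataFrame, meta: pd.DataFrame,
                        n: int = 20, by=("group", "visit")) -> pd.DataFrame:
    """Cluster composition of the n largest clones within each grouping.

    Clones are ranked by cell count; ties at rank n are broken by
    lexicographic clone_id so the selection is deterministic. Per-clone
    composition fractions over clusters sum to 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    df = clonotypes.merge(meta, on="cell_id", how="inner")
    rows = []
    for key, sub in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        sizes = (sub.groupby("clone_id").size()
                 .rename("clone_size").reset_index()
                 .sort_values(["clone_size", "clone_id"],
                              ascending=[False, True]))
        top = sizes.head(n)["clone_id"]
        for rank, clone in enumerate(top, start=1):
            cc = sub.loc[sub["clone_id"] == clone, "cluster"].value_counts()
            frac = cc / cc.sum()
            for cluster, f in frac.items():
                rows.append((*key, clone, rank, int(cc.sum()),
                             cluster, float(f)))
    return pd.DataFrame(rows, columns=[*by, "clone_id", "rank", "clone_size",
                                       "cluster", "fraction"])


def match_public_tcrs(clonotypes: pd.DataFrame,
                      reference: pd.DataFrame) -> pd.DataFrame:
    """Flag TRB clonotypes exactly matching a public-TCR reference.

    The match key is the (CDR3 amino-acid sequence, V gene) pair — same
    CDR3 with a different V gene does not match, and no fuzzy matching is
    performed. Non-TRB chains are never flagged.
    """
    out = clonotypes.copy()
    if len(reference):
        ref_keys = set(zip(reference["cdr3_aa"], reference["v_gene"]))
    else:
        ref_keys = set()
    keys = list(zip(out["cdr3_aa"], out["v_gene"]))
    out["public_match"] = [(k in ref_keys) and c == "TRB"
                           for k, c in zip(keys, out["chain"])]
    return out


def shm_cumulative_compare(group_a, group_b, grid_points: int = 200):
    """Two-sample Kolmogorov-Smirnov comparison of mutation frequencies.

    Returns (D, p, curves) where D = sup |F_A - F_B|, p is the asymptotic
    two-sample KS p-value, and curves is a DataFrame of both empirical
    cumulative curves evaluated on a shared grid for plotting.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyRepertoireError("both mutation-frequency vectors must be "
                                   "non-empty")
    if ((a < 0) | (a > 1)).any() or ((b < 0) | (b > 1)).any():
        raise ValueError("mutation frequencies must lie in [0, 1]")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    grid = np.linspace(0.0, max(a.max(), b.max()), grid_points)
    curves = pd.DataFrame({
        "mutation_frequency": grid,
        "cum_a": np.searchsorted(np.sort(a), grid, side="right") / a.size,
        "cum_b": np.searchsorted(np.sort(b), grid, side="right") / b.size,
    })
    return float(res.statistic), float(res.pvalue), curves
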