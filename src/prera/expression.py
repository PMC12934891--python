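"""Wilcoxon differential expression and pre-ranked gene-set enrichment.

DE: per gene, a two-sided Wilcoxon rank-sum test (midrank ties,
continuity correction) between two disjoint cell sets on log-normalized
expression, with log2FC computed on the de-logged scale,
log2(mean(expm1(x_A)) + 1) - log2(mean(expm1(x_B)) + 1); significance
requires |log2FC| > 1 (strict) and Bonferroni-adjusted p < 0.05.

GSEA: weighted Kolmogorov-Smirnov running-sum enrichment (weight |stat|)
on a ranking of genes by average log2FC, restricted to genes detected in
at least 5% of cells; the null is built by drawing random gene sets of
the same size from the ranked universe, NES = ES / mean(|null ES| of
matching sign), and the permutation p-value carries a +1 pseudocount so
p >= 1/(n_perm + 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import FilteredToEmptyError

logger = logging.getLogger("prera")

__all__ = ["ExpressionMatrix", "wilcoxon_de", "gsea_preranked",
           "detection_fraction", "read_gmt"]


class ExpressionMatrix:
    """Dense genes x cells matrix of nonnegative log-normalized expression."""

    def __init__(self, values, genes, cells):
        self.values = np.asarray(values, dtype=float)
        self.genes = list(genes)
        self.cells = list(cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape inconsistent with genes/cells")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        self._cell_ix = {c: j for j, c in enumerate(self.cells)}

    def subset_cells(self, cell_ids):
        ix = [self._cell_ix[c] for c in cell_ids]
        return self.values[:, ix]


def wilcoxon_de(expr: ExpressionMatrix, cells_a, cells_b) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell sets."""
    set_a, set_b = set(cells_a), set(cells_b)
    if not set_a or not set_b:
        raise ValueError("both cell sets must be non-empty")
    if set_a & set_b:
        raise ValueError("cell sets overlap")
    xa = expr.subset_cells(sorted(set_a))
    xb = expr.subset_cells(sorted(set_b))
    res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    p = np.asarray(res.pvalue, dtype=float)
    log2fc = (np.log2(np.expm1(xa).mean(axis=1) + 1.0)
              - np.log2(np.expm1(xb).mean(axis=1) + 1.0))
    p_bonf = np.minimum(p * len(expr.genes), 1.0)
    significant = (np.abs(log2fc) > 1.0) & (p_bonf < 0.05)
    return pd.DataFrame({
        "gene": expr.genes,
        "log2fc": log2fc,
        "p": p,
        "p_bonferroni": p_bonf,
        "significant": significant,
    })


def detection_fraction(expr: ExpressionMatrix) -> pd.Series:
    """Fraction of cells expressing (value > 0) each gene."""
    return pd.Series((expr.values > 0).mean(axis=1), index=expr.genes)


def _running_es(order_stats: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the weighted KS running sum.

    ``order_stats``: |statistic| in ranked order; ``in_set``: boolean mask
    in the same order.
    """
    w = order_stats * in_set
    denom_hit = w.sum()
    n = len(in_set)
    n_miss = n - int(in_set.sum())
    if denom_hit == 0:  # all member stats zero: uniform hit steps
        hit = np.cumsum(in_set) / max(int(in_set.sum()), 1)
    else:
        hit = np.cumsum(w) / denom_hit
    miss = np.cumsum(~in_set) / max(n_miss, 1)
    run = hit - miss
    return float(run[np.argmax(np.abs(run))])


def gsea_preranked(ranks: pd.Series, gene_set, detection: pd.Series,
                   n_perm: int = 10_000, seed: int = 0,
                   gene_set_name: str = "gene_set",
                   n_sets_tested: int = 1) -> dict:
    """Pre-ranked GSEA of one gene set against a ranking statistic.

    ``ranks``: gene -> ranking statistic (average log2FC). ``gene_set``
    members absent from the ranking are dropped with a logged count, and
    members detected in fewer than 5% of cells are removed by the
    detection filter; an empty post-filter set raises naming the removed
    genes. ``n_sets_tested`` scales the Bonferroni correction when the
    caller tests several sets.
    """
    if len(ranks) < 2:
        raise ValueError("ranking must cover at least 2 genes")
    genes = list(gene_set)
    present = [g for g in genes if g in ranks.index]
    dropped_absent = len(genes) - len(present)
    if dropped_absent:
        logger.info("gsea: %d gene(s) of %r absent from ranking, dropped",
                    dropped_absent, gene_set_name)
    kept = [g for g in present if detection.get(g, 0.0) >= 0.05]
    removed = sorted(set(present) - set(kept))
    if not kept:
        raise FilteredToEmptyError(
            f"gene set {gene_set_name!r} empty after the 5% detection "
            f"filter; removed genes: {removed}")

    order = ranks.sort_values(ascending=False)
    order_stats = np.abs(order.to_numpy(dtype=float))
    pos = {g: j for j, g in enumerate(order.index)}
    mask = np.zeros(len(order), dtype=bool)
    mask[[pos[g] for g in kept]] = True
    es = _running_es(order_stats, mask)

    rng = np.random.default_rng(seed)
    k = len(kept)
    null = np.empty(n_perm)
    for b in range(n_perm):
        m = np.zeros(len(order), dtype=bool)
        m[rng.choice(len(order), size=k, replace=False)] = True
        null[b] = _running_es(order_stats, m)

    same_sign = null * np.sign(es) > 0
    denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and not np.isnan(denom) else np.nan
    # permutation p against same-sign null ES with a +1 pseudocount, so
    # that the sign of the observed extremum does not halve the p range
    n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
    p = (1.0 + n_extreme) / (1.0 + int(same_sign.sum()))
    return {
        "gene_set": gene_set_name,
        "es": float(es),
        "nes": float(nes),
        "p": float(p),
        "p_bonferroni": float(min(p * n_sets_tested, 1.0)),
        "n_genes_used": k,
        "removed_by_detection": removed,
    }


def read_gmt(path) -> dict:
    """Read GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
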