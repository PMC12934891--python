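"""Converter-related peak detection from binarized single-cell
chromatin accessibility.

The staged procedure: (1) pair peaks with genes whose +/-500 kb window
(centered on the TSS) contains the peak midpoint; (2) drop peaks of genes
in the bottom 75% of aggregate fragment coverage; (3) within one lineage
and visit, binarize per-cell accessibility and skip sparsely accessible
peaks (<5% accessible cells); (4) fit null/full binomial-logit models
with age and sex fixed effects, a per-sample random intercept, and the
Converter case term in the full model only, testing by a 1-df LRT; (5)
flag a peak Converter-related when the nominal LRT p < 0.05 and
beta_case > 0; (6) compare mean conservation of the flagged set against
background by a one-sided rank-sum test. Stage-by-stage record counts are
logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import fit_binomial_mixed, lrt
from .io import AccessibilityData, ConservationTrack

logger = logging.getLogger("prera")

__all__ = ["assign_gene_windows", "filter_low_coverage", "test_peak",
           "converter_peaks", "conservation_compare"]

WINDOW_BP = 500_000
MIN_ACCESSIBILITY = 0.05


def assign_gene_windows(data: AccessibilityData,
                        window: int = WINDOW_BP) -> pd.DataFrame:
    """Pair every peak with every gene whose window contains its midpoint.

    The window is [anchor - window, anchor + window) — half-open on the
    right — around the gene's anchor (TSS); a peak may pair with several
    genes. Peaks on chromosomes absent from the gene annotation are
    logged and skipped.
    """
    rows = []
    gene_chroms = set(data.genes["chrom"])
    for chrom, peaks in data.peaks.groupby("chrom"):
        if chrom not in gene_chroms:
            logger.warning("assign_gene_windows: chromosome %s absent from "
                           "gene annotation; %d peak(s) skipped",
                           chrom, len(peaks))
            continue
        genes = data.genes[data.genes["chrom"] == chrom]
        mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
        anchors = genes["anchor_position"].to_numpy()
        for g, anchor in zip(genes["gene"], anchors):
            inside = (mid >= anchor - window) & (mid < anchor + window)
            for pid, m in zip(peaks["peak_id"].to_numpy()[inside],
                              mid[inside]):
                rows.append((g, pid, int(abs(m - anchor))))
    out = pd.DataFrame(rows, columns=["gene", "peak_id", "distance"])
    logger.info("assign_gene_windows: %d gene-peak pair(s)", len(out))
    return out


def filter_low_coverage(pairs: pd.DataFrame, data: AccessibilityData,
                        keep_top_fraction: float = 0.25,
                        per: str = "gene") -> pd.DataFrame:
    """Drop pairs of genes (default) or peaks in the bottom coverage band.

    Per gene, aggregate fragment coverage is summed over its paired peaks
    and genes at or above the (1 - keep_top_fraction) nearest-rank
    quantile are retained; ties at the threshold are kept. ``per='peak'``
    applies the same rule to per-peak coverage instead.
    """
    if pairs.empty:
        logger.warning("filter_low_coverage: no pairs to filter")
        return pairs.copy()
    cov = pd.Series(data.coverage,
                    index=data.peaks["peak_id"].to_numpy())
    if per == "gene":
        totals = (pairs.assign(cov=pairs["peak_id"].map(cov))
                  .groupby("gene")["cov"].sum())
        thresh = _nearest_rank_quantile(totals.to_numpy(),
                                        1.0 - keep_top_fraction)
        keep_genes = set(totals.index[totals >= thresh])
        out = pairs[pairs["gene"].isin(keep_genes)].reset_index(drop=True)
    elif per == "peak":
        peak_cov = pairs["peak_id"].map(cov)
        thresh = _nearest_rank_quantile(
            cov.loc[pairs["peak_id"].unique()].to_numpy(),
            1.0 - keep_top_fraction)
        out = pairs[peak_cov.to_numpy() >= thresh].reset_index(drop=True)
    else:
        raise ValueError("per must be 'gene' or 'peak'")
    logger.info("filter_low_coverage: %d -> %d pair(s)", len(pairs), len(out))
    return out


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank threshold above which the top (1-q) fraction lies.

    Returns the (floor(q*n)+1)-th smallest value so that exactly
    ceil((1-q)*n) values sit at or above it; with q = 0.75 on four values
    this is the largest one (keep the top quarter). Ties at the threshold
    are kept by callers comparing with >=.
    """
    v = np.sort(values)
    rank = int(np.floor(q * len(v) + 1e-9)) + 1
    return float(v[min(max(rank, 1), len(v)) - 1])


def test_peak(accessible: np.ndarray, sample_ids: np.ndarray,
              case: np.ndarray, age: np.ndarray, sex: np.ndarray,
              min_accessibility: float = MIN_ACCESSIBILITY,
              mixed: bool = True) -> dict:
    """Binomial LRT of one peak's binarized accessibility vs case status.

    Inputs are per-cell vectors (cells restricted to one lineage and one
    visit); covariates are sample-level so the fit collapses cells to
    per-sample binomial counts. Returns a dict with beta_case, lrt_p,
    evaluated, converter_related and a skip reason where applicable.
    ``mixed=False`` drops the per-sample random intercept (plain GLM).
    """
    accessible = np.asarray(accessible, dtype=float)
    frac = accessible.mean() if len(accessible) else 0.0
    base = {"beta_case": np.nan, "lrt_p": np.nan, "evaluated": False,
            "converter_related": False, "accessible_fraction": float(frac)}
    if frac < min_accessibility:
        base["reason"] = "sparse"
        return base
    if accessible.min() == accessible.max():
        base["reason"] = "constant outcome"
        return base

    frame = pd.DataFrame({"sample": sample_ids, "y": accessible,
                          "case": case, "age": age, "sex": sex})
    agg = frame.groupby("sample").agg(
        y=("y", "sum"), n=("y", "size"), case=("case", "first"),
        age=("age", "first"), sex=("sex", "first")).reset_index()
    age_v = agg["age"].to_numpy(float)
    age_std = (age_v - age_v.mean()) / (age_v.std() or 1.0)
    X_null = np.column_stack([np.ones(len(agg)), age_std,
                              agg["sex"].to_numpy(float)])
    X_full = np.column_stack([X_null, agg["case"].to_numpy(float)])
    y, n = agg["y"].to_numpy(float), agg["n"].to_numpy(float)
    groups = [np.arange(len(agg))] if mixed else None

    if mixed:
        null = fit_binomial_mixed(y, n, X_null, groups)
        full = fit_binomial_mixed(y, n, X_full, groups)
        ll0, ll1 = null.loglik, full.loglik
        beta_case = float(full.beta[-1])
        ok = null.converged and full.converged
    else:
        import statsmodels.api as sm
        endog = np.column_stack([y, n - y])
        null = sm.GLM(endog, X_null, family=sm.families.Binomial()).fit()
        full = sm.GLM(endog, X_full, family=sm.families.Binomial()).fit()
        ll0, ll1 = float(null.llf), float(full.llf)
        beta_case = float(full.params[-1])
        ok = True
    p = lrt(ll0, ll1, 1)
    base.update({
        "beta_case": beta_case, "lrt_p": p, "evaluated": True,
        "converter_related": bool(p < 0.05 and beta_case > 0 and ok),
        "converged": bool(ok),
    })
    return base


def converter_peaks(data: AccessibilityData, cells: pd.DataFrame,
                    clinical: pd.DataFrame, lineage: str, visit: str,
                    window: int = WINDOW_BP,
                    keep_top_fraction: float = 0.25,
                    min_accessibility: float = MIN_ACCESSIBILITY,
                    mixed: bool = True) -> tuple[pd.DataFrame, dict]:
    """Run the full staged Converter-peak procedure for one lineage/visit.

    Returns (results frame, stage counts). The counts record pairs ->
    coverage-filtered -> evaluated -> converter_related and are logged.
    """
    pairs = assign_gene_windows(data, window=window)
    kept = filter_low_coverage(pairs, data, keep_top_fraction)

    meta = cells.merge(clinical[["subject_id", "group", "age", "sex"]],
                       on="subject_id", how="left")
    mask = (meta["lineage"] == lineage) & (meta["visit"] == visit)
    meta = meta.loc[mask]
    cell_ix = {c: j for j, c in enumerate(data.cell_ids)}
    rows_ix = np.array([cell_ix[c] for c in meta["cell_id"]])
    case = (meta["group"] == "Converter").to_numpy(float)
    age = meta["age"].to_numpy(float)
    sex = (meta["sex"] == "M").to_numpy(float)
    sample_ids = meta["sample_id"].to_numpy()
    dense = np.asarray(data.matrix[rows_ix, :].todense())
    peak_col = {p: j for j, p in enumerate(data.peaks["peak_id"])}

    results = []
    for (gene, peak_id), _ in kept.groupby(["gene", "peak_id"]):
        res = test_peak(dense[:, peak_col[peak_id]], sample_ids, case,
                        age, sex, min_accessibility=min_accessibility,
                        mixed=mixed)
        res.update({"gene": gene, "peak_id": peak_id,
                    "lineage": lineage, "visit": visit})
        results.append(res)
    out = pd.DataFrame(results)
    stage_counts = {
        "pairs": int(len(pairs)),
        "coverage_filtered": int(len(kept)),
        "evaluated": int(out["evaluated"].sum()) if len(out) else 0,
        "converter_related": (int(out["converter_related"].sum())
                              if len(out) else 0),
    }
    logger.info("converter_peaks[%s,%s]: %s", lineage, visit, stage_counts)
    return out, stage_counts


def conservation_compare(foreground: pd.DataFrame, background: pd.DataFrame,
                         track: ConservationTrack) -> tuple[float, float]:
    """One-sided rank-sum comparison of mean conservation, fg > bg.

    Peaks with no track coverage are flagged (NaN) and excluded; the
    effect is the difference in median per-peak mean scores.
    """
    if foreground.empty:
        raise ValueError("foreground peak set is empty")
    if background.empty:
        raise ValueError("background peak set is empty")

    def scores(peaks):
        vals = np.array([track.mean_score(c, s, e) for c, s, e in
                         zip(peaks["chrom"], peaks["start"], peaks["end"])])
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.warning("conservation_compare: %d/%d peak(s) missing "
                           "from track", n_missing, len(vals))
        if n_missing > 0.1 * len(vals):
            raise ValueError("conservation track covers <90% of peaks")
        return vals[~np.isnan(vals)]

    fg, bg = scores(foreground), scores(background)
    res = stats.mannwhitneyu(fg, bg, alternative="greater",
                             method="asymptotic")
    effect = float(np.median(fg) - np.median(bg))
    return effect, float(res.pvalue)
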