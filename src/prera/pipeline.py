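"""End-to-end orchestration of the analysis stages from a JSON config.

A run executes the requested stages in dependency order on a working
directory: ``simulate`` writes the synthetic cohort bundle
(CSV/TSV/BED/MTX), and each downstream stage reads the files it needs
from that directory and writes its own artifacts. The manifest records,
per stage, the seed used, record counts, and a SHA-256 hash of every
output file, so deterministic stages can be checked for bit-identical
reruns. The config schema is strict: unknown keys are fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, atac, cdr3, expression, integration
from . import prediction, repertoire as rep
from . import synthetic as syn
from . import io as pio

logger = logging.getLogger("prera")

STAGES = ("simulate", "associate", "repertoire", "cdr3risk", "de", "gsea",
          "atac", "transfer", "predict")

#: Per-stage defaults mirroring the study's printed settings.
STAGE_DEFAULTS = {
    "simulate": {"n_subjects_per_group": 10, "cells_per_sample": 400,
                 "planted_log_or": {"Tph": float(np.log(1.5))},
                 "group_score_shift": 0.3, "effect_log_or": 0.7,
                 "n_peaks": 60, "n_effect_peaks": 10,
                 "n_genes": 150, "n_de_genes": 12},
    "associate": {"visit": "V0"},
    "repertoire": {"top_n": 20},
    "cdr3risk": {"chains": 4, "iterations": 2000},
    "de": {"visit": "V0"},
    "gsea": {"n_perm": 2000},
    "atac": {"lineage": "T", "visit": "V0", "window": 500_000,
             "min_accessibility": 0.05, "keep_top_fraction": 0.25},
    "transfer": {"k": 30},
    "predict": {"max_depth": 4, "min_bucket": 1, "cp": 0.0,
                "priors": [0.5, 0.5]},
}
_TOP_KEYS = {"stages", "seed", "outdir", "params"}


class ConfigError(pio.PreraError):
    pass


class DependencyError(pio.PreraError):
    pass


def load_config(obj) -> dict:
    """Validate a run config (dict or path to JSON); strict schema."""
    if not isinstance(obj, dict):
        with open(obj) as fh:
            obj = json.load(fh)
    unknown = set(obj) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {"stages": obj.get("stages", list(STAGES)),
           "seed": int(obj.get("seed", 0)),
           "outdir": obj.get("outdir", "prera_run"),
           "params": obj.get("params", {})}
    for st in cfg["stages"]:
        if st not in STAGES:
            raise ConfigError(f"unknown stage {st!r}")
    for st, block in cfg["params"].items():
        if st not in STAGES:
            raise ConfigError(f"params for unknown stage {st!r}")
        unknown = set(block) - set(STAGE_DEFAULTS[st])
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in stage {st!r}")
    return cfg


def _stage_params(cfg, stage) -> dict:
    p = dict(STAGE_DEFAULTS[stage])
    p.update(cfg["params"].get(stage, {}))
    return p


def _stage_seed(cfg, stage) -> int:
    return (cfg["seed"] * 1009 + STAGES.index(stage) * 101) % (2 ** 31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(outdir: Path, name: str, stage: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise DependencyError(
            f"stage {stage!r} needs {name}, produced by an earlier stage")
    return p


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _run_simulate(outdir: Path, params: dict, seed: int) -> dict:
    cs = syn.CohortSpec(
        n_subjects_per_group=params["n_subjects_per_group"],
        cells_per_sample=params["cells_per_sample"],
        planted_log_or=params["planted_log_or"], seed=seed)
    clinical, cells = syn.generate_cohort(cs)
    coeffs = syn.generate_coefficients(seed=seed + 1)
    clono = syn.generate_repertoire(
        syn.RepertoireSpec(group_score_shift=params["group_score_shift"],
                           seed=seed + 2),
        cells, coeffs)
    acc = syn.generate_accessibility(
        syn.PeakSpec(n_peaks=params["n_peaks"],
                     n_effect_peaks=params["n_effect_peaks"],
                     effect_log_or=params["effect_log_or"], seed=seed + 3),
        cells)
    tph = (cells[cells["visit"] == "V0"].groupby("subject_id")
           .apply(lambda s: (s["cluster"] == "Tph").mean(), include_groups=False)
           .rename("tph_frac"))
    clinical = clinical.merge(tph, left_on="subject_id", right_index=True)
    clinical = syn.generate_survival(
        clinical, {"tph_frac": np.log(2.0), "ccp3": 0.3}, seed=seed + 4)
    expr, de_genes = _synthesize_expression(
        cells, params["n_genes"], params["n_de_genes"], seed=seed + 5)

    pio.write_cell_table(cells, outdir / "cells.csv")
    pio.write_clinical(clinical, outdir / "clinical.csv")
    pio.write_airr(clono, outdir / "airr.tsv")
    pio.write_coefficients(coeffs, outdir / "coefficients.tsv")
    pio.write_bed(acc.peaks, outdir / "peaks.bed")
    pio.write_mtx(acc.matrix, outdir / "accessibility.mtx")
    pd.DataFrame({"peak_id": acc.peaks["peak_id"],
                  "coverage": acc.coverage,
                  "planted_effect": acc.peaks["planted_effect"]}).to_csv(
        outdir / "coverage.tsv", sep="\t", index=False)
    acc.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(expr.values, index=expr.genes,
                 columns=expr.cells).to_csv(outdir / "expression.tsv",
                                            sep="\t")
    with open(outdir / "de_genes.json", "w") as fh:
        json.dump(de_genes, fh)
    return {"n_cells": len(cells), "n_subjects": len(clinical),
            "n_clonotypes": len(clono), "n_peaks": len(acc.peaks)}


def _synthesize_expression(cells: pd.DataFrame, n_genes: int,
                           n_de: int, seed: int):
    """Log-normal expression for T cells with a planted Converter program."""
    rng = np.random.default_rng(seed)
    sub = cells[(cells["lineage"] == "T") & (cells["visit"] == "V0")]
    sub = sub.iloc[:: max(1, len(sub) // 1500)]  # thin for tractability
    genes = [f"G{j:04d}" for j in range(n_genes)]
    vals = rng.lognormal(0.0, 0.4, size=(n_genes, len(sub)))
    vals = np.log1p(vals)
    is_conv = sub["subject_id"].str.startswith("C").to_numpy()
    vals[:n_de, is_conv] += 1.2
    expr = expression.ExpressionMatrix(vals, genes,
                                       sub["cell_id"].tolist())
    return expr, genes[:n_de]


def _read_expression(outdir: Path, stage: str):
    df = pd.read_csv(_need(outdir, "expression.tsv", stage), sep="\t",
                     index_col=0)
    return expression.ExpressionMatrix(df.to_numpy(), list(df.index),
                                       list(df.columns))


def _run_associate(outdir: Path, params: dict, seed: int) -> dict:
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "associate"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "associate"))
    res = association.associate_clusters(cells, clinical,
                                         visit=params["visit"])
    res.to_csv(outdir / "association.tsv", sep="\t", index=False)
    return {"n_clusters": len(res),
            "n_significant": int((res["lrt_p"] < 0.05).sum())}


def _run_repertoire(outdir: Path, params: dict, seed: int) -> dict:
    clono = pio.read_airr(_need(outdir, "airr.tsv", "repertoire"))
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "repertoire"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "repertoire"))
    meta = cells.merge(clinical[["subject_id", "group"]], on="subject_id")
    curve = rep.diversity_curve(clono[clono["chain"] == "TRB"], meta)
    curve.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    top = rep.top_expanded_clones(clono[clono["chain"] == "TRB"], meta,
                                  n=params["top_n"])
    top.to_csv(outdir / "top_clones.tsv", sep="\t", index=False)
    return {"n_diversity_rows": len(curve), "n_top_rows": len(top)}


def _run_cdr3risk(outdir: Path, params: dict, seed: int) -> dict:
    clono = pio.read_airr(_need(outdir, "airr.tsv", "cdr3risk"))
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "cdr3risk"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "cdr3risk"))
    coeffs = pio.read_coefficients(_need(outdir, "coefficients.tsv",
                                         "cdr3risk"))
    meta = cells.merge(clinical[["subject_id", "group"]],
                       on="subject_id")[["cell_id", "sample_id", "group",
                                         "visit"]]
    scores = cdr3.score_table(clono, meta, coeffs)
    scores.to_csv(outdir / "cdr3_scores.tsv", sep="\t", index=False)
    fit = cdr3.fit_zi_gaussian(scores)
    contrasts = [(("Converter", "V0"), ("Nonconverter", "V0")),
                 (("Converter", "V1"), ("Nonconverter", "V1")),
                 (("Converter", "V1"), ("Converter", "V0"))]
    zi = {f"{a[0]}:{a[1]}>{b[0]}:{b[1]}":
          cdr3.one_sided_contrast(fit, (a, b)) for a, b in contrasts}
    post, diag = cdr3.bayes_compare(scores, level="cell",
                                    contrasts=contrasts,
                                    chains=params["chains"],
                                    iterations=params["iterations"],
                                    seed=seed)
    out = {"zero_inflated_one_sided_p": zi,
           "posterior": [{"contrast": list(map(list, r.contrast)),
                          "prob_greater": r.prob_greater,
                          "mean_diff": r.mean_diff,
                          "rhat_max": r.rhat_max} for r in post],
           "sigma": fit.sigma, "loglik": fit.loglik, "seed": seed}
    with open(outdir / "cdr3_inference.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return {"n_scored": len(scores),
            "max_rhat": max(r.rhat_max for r in post)}


def _run_de(outdir: Path, params: dict, seed: int) -> dict:
    expr = _read_expression(outdir, "de")
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "de"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "de"))
    meta = cells.merge(clinical[["subject_id", "group"]], on="subject_id")
    meta = meta[meta["cell_id"].isin(expr.cells)]
    a = meta.loc[meta["group"] == "Converter", "cell_id"]
    b = meta.loc[meta["group"] == "Nonconverter", "cell_id"]
    res = expression.wilcoxon_de(expr, a, b)
    res.to_csv(outdir / "de.tsv", sep="\t", index=False)
    return {"n_genes": len(res),
            "n_significant": int(res["significant"].sum())}


def _run_gsea(outdir: Path, params: dict, seed: int) -> dict:
    de = pd.read_csv(_need(outdir, "de.tsv", "gsea"), sep="\t")
    expr = _read_expression(outdir, "gsea")
    with open(_need(outdir, "de_genes.json", "gsea")) as fh:
        gene_set = json.load(fh)
    ranks = pd.Series(de["log2fc"].to_numpy(), index=de["gene"])
    det = expression.detection_fraction(expr)
    res = expression.gsea_preranked(ranks, gene_set, det,
                                    n_perm=params["n_perm"], seed=seed,
                                    gene_set_name="planted_program")
    with open(outdir / "gsea.json", "w") as fh:
        json.dump(res, fh, indent=2)
    return {"es": res["es"], "nes": res["nes"], "p": res["p"]}


def _run_atac(outdir: Path, params: dict, seed: int) -> dict:
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "atac"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "atac"))
    peaks = pio.read_bed(_need(outdir, "peaks.bed", "atac"))
    cov = pd.read_csv(_need(outdir, "coverage.tsv", "atac"), sep="\t")
    genes = pd.read_csv(_need(outdir, "genes.tsv", "atac"), sep="\t")
    matrix = pio.read_mtx(_need(outdir, "accessibility.mtx", "atac"))
    data = pio.AccessibilityData(
        peaks=peaks, coverage=cov["coverage"].to_numpy(), matrix=matrix,
        cell_ids=cells["cell_id"].tolist(), genes=genes)
    res, counts = atac.converter_peaks(
        data, cells, clinical, lineage=params["lineage"],
        visit=params["visit"], window=params["window"],
        keep_top_fraction=params["keep_top_fraction"],
        min_accessibility=params["min_accessibility"])
    res.to_csv(outdir / "atac_results.tsv", sep="\t", index=False)
    return counts


def _run_transfer(outdir: Path, params: dict, seed: int) -> dict:
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "transfer"))
    rng = np.random.default_rng(seed)
    # synthetic joint embedding: per-cluster Gaussian blobs in 4-D
    clusters = sorted(cells["cluster"].unique())
    centers = {c: rng.normal(0.0, 3.0, size=4) for c in clusters}
    coords = np.vstack([centers[c] for c in cells["cluster"]])
    coords = coords + rng.normal(0.0, 0.8, size=coords.shape)
    half = len(cells) // 2
    ref, qry = coords[:half], coords[half:]
    ref_labels = cells["cluster"].to_numpy()[:half]
    qry_labels = cells["cluster"].to_numpy()[half:]
    assigned = integration.knn_transfer(ref, ref_labels, qry,
                                        k=params["k"])
    rate = integration.match_rate(assigned["label"], qry_labels)
    assigned.assign(cell_id=cells["cell_id"].to_numpy()[half:]).to_csv(
        outdir / "transfer_labels.tsv", sep="\t", index=False)
    rate.to_csv(outdir / "match_rate.tsv", sep="\t")
    diag = np.array([rate.loc[r, r] for r in rate.index if r in rate.columns])
    return {"n_query": len(qry), "mean_diagonal_match": float(diag.mean())}


def _run_predict(outdir: Path, params: dict, seed: int) -> dict:
    cells = pio.read_cell_table(_need(outdir, "cells.csv", "predict"))
    clinical = pio.read_clinical(_need(outdir, "clinical.csv", "predict"))
    v0 = cells[cells["visit"] == "V0"]
    t = v0[v0["lineage"] == "T"]

    def frac(cluster):
        num = t[t["cluster"] == cluster].groupby("subject_id").size()
        den = t.groupby("subject_id").size()
        return (num.reindex(den.index, fill_value=0) / den * 100.0)

    feats = pd.DataFrame({
        "tph_pct": frac("Tph"),
        "gzmk_cd8_pct": frac("GZMK_CD8"),
        "gzmb_cd8_pct": frac("GZMB_CD8"),
    })
    clin = clinical.set_index("subject_id")
    feats["age"] = clin["age"]
    feats["sex"] = (clin["sex"] == "M").astype(float)
    feats["ccp3"] = clin["ccp3"]
    feats["rf_positive"] = clin["rf_positive"].astype(float)
    feats["se_dosage"] = clin["se_dosage"].astype(float)
    outcome = (clin["group"] == "Converter").astype(int)

    imp = prediction.gini_importance(feats, outcome, seed=seed)
    imp.rename("importance").to_csv(outdir / "importance.tsv", sep="\t")
    cellular = ["tph_pct", "gzmk_cd8_pct", "gzmb_cd8_pct"]
    clinical_f = ["age", "sex", "ccp3", "rf_positive", "se_dosage"]
    aucs = {}
    for name, cols in (("cellular", cellular), ("clinical", clinical_f),
                       ("combined", cellular + clinical_f)):
        tree = prediction.fit_decision_tree(
            feats[cols], outcome, max_depth=params["max_depth"],
            min_bucket=params["min_bucket"], cp=params["cp"],
            priors=tuple(params["priors"]))
        risk = prediction.predict_tree(tree, feats[cols])
        auc, ci = prediction.roc_auc(risk, outcome.to_numpy(), seed=seed)
        aucs[name] = {"auc": auc, "ci": list(ci)}
        if name == "combined":
            with open(outdir / "tree.json", "w") as fh:
                json.dump(tree.to_dict(), fh, indent=2)

    conv = clinical[clinical["group"] == "Converter"].set_index("subject_id")
    conv = conv.join(feats[["tph_pct"]])
    bins = prediction.stratify_quantiles(conv["tph_pct"])
    conv["tph_bin"] = bins
    cox = prediction.fit_cox(conv, ["tph_bin"])
    cox.summary().to_csv(outdir / "cox.tsv", sep="\t", index=False)
    extreme = conv[conv["tph_bin"].isin(["bottom20", "top20"])]
    curves, chi2, p = prediction.km_logrank(extreme, extreme["tph_bin"])
    km = {lv: {"median": c["median"]} for lv, c in curves.items()}
    with open(outdir / "survival.json", "w") as fh:
        json.dump({"aucs": aucs, "logrank_chi2": chi2, "logrank_p": p,
                   "km_medians": km}, fh, indent=2)
    return {"auc_combined": aucs["combined"]["auc"],
            "logrank_p": p}


_STAGE_OUTPUTS = {
    "simulate": ["cells.csv", "clinical.csv", "airr.tsv",
                 "coefficients.tsv", "peaks.bed", "accessibility.mtx",
                 "coverage.tsv", "genes.tsv", "expression.tsv",
                 "de_genes.json"],
    "associate": ["association.tsv"],
    "repertoire": ["diversity.tsv", "top_clones.tsv"],
    "cdr3risk": ["cdr3_scores.tsv", "cdr3_inference.json"],
    "de": ["de.tsv"],
    "gsea": ["gsea.json"],
    "atac": ["atac_results.tsv"],
    "transfer": ["transfer_labels.tsv", "match_rate.tsv"],
    "predict": ["importance.tsv", "tree.json", "cox.tsv", "survival.json"],
}

_STAGE_FN = {
    "simulate": _run_simulate, "associate": _run_associate,
    "repertoire": _run_repertoire, "cdr3risk": _run_cdr3risk,
    "de": _run_de, "gsea": _run_gsea, "atac": _run_atac,
    "transfer": _run_transfer, "predict": _run_predict,
}


def run(config) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in cfg["stages"]]
    manifest = {"version": __version__, "seed": cfg["seed"], "stages": {}}
    for stage in ordered:
        seed = _stage_seed(cfg, stage)
        logger.info("running stage %s (seed %d)", stage, seed)
        counts = _STAGE_FN[stage](outdir, _stage_params(cfg, stage), seed)
        manifest["stages"][stage] = {
            "seed": seed,
            "counts": counts,
            "outputs": {n: _sha256(outdir / n)
                        for n in _STAGE_OUTPUTS[stage]
                        if (outdir / n).exists()},
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
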