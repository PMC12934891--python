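"""Synthetic cohorts with planted, recoverable effects.

Every generator is a pure function of its spec (the seed included): the
same spec yields byte-identical tables. The cohort layout mirrors a
two-group (Converter / Nonconverter), two-visit (V0 / V1) design with one
sample per subject and visit; planted effects are expressed on the same
scale the downstream estimators work on (log odds-ratios on cluster
logits and peak-accessibility logits, mean shifts on CDR3 risk scores,
log hazard ratios on event times), so each estimator can be checked for
parameter recovery against its generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import optimize

from .io import (AA_ALPHABET, AccessibilityData, RiskCoefficientTable,
                 SCORE_MAX_LEN, SCORE_MIN_LEN, SpecError)

__all__ = ["CohortSpec", "RepertoireSpec", "PeakSpec", "generate_cohort",
           "generate_repertoire", "generate_accessibility",
           "generate_survival", "generate_coefficients"]

# Default cluster catalogue: baseline proportions sum to 1, lineage per
# cluster. Tph at ~5% of cells mirrors its scale as a minority CD4 subset.
DEFAULT_CLUSTERS = {
    "Tph":        (0.050, "T"),
    "Tfh":        (0.040, "T"),
    "Treg":       (0.050, "T"),
    "NaiveCD4":   (0.200, "T"),
    "MemCD4":     (0.150, "T"),
    "GZMK_CD8":   (0.080, "T"),
    "GZMB_CD8":   (0.080, "T"),
    "NaiveB":     (0.080, "B"),
    "MemB":       (0.050, "B"),
    "DNB":        (0.020, "B"),
    "NK_CD56dim": (0.100, "NK"),
    "cM":         (0.100, "myeloid"),
}

FOLLOWUP_DAYS = 1095.0  # 36-month trial horizon

# Somatic hypermutation Beta laws per (group, visit): means mirror the
# observed contrast (Converters ~3.8% at baseline declining to ~3.5% at
# onset; Nonconverters slightly lower and rising), concentration 60.
_SHM_K = 60.0
DEFAULT_SHM_BETA = {
    ("Converter", "V0"): (0.0381 * _SHM_K, (1 - 0.0381) * _SHM_K),
    ("Converter", "V1"): (0.0351 * _SHM_K, (1 - 0.0351) * _SHM_K),
    ("Nonconverter", "V0"): (0.0300 * _SHM_K, (1 - 0.0300) * _SHM_K),
    ("Nonconverter", "V1"): (0.0315 * _SHM_K, (1 - 0.0315) * _SHM_K),
}


def _default_length_distribution() -> dict:
    # triangular-ish mass over CDR3 lengths 8..20, peaked at 14
    lengths = np.arange(8, 21)
    w = 7.0 - np.abs(lengths - 14)
    w = np.clip(w, 1.0, None) ** 2
    return dict(zip(lengths.tolist(), (w / w.sum()).tolist()))


@dataclass(frozen=True)
class CohortSpec:
    n_subjects_per_group: int = 20
    cells_per_sample: int = 2000
    cluster_baseline_props: dict = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_CLUSTERS.items()})
    cluster_lineages: dict = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_CLUSTERS.items()})
    planted_log_or: dict = field(default_factory=dict)
    sample_re_sd: float = 0.2
    n_batches: int = 4
    seed: int = 0

    def __post_init__(self):
        props = np.array(list(self.cluster_baseline_props.values()))
        if abs(props.sum() - 1.0) > 1e-12 or (props <= 0).any():
            raise SpecError("cluster_baseline_props must be a positive "
                            "probability vector summing to 1")
        if self.n_subjects_per_group < 2:
            raise SpecError("need at least 2 subjects per group")
        unknown = set(self.planted_log_or) - set(self.cluster_baseline_props)
        if unknown:
            raise SpecError(f"planted_log_or names unknown clusters {unknown}")


@dataclass(frozen=True)
class RepertoireSpec:
    clones_per_sample: int = 400
    clone_size_exponent: float = 1.2
    length_distribution: dict = field(
        default_factory=_default_length_distribution)
    group_score_shift: float = 0.0
    shm_beta_params: dict = field(
        default_factory=lambda: dict(DEFAULT_SHM_BETA))
    seed: int = 0

    def __post_init__(self):
        probs = np.array(list(self.length_distribution.values()))
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise SpecError("length_distribution must sum to 1")
        for ab in self.shm_beta_params.values():
            if min(ab) <= 0:
                raise SpecError("Beta parameters must be positive")


@dataclass(frozen=True)
class PeakSpec:
    n_peaks: int = 200
    n_effect_peaks: int = 20
    baseline_accessibility: float = 0.15
    effect_log_or: float = 0.0
    coverage_nb_mean: float = 200.0
    coverage_nb_dispersion: float = 2.0
    sample_re_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseline_accessibility < 1:
            raise SpecError("baseline_accessibility must lie in (0, 1)")
        if self.n_effect_peaks > self.n_peaks:
            raise SpecError("n_effect_peaks must not exceed n_peaks")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the clinical table and cell table of a two-visit cohort.

    Per sample, cell counts are multinomial over cluster proportions whose
    logits are shifted by the planted per-cluster log odds-ratio for
    Converters plus an iid Gaussian per-(sample, cluster) random intercept
    on the logit scale.
    """
    rng = np.random.default_rng(spec.seed)
    clusters = list(spec.cluster_baseline_props)
    base_logit = np.log(np.array(
        [spec.cluster_baseline_props[c] for c in clusters]))
    plant = np.array([spec.planted_log_or.get(c, 0.0) for c in clusters])

    subjects, cell_rows = [], []
    for gi, group in enumerate(("Converter", "Nonconverter")):
        for si in range(spec.n_subjects_per_group):
            sid = f"{'C' if gi == 0 else 'N'}{si:03d}"
            subjects.append({
                "subject_id": sid,
                "group": group,
                "arm": "placebo",
                "age": float(np.clip(rng.normal(55.0, 10.0), 25.0, 85.0)),
                "sex": "F" if rng.random() < 0.7 else "M",
                "ccp3": float(rng.lognormal(np.log(120.0), 0.8)),
                "rf_positive": bool(rng.random() < 0.5),
                "se_dosage": int(rng.choice([0, 1, 2], p=[0.35, 0.45, 0.2])),
                "time_to_event": FOLLOWUP_DAYS,
                "event": False,
            })
    clinical = pd.DataFrame(subjects)

    for _, subj in clinical.iterrows():
        is_conv = subj["group"] == "Converter"
        for visit in ("V0", "V1"):
            sample_id = f"{subj['subject_id']}_{visit}"
            logits = base_logit + rng.normal(
                0.0, spec.sample_re_sd, size=len(clusters))
            if is_conv:
                logits = logits + plant
            probs = np.exp(logits)
            probs /= probs.sum()
            counts = rng.multinomial(spec.cells_per_sample, probs)
            for c, k in zip(clusters, counts):
                if k:
                    cell_rows.append((sample_id, subj["subject_id"], visit,
                                      c, spec.cluster_lineages[c], int(k)))

    rows = pd.DataFrame(cell_rows, columns=[
        "sample_id", "subject_id", "visit", "cluster", "lineage", "count"])
    cells = rows.loc[rows.index.repeat(rows["count"])].drop(columns="count")
    cells = cells.reset_index(drop=True)
    cells["cell_id"] = [f"cell{j:07d}" for j in range(len(cells))]
    cells["modality"] = "citeseq"
    sample_ids = cells["sample_id"].unique()
    batch_of = {s: f"batch{j % spec.n_batches}"
                for j, s in enumerate(sorted(sample_ids))}
    cells["batch"] = cells["sample_id"].map(batch_of)
    cells = cells[["cell_id", "sample_id", "subject_id", "visit", "modality",
                   "batch", "lineage", "cluster"]]
    return clinical, cells


# ---------------------------------------------------------------------------
# Repertoire
# ---------------------------------------------------------------------------

def generate_coefficients(seed: int = 0, coverage: float = 0.35,
                          scale: float = 0.3) -> RiskCoefficientTable:
    """Draw a synthetic positional CDR3 coefficient table.

    A random ``coverage`` fraction of (length, position, amino-acid)
    triples over lengths 12-17 receives a Normal(0, scale) effect size;
    the rest score zero, which reproduces the sparse coefficient structure
    (and hence the excess of exact-zero scores) the scoring layer expects.
    """
    rng = np.random.default_rng(seed)
    beta = {}
    for length in range(SCORE_MIN_LEN, SCORE_MAX_LEN + 1):
        for pos in range(1, length + 1):
            for aa in AA_ALPHABET:
                if rng.random() < coverage:
                    beta[(length, pos, aa)] = float(rng.normal(0.0, scale))
    return RiskCoefficientTable(beta)


def _tilted_residue_law(coefficients, length, lam):
    """Per-position residue distributions proportional to exp(lam * beta)."""
    n_aa = len(AA_ALPHABET)
    mats = np.zeros((length, n_aa))
    for pos in range(1, length + 1):
        b = np.array([coefficients.lookup(length, pos, aa)
                      for aa in AA_ALPHABET])
        w = np.exp(lam * b - (lam * b).max())
        mats[pos - 1] = w / w.sum()
    return mats


def _expected_score(coefficients, length, residue_law):
    total = 0.0
    for pos in range(1, length + 1):
        b = np.array([coefficients.lookup(length, pos, aa)
                      for aa in AA_ALPHABET])
        total += float(residue_law[pos - 1] @ b)
    return total


def _solve_tilt(coefficients, length_distribution, shift):
    """Find lam so the expected risk score exceeds the uniform-residue
    expectation by ``shift``, averaging over scored lengths."""
    scored = {l: p for l, p in length_distribution.items()
              if SCORE_MIN_LEN <= l <= SCORE_MAX_LEN and p > 0}
    if not scored:
        raise SpecError("length_distribution puts no mass on lengths 12-17")
    mass = sum(scored.values())

    def gap(lam):
        total = 0.0
        for length, p in scored.items():
            tilted = _tilted_residue_law(coefficients, length, lam)
            unif = np.full_like(tilted, 1.0 / len(AA_ALPHABET))
            total += (p / mass) * (
                _expected_score(coefficients, length, tilted)
                - _expected_score(coefficients, length, unif))
        return total - shift

    if shift == 0.0:
        return 0.0
    hi = 1.0
    while gap(hi) < 0 and hi < 64:
        hi *= 2.0
    if gap(hi) < 0:
        raise SpecError(f"cannot plant score shift {shift}: coefficient "
                        "table too weak")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-6))


def generate_repertoire(spec: RepertoireSpec, cells: pd.DataFrame,
                        coefficients: RiskCoefficientTable,
                        group_of_subject: dict | None = None) -> pd.DataFrame:
    """Draw a clonotype table matching a cell table.

    T-lineage cells receive TRB chains whose clone sizes follow a rank
    power law (P(clone r) ~ r^-exponent) and whose CDR3 lengths follow the
    spec distribution; in Converter samples residues are drawn from an
    exponentially tilted law calibrated so the expected risk score exceeds
    the Nonconverter (uniform-residue) expectation by
    ``group_score_shift``. B-lineage cells receive IGH chains with
    isotypes and Beta-distributed mutation frequencies per (group, visit).
    """
    if spec.group_score_shift != 0.0 and coefficients.is_empty:
        raise SpecError("nonzero group_score_shift requires a non-empty "
                        "coefficient table")
    rng = np.random.default_rng(spec.seed)
    lengths = np.array(list(spec.length_distribution))
    lprobs = np.array(list(spec.length_distribution.values()))
    lam = (_solve_tilt(coefficients, spec.length_distribution,
                       spec.group_score_shift)
           if spec.group_score_shift else 0.0)
    tilted_laws = {
        int(l): _tilted_residue_law(coefficients, int(l), lam)
        for l in lengths if SCORE_MIN_LEN <= l <= SCORE_MAX_LEN
    } if lam else {}
    aa = np.array(list(AA_ALPHABET))
    isotypes = np.array(["IGHM", "IGHG1", "IGHG3", "IGHA1"])

    rows = []
    for sample_id, sub in cells.groupby("sample_id"):
        subject = sub["subject_id"].iloc[0]
        # group comes from the clinical mapping when given, else from the
        # C/N subject-id prefix generate_cohort assigns
        if group_of_subject is not None:
            is_conv = group_of_subject[subject] == "Converter"
        else:
            is_conv = subject.startswith("C")
        visit = sub["visit"].iloc[0]
        group = "Converter" if is_conv else "Nonconverter"

        tcells = sub.loc[sub["lineage"] == "T", "cell_id"].to_numpy()
        if len(tcells):
            n_clones = min(spec.clones_per_sample, len(tcells))
            w = np.arange(1, n_clones + 1, dtype=float) ** (
                -spec.clone_size_exponent)
            w /= w.sum()
            assign = rng.choice(n_clones, size=len(tcells), p=w)
            clone_len = rng.choice(lengths, size=n_clones, p=lprobs)
            clone_cdr3 = []
            for ci in range(n_clones):
                L = int(clone_len[ci])
                if is_conv and L in tilted_laws:
                    seq = "".join(
                        aa[rng.choice(20, p=tilted_laws[L][pos])]
                        for pos in range(L))
                else:
                    seq = "".join(rng.choice(aa, size=L))
                clone_cdr3.append(seq)
            vgenes = rng.choice(
                [f"TRBV{k}" for k in (2, 5, 7, 9, 12, 19, 20, 28)],
                size=n_clones)
            for cid, ci in zip(tcells, assign):
                rows.append((cid, "TRB", clone_cdr3[ci], vgenes[ci],
                             f"{sample_id}_T{ci:04d}", np.nan, np.nan))

        bcells = sub.loc[sub["lineage"] == "B", "cell_id"].to_numpy()
        if len(bcells):
            n_clones = max(1, min(spec.clones_per_sample // 2, len(bcells)))
            w = np.arange(1, n_clones + 1, dtype=float) ** (
                -spec.clone_size_exponent)
            w /= w.sum()
            assign = rng.choice(n_clones, size=len(bcells), p=w)
            clone_len = rng.choice(lengths, size=n_clones, p=lprobs)
            clone_cdr3 = ["".join(rng.choice(aa, size=int(L)))
                          for L in clone_len]
            vgenes = rng.choice(
                [f"IGHV{k}" for k in (1, 3, 4, 5)], size=n_clones)
            a, b = spec.shm_beta_params.get((group, visit), (2.0, 60.0))
            mf = rng.beta(a, b, size=len(bcells))
            iso = rng.choice(isotypes, size=len(bcells),
                             p=[0.35, 0.35, 0.15, 0.15])
            for j, (cid, ci) in enumerate(zip(bcells, assign)):
                rows.append((cid, "IGH", clone_cdr3[ci], vgenes[ci],
                             f"{sample_id}_B{ci:04d}", iso[j],
                             float(mf[j])))

    return pd.DataFrame(rows, columns=[
        "cell_id", "chain", "cdr3_aa", "v_gene", "clone_id", "isotype",
        "mutation_frequency"])


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------

def generate_accessibility(spec: PeakSpec, cells: pd.DataFrame,
                           group_of_subject: dict | None = None
                           ) -> AccessibilityData:
    """Draw a Bernoulli peak-accessibility bundle for a cell table.

    Per-cell accessibility of peak p has logit(baseline) shifted by
    effect_log_or for Converter cells at effect peaks, plus a per-sample
    Gaussian intercept shared across peaks of the sample. Coverage is
    negative-binomial per peak, and gene anchors are laid out densely
    enough that every peak falls within at least one +/-500 kb window.
    """
    rng = np.random.default_rng(spec.seed)
    starts = np.sort(rng.choice(
        np.arange(1, 4000), size=spec.n_peaks, replace=False)) * 10_000
    peaks = pd.DataFrame({
        "peak_id": [f"peak{j:05d}" for j in range(spec.n_peaks)],
        "chrom": "chr1",
        "start": starts,
        "end": starts + 500,
    })
    is_effect = np.zeros(spec.n_peaks, dtype=bool)
    is_effect[rng.choice(spec.n_peaks, size=spec.n_effect_peaks,
                         replace=False)] = True
    peaks["planted_effect"] = is_effect

    nb_n = spec.coverage_nb_dispersion
    nb_p = nb_n / (nb_n + spec.coverage_nb_mean)
    coverage = rng.negative_binomial(nb_n, nb_p, size=spec.n_peaks)

    sample_codes, sample_index = pd.factorize(cells["sample_id"])
    if group_of_subject is not None:
        is_conv = (cells["subject_id"].map(group_of_subject)
                   == "Converter").to_numpy()
    else:
        is_conv = cells["subject_id"].str.startswith("C").to_numpy()
    base = np.log(spec.baseline_accessibility
                  / (1 - spec.baseline_accessibility))

    cols = []
    for j in range(spec.n_peaks):
        # independent per-(sample, peak) Gaussian intercept: matches the
        # per-peak mixed model fitted downstream
        sample_re = rng.normal(0.0, spec.sample_re_sd,
                               size=len(sample_index))
        logit = base + sample_re[sample_codes]
        if is_effect[j] and spec.effect_log_or:
            logit = logit + spec.effect_log_or * is_conv
        p = 1.0 / (1.0 + np.exp(-logit))
        cols.append(scipy.sparse.csc_matrix(
            (rng.random(len(cells)) < p).astype(np.int8)[:, None]))
    matrix = scipy.sparse.hstack(cols, format="csc")

    # gene anchors every 250 kb span the peak range, so each peak midpoint
    # lies inside >=1 +/-500 kb window
    lo = int(peaks["start"].min()) - 100_000
    hi = int(peaks["end"].max()) + 100_000
    anchors = np.arange(max(lo, 0), hi, 250_000)
    genes = pd.DataFrame({
        "gene": [f"gene{j:04d}" for j in range(len(anchors))],
        "chrom": "chr1",
        "anchor_position": anchors,
        "strand": rng.choice(["+", "-"], size=len(anchors)),
    })
    return AccessibilityData(peaks=peaks, coverage=coverage, matrix=matrix,
                             cell_ids=cells["cell_id"].tolist(), genes=genes)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(clinical: pd.DataFrame, feature_log_hrs: dict,
                      seed: int = 0,
                      baseline_median_days: float = 400.0,
                      followup_days: float = FOLLOWUP_DAYS) -> pd.DataFrame:
    """Attach exponential event times driven by baseline features.

    Converters draw event times from an exponential law whose log hazard
    is linear in the standardized named features (rate calibrated so the
    all-zero-covariate median is ``baseline_median_days``); Nonconverters
    are censored at the end of follow-up.
    """
    rng = np.random.default_rng(seed)
    out = clinical.copy()
    missing = [f for f in feature_log_hrs if f not in out.columns]
    if missing:
        raise SpecError(f"missing feature column(s): {missing}")
    lp = np.zeros(len(out))
    for feat, beta in feature_log_hrs.items():
        x = out[feat].astype(float).to_numpy()
        sd = x.std()
        if sd == 0:
            raise SpecError(f"feature {feat!r} has zero variance; its "
                            "planted effect is unidentifiable")
        lp += beta * (x - x.mean()) / sd
    rate0 = np.log(2.0) / baseline_median_days
    is_conv = (out["group"] == "Converter").to_numpy()
    times = rng.exponential(1.0 / (rate0 * np.exp(lp)))
    out.loc[is_conv, "time_to_event"] = times[is_conv]
    out.loc[is_conv, "event"] = True
    out.loc[~is_conv, "time_to_event"] = followup_days
    out.loc[~is_conv, "event"] = False
    return out
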