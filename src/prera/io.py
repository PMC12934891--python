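"""Domain tables, readers and writers for the pre-RA pipeline.

All tabular data are carried as validated :class:`pandas.DataFrame` objects
with fixed column contracts; the heavier containers (peak accessibility,
conservation track, CDR3 coefficient table) get small dedicated classes.
Readers reject rows that violate the type invariants and log counts of
accepted/rejected rows; write -> read round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from intervaltree import IntervalTree

logger = logging.getLogger("prera")

# ---------------------------------------------------------------------------
# Shared constants and errors
# ---------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

GROUPS = ("Converter", "Nonconverter")
ARMS = ("placebo", "HCQ")
VISITS = ("V0", "V0.5", "V1")
MODALITIES = ("citeseq", "masscytometry", "asapseq")
LINEAGES = ("T", "B", "NK", "myeloid")
CHAINS = ("TRB", "TRA", "IGH", "IGK", "IGL")
TCR_CHAINS = frozenset({"TRB", "TRA"})

#: CDR3 lengths carrying non-zero risk coefficients.
SCORE_MIN_LEN = 12
SCORE_MAX_LEN = 17


class PreraError(Exception):
    """Base class for package errors."""


class SchemaError(PreraError):
    """A required column or field is missing or has the wrong type."""


class IntegrityError(PreraError):
    """A table violates a uniqueness or consistency invariant."""


class SpecError(PreraError):
    """A generator or model specification is invalid."""


class NoContrastError(PreraError):
    """The case label does not vary, so no association can be estimated."""


class EmptyRepertoireError(PreraError):
    """A repertoire operation received no usable receptor records."""


class InvalidSequenceError(PreraError):
    """A CDR3 sequence contains characters outside the amino-acid alphabet."""


class DegenerateFitError(PreraError):
    """The data admit no non-trivial model fit (e.g. all scores zero)."""


class DegenerateStratificationError(PreraError):
    """Quantile stratification is impossible (e.g. constant feature)."""


class NoEventsError(PreraError):
    """Survival modelling requires at least one observed event."""


class FilteredToEmptyError(PreraError):
    """A filter removed every member of a gene set."""


CELL_COLUMNS = [
    "cell_id", "sample_id", "subject_id", "visit",
    "modality", "batch", "lineage", "cluster",
]
CLINICAL_COLUMNS = [
    "subject_id", "group", "arm", "age", "sex", "ccp3",
    "rf_positive", "se_dosage", "time_to_event", "event",
]
AIRR_COLUMNS = ["cell_id", "junction_aa", "v_call", "clone_id",
                "isotype", "mutation_frequency"]


def _read_table(path, fmt: str) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'tsv'")
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       na_values=[""])


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _log_counts(what: str, accepted: int, rejected: int) -> None:
    logger.info("%s: accepted %d row(s), rejected %d row(s)",
                what, accepted, rejected)


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------

def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell-level metadata table (one row per cell).

    Enforces: unique ``cell_id``; ``visit``/``modality``/``lineage`` drawn
    from their declared vocabularies; every ``sample_id`` maps to exactly
    one (subject, visit, modality). Rows with out-of-vocabulary labels are
    rejected with row-indexed diagnostics; structural violations raise.
    """
    _require_columns(df, CELL_COLUMNS, "cell table")
    df = df[CELL_COLUMNS].copy()
    bad = (~df["visit"].isin(VISITS)
           | ~df["modality"].isin(MODALITIES)
           | ~df["lineage"].isin(LINEAGES)
           | df[CELL_COLUMNS].isna().any(axis=1))
    if bad.any():
        idx = list(df.index[bad][:20])
        logger.warning("cell table: rejecting rows %s (invalid labels)", idx)
    out = df.loc[~bad].reset_index(drop=True)
    dup = out["cell_id"][out["cell_id"].duplicated()]
    if len(dup):
        raise IntegrityError(
            f"duplicate cell_id(s): {sorted(set(dup))[:10]}")
    nmap = out.groupby("sample_id")[["subject_id", "visit", "modality"]].nunique()
    broken = nmap.index[(nmap > 1).any(axis=1)]
    if len(broken):
        raise IntegrityError(
            f"sample_id(s) mapping to >1 (subject, visit, modality): "
            f"{list(broken)[:10]}")
    _log_counts("cell table", len(out), int(bad.sum()))
    return out


def read_cell_table(path, fmt: str = "csv") -> pd.DataFrame:
    return validate_cell_table(_read_table(path, fmt))


def write_cell_table(df: pd.DataFrame, path, fmt: str = "csv") -> None:
    df[CELL_COLUMNS].to_csv(path, sep={"csv": ",", "tsv": "\t"}[fmt],
                            index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-subject clinical table.

    ``event`` may be true only for Converters; ``se_dosage`` is 0/1/2;
    ``time_to_event`` must be positive wherever present.
    """
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    out = df.copy()
    out["age"] = out["age"].astype(float)
    out["ccp3"] = out["ccp3"].astype(float)
    out["se_dosage"] = out["se_dosage"].astype(int)
    out["time_to_event"] = out["time_to_event"].astype(float)
    for col in ("rf_positive", "event"):
        if out[col].dtype == object:
            out[col] = out[col].map(
                {"True": True, "False": False, True: True, False: False})
        out[col] = out[col].astype(bool)
    dup = out["subject_id"][out["subject_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate subject_id(s): {sorted(set(dup))}")
    if not out["group"].isin(GROUPS).all():
        raise SchemaError("clinical table: group must be Converter/Nonconverter")
    if not out["sex"].isin(["F", "M"]).all():
        raise SchemaError("clinical table: sex must be F/M")
    if not out["se_dosage"].isin([0, 1, 2]).all():
        raise SchemaError("clinical table: se_dosage must be 0, 1 or 2")
    if (out["event"] & (out["group"] != "Converter")).any():
        raise IntegrityError("event=True only permitted for Converters")
    if (out["time_to_event"].dropna() <= 0).any():
        raise IntegrityError("time_to_event must be positive")
    if (out["ccp3"] < 0).any():
        raise IntegrityError("ccp3 must be nonnegative")
    return out.reset_index(drop=True)


def read_clinical(path, fmt: str = "csv") -> pd.DataFrame:
    return validate_clinical(_read_table(path, fmt))


def write_clinical(df: pd.DataFrame, path, fmt: str = "csv") -> None:
    cols = [c for c in df.columns if c in CLINICAL_COLUMNS or c not in CLINICAL_COLUMNS]
    df[cols].to_csv(path, sep={"csv": ",", "tsv": "\t"}[fmt], index=False)


# ---------------------------------------------------------------------------
# AIRR rearrangement tables
# ---------------------------------------------------------------------------

def _chain_from_v_call(v_call: str) -> str | None:
    prefix = str(v_call)[:3]
    return prefix if prefix in CHAINS else None


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV into a clonotype table.

    Column mapping: ``junction_aa`` -> ``cdr3_aa``; ``v_call`` -> ``v_gene``
    with the allele suffix (``*01``) stripped; the chain is inferred from
    the locus prefix of the V call (TRB/TRA/IGH/IGK/IGL). Records whose
    junction contains characters outside the 20-letter amino-acid alphabet
    are rejected with a diagnostic; ``mutation_frequency`` is cleared for
    TCR chains, where somatic hypermutation is not defined.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      na_values=[""])
    _require_columns(raw, ["cell_id", "junction_aa", "v_call"], "AIRR table")
    out = pd.DataFrame({
        "cell_id": raw["cell_id"],
        "cdr3_aa": raw["junction_aa"].astype(str),
        "v_gene": raw["v_call"].astype(str).str.split("*").str[0],
    })
    out["chain"] = out["v_gene"].map(_chain_from_v_call)
    out["clone_id"] = raw.get("clone_id", pd.Series("", index=raw.index))
    out["isotype"] = raw["isotype"] if "isotype" in raw else np.nan
    mf = (pd.to_numeric(raw["mutation_frequency"], errors="coerce")
          if "mutation_frequency" in raw else np.nan)
    out["mutation_frequency"] = mf

    valid_seq = out["cdr3_aa"].map(lambda s: len(s) > 0 and set(s) <= AA_SET)
    bad = ~valid_seq | out["chain"].isna()
    if bad.any():
        logger.warning("AIRR table: rejecting rows %s (invalid junction_aa "
                       "or unrecognized locus)", list(raw.index[bad][:20]))
    out = out.loc[~bad].reset_index(drop=True)
    out.loc[out["chain"].isin(TCR_CHAINS), "mutation_frequency"] = np.nan
    mf_ok = out["mutation_frequency"].isna() | out["mutation_frequency"].between(0, 1)
    if not mf_ok.all():
        raise IntegrityError("mutation_frequency must lie in [0, 1]")
    _log_counts("AIRR table", len(out), int(bad.sum()))
    return out[["cell_id", "chain", "cdr3_aa", "v_gene", "clone_id",
                "isotype", "mutation_frequency"]]


def write_airr(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "cell_id": df["cell_id"],
        "junction_aa": df["cdr3_aa"],
        "v_call": df["v_gene"],
        "clone_id": df["clone_id"],
        "isotype": df.get("isotype"),
        "mutation_frequency": df.get("mutation_frequency"),
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CDR3 risk coefficient table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskCoefficientTable:
    """Positional CDR3beta risk coefficients, keyed (length, position, AA).

    Lengths are restricted to 12-17 and positions are 1-based within the
    CDR3. Lookups are total: absent keys score 0.
    """

    beta: dict = field(default_factory=dict)

    def lookup(self, length: int, position: int, aa: str) -> float:
        return self.beta.get((int(length), int(position), aa), 0.0)

    @property
    def is_empty(self) -> bool:
        return not self.beta

    def to_frame(self) -> pd.DataFrame:
        rows = [(l, p, a, b) for (l, p, a), b in sorted(self.beta.items())]
        return pd.DataFrame(rows, columns=["length", "position",
                                           "amino_acid", "beta"])


def read_coefficients(path) -> RiskCoefficientTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["length", "position", "amino_acid", "beta"],
                     "coefficient table")
    beta: dict = {}
    n_ignored = 0
    for _, row in df.iterrows():
        length, pos = int(row["length"]), int(row["position"])
        if not SCORE_MIN_LEN <= length <= SCORE_MAX_LEN:
            logger.warning("coefficient table: ignoring row with length %d "
                           "(outside %d-%d)", length, SCORE_MIN_LEN,
                           SCORE_MAX_LEN)
            n_ignored += 1
            continue
        key = (length, pos, str(row["amino_acid"]))
        if key in beta:
            raise IntegrityError(f"duplicate coefficient key {key}")
        beta[key] = float(row["beta"])
    _log_counts("coefficient table", len(beta), n_ignored)
    return RiskCoefficientTable(beta)


def write_coefficients(table: RiskCoefficientTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False,
                            float_format="%.17g")


# ---------------------------------------------------------------------------
# Peak accessibility bundle
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityData:
    """Peak intervals with per-cell binary accessibility.

    ``peaks``: DataFrame (peak_id, chrom, start, end), BED convention
    (0-based, half-open). ``coverage``: per-peak fragment counts aligned to
    ``peaks``. ``matrix``: cells x peaks sparse binary matrix with rows
    aligned to ``cell_ids``. ``genes``: DataFrame (gene, chrom,
    anchor_position, strand) where the anchor is the TSS.
    """

    peaks: pd.DataFrame
    coverage: np.ndarray
    matrix: scipy.sparse.spmatrix
    cell_ids: list
    genes: pd.DataFrame

    def __post_init__(self):
        if self.peaks["peak_id"].duplicated().any():
            raise IntegrityError("duplicate peak_id")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise IntegrityError("peak intervals must satisfy start < end")
        self.matrix = scipy.sparse.csc_matrix(self.matrix)
        if self.matrix.nnz and not np.isin(self.matrix.data, [0, 1]).all():
            raise IntegrityError("accessibility matrix must be binary")
        if self.matrix.shape != (len(self.cell_ids), len(self.peaks)):
            raise IntegrityError("matrix shape inconsistent with cells/peaks")
        self.coverage = np.asarray(self.coverage, dtype=int)
        if (self.coverage < 0).any():
            raise IntegrityError("coverage must be nonnegative")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "peak_id"],
                     usecols=[0, 1, 2, 3])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[["peak_id", "chrom", "start", "end"]]


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_mtx(path) -> scipy.sparse.csc_matrix:
    return scipy.sparse.csc_matrix(scipy.io.mmread(path))


def write_mtx(matrix, path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix))


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Per-interval evolutionary conservation scores in [0, 1].

    Queries return the overlap-weighted mean score of covering elements;
    intervals with no coverage return NaN (a flagged absent value), never 0.
    """

    def __init__(self, elements: pd.DataFrame):
        _require_columns(elements, ["chrom", "start", "end", "score"],
                         "conservation track")
        if ((elements["score"] < 0) | (elements["score"] > 1)).any():
            raise IntegrityError("conservation scores must lie in [0, 1]")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in elements.groupby("chrom"):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), float(v))
                for s, e, v in zip(sub["start"], sub["end"], sub["score"]))

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        tree = self._trees.get(chrom)
        if tree is None:
            return float("nan")
        hits = tree.overlap(start, end)
        if not hits:
            return float("nan")
        total_w = total = 0.0
        for iv in hits:
            w = min(iv.end, end) - max(iv.begin, start)
            total_w += w
            total += w * iv.data
        return total / total_w
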