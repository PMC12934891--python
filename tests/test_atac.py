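import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from prera import synthetic as syn
from prera.atac import (assign_gene_windows, conservation_compare,
                        converter_peaks, filter_low_coverage)
from prera.atac import test_peak as peak_lrt  # alias: not a pytest test
from prera.io import AccessibilityData, ConservationTrack


def _bundle(peaks, genes, n_cells=4, coverage=None):
    peaks = pd.DataFrame(peaks, columns=["peak_id", "chrom", "start", "end"])
    genes = pd.DataFrame(genes, columns=["gene", "chrom", "anchor_position",
                                         "strand"])
    cov = coverage if coverage is not None else np.ones(len(peaks), int)
    mat = scipy.sparse.csc_matrix(
        np.zeros((n_cells, len(peaks)), dtype=np.int8))
    return AccessibilityData(peaks=peaks, coverage=cov, matrix=mat,
                             cell_ids=[f"c{i}" for i in range(n_cells)],
                             genes=genes)


class TestAssignGeneWindows:
    def test_boundary_conventions(self):
        data = _bundle(
            peaks=[("p_center", "chr1", 999_750, 1_000_250),   # mid at anchor
                   ("p_edge", "chr1", 1_499_750, 1_500_250),   # mid = +500kb
                   ("p_in", "chr1", 1_499_749, 1_500_249)],    # mid = +499999
            genes=[("G", "chr1", 1_000_000, "+")])
        pairs = assign_gene_windows(data)
        got = dict(zip(pairs["peak_id"], pairs["distance"]))
        assert got.get("p_center") == 0
        assert "p_edge" not in got          # half-open right boundary
        assert got.get("p_in") == 499_999

    def test_peak_between_two_genes(self):
        data = _bundle(
            peaks=[("p", "chr1", 1_299_900, 1_300_100)],
            genes=[("G1", "chr1", 1_000_000, "+"),
                   ("G2", "chr1", 1_600_000, "-")])
        pairs = assign_gene_windows(data)
        assert len(pairs) == 2
        assert set(pairs["gene"]) == {"G1", "G2"}

    def test_unknown_chromosome_skipped(self):
        data = _bundle(
            peaks=[("p1", "chr9", 100, 200), ("p2", "chr1", 999_900,
                                              1_000_100)],
            genes=[("G", "chr1", 1_000_000, "+")])
        pairs = assign_gene_windows(data)
        assert set(pairs["peak_id"]) == {"p2"}

    def test_agrees_with_brute_force(self, rng):
        n_peaks, n_genes = 60, 15
        starts = rng.integers(0, 5_000_000, size=n_peaks)
        anchors = rng.integers(0, 5_000_000, size=n_genes)
        data = _bundle(
            peaks=[(f"p{i}", "chr1", int(s), int(s) + 400)
                   for i, s in enumerate(starts)],
            genes=[(f"G{i}", "chr1", int(a), "+")
                   for i, a in enumerate(anchors)])
        pairs = assign_gene_windows(data)
        got = set(zip(pairs["gene"], pairs["peak_id"]))
        brute = set()
        for i, s in enumerate(starts):
            mid = s + 200
            for j, a in enumerate(anchors):
                if a - 500_000 <= mid < a + 500_000:
                    brute.add((f"G{j}", f"p{i}"))
        assert got == brute


class TestFilterLowCoverage:
    def _pairs_four_genes(self):
        pairs = pd.DataFrame({
            "gene": ["G1", "G2", "G3", "G4"],
            "peak_id": ["p1", "p2", "p3", "p4"],
            "distance": [0, 0, 0, 0]})
        data = _bundle(
            peaks=[(f"p{i}", "chr1", i * 1000, i * 1000 + 100)
                   for i in range(1, 5)],
            genes=[(f"G{i}", "chr1", i * 1000, "+") for i in range(1, 5)],
            coverage=np.array([10, 20, 30, 40]))
        return pairs, data

    def test_top_quartile_of_four(self):
        pairs, data = self._pairs_four_genes()
        out = filter_low_coverage(pairs, data, keep_top_fraction=0.25)
        assert list(out["gene"]) == ["G4"]

    def test_all_equal_all_kept(self):
        pairs, data = self._pairs_four_genes()
        data.coverage = np.array([7, 7, 7, 7])
        out = filter_low_coverage(pairs, data, keep_top_fraction=0.25)
        assert len(out) == 4

    def test_keep_everything_is_identity(self):
        pairs, data = self._pairs_four_genes()
        out = filter_low_coverage(pairs, data, keep_top_fraction=1.0)
        pd.testing.assert_frame_equal(out, pairs)

    def test_per_peak_mode(self):
        pairs, data = self._pairs_four_genes()
        out = filter_low_coverage(pairs, data, keep_top_fraction=0.5,
                                  per="peak")
        assert set(out["peak_id"]) == {"p3", "p4"}


class TestTestPeak:
    def _labels(self, n_cells=400, n_samples=8):
        rng = np.random.default_rng(0)
        sample = np.repeat([f"s{i}" for i in range(n_samples)],
                           n_cells // n_samples)
        case = np.repeat([1.0, 0.0], n_cells // 2)
        age = np.repeat(rng.normal(55, 8, n_samples),
                        n_cells // n_samples)
        sex = np.repeat(rng.integers(0, 2, n_samples).astype(float),
                        n_cells // n_samples)
        return sample, case, age, sex

    def test_sparse_gate(self):
        sample, case, age, sex = self._labels()
        acc = np.zeros(400)
        acc[:15] = 1.0   # 3.75% < 5%
        res = peak_lrt(acc, sample, case, age, sex)
        assert not res["evaluated"]
        assert res["reason"] == "sparse"

    def test_constant_outcome(self):
        sample, case, age, sex = self._labels()
        res = peak_lrt(np.ones(400), sample, case, age, sex)
        assert not res["evaluated"]
        assert res["reason"] == "constant outcome"

    def test_directional_rule(self):
        rng = np.random.default_rng(1)
        sample, case, age, sex = self._labels()
        p = np.where(case > 0, 0.45, 0.15)
        acc = (rng.random(400) < p).astype(float)
        res = peak_lrt(acc, sample, case, age, sex)
        assert res["evaluated"]
        assert res["converter_related"] == (res["lrt_p"] < 0.05
                                            and res["beta_case"] > 0)
        assert res["converter_related"]

    def test_glm_path(self):
        rng = np.random.default_rng(2)
        sample, case, age, sex = self._labels()
        acc = (rng.random(400) < 0.3).astype(float)
        res = peak_lrt(acc, sample, case, age, sex, mixed=False)
        assert res["evaluated"]
        assert np.isfinite(res["lrt_p"])

    def test_evaluated_monotone_in_gate(self, small_cohort):
        clinical, cells = small_cohort
        acc = syn.generate_accessibility(
            syn.PeakSpec(n_peaks=30, n_effect_peaks=0,
                         baseline_accessibility=0.08, seed=5), cells)
        counts = []
        for gate in (0.02, 0.05, 0.10, 0.2):
            _, c = converter_peaks(acc, cells, clinical, "T", "V0",
                                   min_accessibility=gate)
            counts.append(c["evaluated"])
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConservationCompare:
    def _track(self, fg_scores, bg_scores):
        rows = []
        peaks_fg, peaks_bg = [], []
        pos = 0
        for i, s in enumerate(fg_scores):
            rows.append(("chr1", pos, pos + 100, s))
            peaks_fg.append((f"f{i}", "chr1", pos, pos + 100))
            pos += 200
        for i, s in enumerate(bg_scores):
            rows.append(("chr1", pos, pos + 100, s))
            peaks_bg.append((f"b{i}", "chr1", pos, pos + 100))
            pos += 200
        track = ConservationTrack(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "score"]))
        cols = ["peak_id", "chrom", "start", "end"]
        return (pd.DataFrame(peaks_fg, columns=cols),
                pd.DataFrame(peaks_bg, columns=cols), track)

    def test_complete_separation(self, rng):
        fg, bg, track = self._track(rng.uniform(0.7, 0.9, 12),
                                    rng.uniform(0.1, 0.3, 12))
        effect, p = conservation_compare(fg, bg, track)
        assert p < 0.01
        assert effect > 0.3

    def test_identity_sets(self, rng):
        fg, _, track = self._track(rng.uniform(0.2, 0.8, 15),
                                   rng.uniform(0.2, 0.8, 5))
        effect, p = conservation_compare(fg, fg, track)
        assert effect == 0.0
        assert 0.4 < p < 0.6

    def test_planted_shift_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 20
        for _ in range(reps):
            fg, bg, track = self._track(
                np.clip(rng.normal(0.55, 0.15, 30), 0, 1),
                np.clip(rng.normal(0.35, 0.15, 150), 0, 1))
            _, p = conservation_compare(fg, bg, track)
            hits += p < 0.05
        assert hits >= 0.9 * reps

    def test_empty_foreground(self, rng):
        fg, bg, track = self._track(rng.uniform(0, 1, 5),
                                    rng.uniform(0, 1, 5))
        with pytest.raises(ValueError):
            conservation_compare(fg.iloc[:0], bg, track)


class TestStagedProcedure:
    def test_stage_counts_on_crafted_fixture(self, small_cohort):
        """Hand-countable fixture: window boundary, coverage quartile and
        the 5% sparsity gate each remove a known number of records."""
        clinical, cells = small_cohort
        n_cells = len(cells)
        rng = np.random.default_rng(9)
        # 4 peaks: p4 lies outside every gene window; per-gene coverages
        # 10/20/30/40 keep only G4; p_low is sparsely accessible.
        peaks = pd.DataFrame({
            "peak_id": ["p1", "p2", "p3", "p4"],
            "chrom": "chr1",
            "start": [999_900, 2_999_900, 4_999_900, 98_999_900],
            "end": [1_000_100, 3_000_100, 5_000_100, 99_000_100]})
        genes = pd.DataFrame({
            "gene": ["G1", "G2", "G3"],
            "chrom": "chr1",
            "anchor_position": [1_000_000, 3_000_000, 5_000_000],
            "strand": "+"})
        mat = np.zeros((n_cells, 4), dtype=np.int8)
        mat[:, 0] = rng.random(n_cells) < 0.3
        mat[:, 1] = rng.random(n_cells) < 0.02   # below the 5% gate
        mat[:, 2] = rng.random(n_cells) < 0.3
        mat[:, 3] = rng.random(n_cells) < 0.3
        data = AccessibilityData(
            peaks=peaks, coverage=np.array([10, 20, 40, 99]),
            matrix=scipy.sparse.csc_matrix(mat),
            cell_ids=cells["cell_id"].tolist(), genes=genes)
        res, counts = converter_peaks(data, cells, clinical, "T", "V0",
                                      keep_top_fraction=0.34)
        # pairs: p1-G1, p2-G2, p3-G3 (p4 outside all windows)
        assert counts["pairs"] == 3
        # top 34% of genes by coverage (10/20/40): threshold at the 2nd
        # nearest-rank value, so G2 and G3 survive
        assert counts["coverage_filtered"] == 2
        # p2 is under the 5% accessibility gate, leaving only p3
        assert counts["evaluated"] == 1
        assert set(res["peak_id"]) == {"p2", "p3"}
        assert not res.loc[res["peak_id"] == "p2", "evaluated"].iloc[0]
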