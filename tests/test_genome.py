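"""Featurization: oriented sequence extraction, windowed counts, signal means."""

import numpy as np
import pandas as pd
import pytest

from cpgprofiler import (
    GeneRecord,
    dinucleotide_density_matrix,
    extract_window_sequence,
    methylation_window_matrix,
    peak_overlap_proportion,
    signal_window_matrix,
    tss_signed_distance,
)
from cpgprofiler.genome import reverse_complement


def naive_window_counts(seq, dinucleotide, grid):
    """Independent per-position scan: count s[i:i+2] matches per window."""
    counts = np.zeros(grid.n_windows, dtype=int)
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == dinucleotide:
            counts[i // grid.window] += 1
    return counts


def naive_gene_counts(genome, gene, dinucleotide, grid):
    """Brute-force oracle for one gene: scan the reference-strand slice for
    the sense-strand dinucleotide (translated to the reference strand for
    minus genes), attribute by leftmost reference base, reverse for minus."""
    plus = GeneRecord(gene.gene_id, gene.chrom, gene.tss, "+")
    seq = extract_window_sequence(genome, plus, grid)
    target = dinucleotide if gene.strand == "+" else reverse_complement(dinucleotide)
    counts = naive_window_counts(seq, target, grid)
    return counts if gene.strand == "+" else counts[::-1]


class TestExtractWindowSequence:
    def test_plus_strand_identity_placement(self):
        chrom = "A" * 8000 + "CG" + "A" * 7998
        gene = GeneRecord("g", "c", 8000, "+")
        seq = extract_window_sequence({"c": chrom}, gene)
        assert seq[8000:8002] == "CG"
        assert len(seq) == 16000

    def test_minus_strand_palindromic_dinucleotide(self):
        chrom = "A" * 8000 + "CG" + "A" * 7998
        gene = GeneRecord("g", "c", 8000, "-")
        seq = extract_window_sequence({"c": chrom}, gene)
        assert seq[7998:8000] == "CG"

    def test_off_chromosome_padding_warns(self):
        gene = GeneRecord("g", "c", 100, "+")
        with pytest.warns(UserWarning, match="padding"):
            seq = extract_window_sequence({"c": "A" * 20000}, gene)
        assert seq[:7900] == "N" * 7900
        assert set(seq[7900:]) == {"A"}

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            extract_window_sequence({"c": "A" * 20000}, GeneRecord("g", "x", 8000, "+"))

    def test_minus_strand_is_reverse_complement(self, random_locus_set, small_grid):
        genome, genes = random_locus_set
        gene = next(g for g in genes if g.strand == "-")
        plus = GeneRecord(gene.gene_id, gene.chrom, gene.tss, "+")
        assert extract_window_sequence(genome, gene, small_grid) == reverse_complement(
            extract_window_sequence(genome, plus, small_grid)
        )


class TestDensityMatrix:
    def test_periodic_pattern_counts(self, small_grid):
        genome = {"c": "ACGT" * 1000}
        gene = GeneRecord("g", "c", 2000, "+")
        row = dinucleotide_density_matrix(genome, [gene], small_grid, "CG").iloc[0]
        assert (row == 10).all()

    def test_saturated_window_counts(self, small_grid):
        genome = {"c": "CG" * 2000}
        gene = GeneRecord("g", "c", 2000, "+")
        row = dinucleotide_density_matrix(genome, [gene], small_grid, "CG").iloc[0]
        assert (row == 20).all()

    def test_matches_naive_scan_on_random_loci(self, random_locus_set, small_grid):
        genome, genes = random_locus_set
        matrix = dinucleotide_density_matrix(genome, genes, small_grid, "CG")
        for gene in genes:
            expected = naive_gene_counts(genome, gene, "CG", small_grid)
            np.testing.assert_array_equal(matrix.loc[gene.gene_id].to_numpy(), expected)

    def test_count_bound(self, random_locus_set, small_grid):
        genome, genes = random_locus_set
        matrix = dinucleotide_density_matrix(genome, genes, small_grid, "CG")
        assert matrix.to_numpy().min() >= 0
        assert matrix.to_numpy().max() <= small_grid.window // 2

    def test_strand_symmetry_cg_exact(self, random_locus_set, small_grid):
        """CG is palindromic: a minus-strand vector equals the reversed plus vector."""
        genome, genes = random_locus_set
        minus = [g for g in genes if g.strand == "-"]
        plus = [GeneRecord(g.gene_id, g.chrom, g.tss, "+") for g in minus]
        m_minus = dinucleotide_density_matrix(genome, minus, small_grid, "CG").to_numpy()
        m_plus = dinucleotide_density_matrix(genome, plus, small_grid, "CG").to_numpy()
        np.testing.assert_array_equal(m_minus, m_plus[:, ::-1])

    def test_tg_equals_reversed_ca(self, random_locus_set, small_grid):
        genome, genes = random_locus_set
        gene = next(g for g in genes if g.strand == "-")
        plus = GeneRecord(gene.gene_id, gene.chrom, gene.tss, "+")
        tg_minus = dinucleotide_density_matrix(genome, [gene], small_grid, "TG").to_numpy()[0]
        ca_plus = dinucleotide_density_matrix(genome, [plus], small_grid, "CA").to_numpy()[0]
        np.testing.assert_array_equal(tg_minus, ca_plus[::-1])

    def test_window_sum_conservation(self, random_locus_set, small_grid):
        genome, genes = random_locus_set
        matrix = dinucleotide_density_matrix(genome, genes, small_grid, "CG")
        for gene in genes[:20]:
            seq = extract_window_sequence(genome, gene, small_grid)
            total = sum(seq[i:i+2] == "CG" for i in range(len(seq) - 1))
            assert matrix.loc[gene.gene_id].sum() == total

    def test_empty_gene_list_raises(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            dinucleotide_density_matrix({"c": "ACGT" * 100}, [], small_grid)


class TestSignalMatrix:
    def test_constant_track(self, small_grid):
        track = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [4000], "value": [2.0]})
        genes = [GeneRecord("g", "c", 2000, "+"), GeneRecord("h", "c", 2000, "-")]
        m = signal_window_matrix(track, genes, small_grid)
        assert (m.to_numpy() == 2.0).all()

    def test_partial_coverage_is_mean_over_covered(self, small_grid):
        # track covers only the left half of the first window at value 4
        track = pd.DataFrame({"chrom": ["c"], "start": [1800], "end": [1820], "value": [4.0]})
        gene = GeneRecord("g", "c", 2000, "+")
        m = signal_window_matrix(track, [gene], small_grid)
        assert m.iloc[0, 0] == 4.0
        assert m.iloc[0, 1:].isna().all()

    def test_uncovered_windows_missing_not_zero(self, small_grid):
        track = pd.DataFrame({"chrom": ["x"], "start": [0], "end": [10], "value": [1.0]})
        gene = GeneRecord("g", "c", 2000, "+")
        m = signal_window_matrix(track, [gene], small_grid)
        assert m.isna().all().all()

    def test_sawtooth_matches_per_base_oracle(self, rng, small_grid):
        starts = np.arange(1700, 2400, 7)
        track = pd.DataFrame({
            "chrom": "c", "start": starts, "end": starts + 7,
            "value": rng.normal(size=len(starts)),
        })
        genes = [GeneRecord("g", "c", 2000, "+"), GeneRecord("h", "c", 2000, "-")]
        m = signal_window_matrix(track, genes, small_grid)
        for gene in genes:
            per_base = np.full(small_grid.span, np.nan)
            for _, row in track.iterrows():
                a = max(int(row.start), gene.tss - small_grid.flank)
                b = min(int(row.end), gene.tss + small_grid.flank)
                per_base[a - (gene.tss - small_grid.flank): b - (gene.tss - small_grid.flank)] = row.value
            if gene.strand == "-":
                per_base = per_base[::-1]
            expected = [
                np.nanmean(w) if np.isfinite(w).any() else np.nan
                for w in per_base.reshape(small_grid.n_windows, small_grid.window)
            ]
            np.testing.assert_allclose(m.loc[gene.gene_id].to_numpy(), expected, rtol=1e-12)

    def test_malformed_bedgraph_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("c\t0\t10\t1.0\nc\t10\tbroken\t2.0\n")
        with pytest.raises(ValueError, match=":2"):
            signal_window_matrix(path, [GeneRecord("g", "c", 2000, "+")])


class TestMethylationMatrix:
    def test_single_and_mean_betas(self, small_grid):
        sites = pd.DataFrame({"chrom": ["c", "c", "c"], "pos": [1805, 1850, 1870],
                              "beta": [0.8, 0.2, 0.6]})
        gene = GeneRecord("g", "c", 2000, "+")
        m = methylation_window_matrix(sites, [gene], small_grid)
        assert m.iloc[0, 0] == pytest.approx(0.8)
        assert m.iloc[0, 1] == pytest.approx(0.4)
        assert m.iloc[0, 2:].isna().all()

    def test_minus_strand_window_orientation(self, small_grid):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1805], "beta": [0.5]})
        gene = GeneRecord("g", "c", 2000, "-")
        m = methylation_window_matrix(sites, [gene], small_grid)
        # offset 5 from the left end maps to the last oriented window
        assert m.iloc[0, -1] == pytest.approx(0.5)
        assert m.iloc[0, :-1].isna().all()

    def test_beta_out_of_range_raises(self, small_grid):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1805], "beta": [1.2]})
        with pytest.raises(ValueError, match="beta"):
            methylation_window_matrix(sites, [GeneRecord("g", "c", 2000, "+")], small_grid)


class TestPeakGeometry:
    peaks = pd.DataFrame({"chrom": ["c", "c"], "start": [880, 1290], "end": [920, 1310]})

    def test_signed_distance_follows_transcription(self):
        genes = [GeneRecord("p", "c", 1000, "+"), GeneRecord("m", "c", 1000, "-")]
        d = tss_signed_distance(pd.DataFrame(
            {"chrom": ["c"], "start": [1190], "end": [1210]}), genes)
        assert d["p"] == 200
        assert d["m"] == -200

    def test_nearest_by_absolute_distance(self):
        d = tss_signed_distance(self.peaks, [GeneRecord("g", "c", 1000, "+")])
        assert d["g"] == -100  # mid 900 at distance 100 beats mid 1300 at 300

    def test_no_peak_on_chromosome_is_missing(self):
        d = tss_signed_distance(self.peaks, [GeneRecord("g", "x", 1000, "+")])
        assert np.isnan(d["g"])

    @pytest.mark.parametrize(
        "tss_list, expected",
        [([900, 1300, 5000, 6000], 0.5), ([5000, 6000], 0.0), ([900, 1300], 1.0)],
    )
    def test_overlap_proportion(self, tss_list, expected):
        genes = [GeneRecord(f"g{i}", "c", t, "+") for i, t in enumerate(tss_list)]
        assert peak_overlap_proportion(self.peaks, genes, 100) == expected

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            peak_overlap_proportion(self.peaks, [], 100)
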