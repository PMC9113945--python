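"""Synthetic-data generator: determinism, planted structure, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cpgprofiler import (
    ContactMatrix,
    SimulationConfig,
    call_compartments,
    classify_de,
    dinucleotide_density_matrix,
    gen_contact_matrix,
    gen_de_table,
    gen_expression,
    gen_marks,
    gen_sequences,
    insulation_score,
    simulate_all,
)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        config = SimulationConfig(n_genes=(10, 20, 30), seed=42, baseline_rate=0.7)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == config

    def test_classifier_benchmark_sizes(self):
        config = SimulationConfig.classifier_benchmark(seed=5)
        assert config.n_genes == (1300, 1000, 1300)
        assert config.seed == 5


class TestSequences:
    def test_deterministic(self):
        config = SimulationConfig(n_genes=(5, 5, 5), seed=3)
        g1, genes1, t1 = gen_sequences(config)
        g2, genes2, t2 = gen_sequences(config)
        assert g1 == g2
        assert genes1 == genes2
        pd.testing.assert_frame_equal(t1, t2)

    def test_labels_follow_archetypes(self, small_sim):
        truth = small_sim[3]
        mapping = truth.groupby("archetype")["label"].unique()
        assert list(mapping[1]) == [0]
        assert list(mapping[2]) == [-1]
        assert list(mapping[3]) == [1]
        assert truth["archetype"].value_counts().to_dict() == {1: 60, 2: 60, 3: 60}

    def test_central_cg_truth_matches_featurization(self, small_sim):
        """End-to-end oracle: the recorded central CG count of every gene equals
        the featurized density summed over the central 13 windows, across both
        strands — verifying placement, orientation and counting together."""
        config, genome, genes, truth = small_sim
        density = dinucleotide_density_matrix(genome, genes, config.grid, "CG")
        nw = config.grid.n_windows
        central = density.iloc[:, nw // 2 - 6: nw // 2 + 7].sum(axis=1)
        np.testing.assert_array_equal(central.to_numpy(),
                                      truth["central_cg"].to_numpy())

    def test_profile_means_match_planted_rates(self, small_sim):
        config, genome, genes, truth = small_sim
        density = dinucleotide_density_matrix(genome, genes, config.grid, "CG")
        nw = config.grid.n_windows
        arch = truth["archetype"]
        prof = {k: density.loc[arch[arch == k].index].mean(axis=0).to_numpy()
                for k in (1, 2, 3)}
        # flat archetype: everywhere near baseline
        assert prof[3].mean() == pytest.approx(config.baseline_rate, rel=0.1)
        assert prof[3].max() < 2.0
        # sharp archetype: peak window near baseline + height, far flanks near baseline
        peak = prof[1][nw // 2 - 1: nw // 2 + 2].max()
        assert peak == pytest.approx(config.baseline_rate + config.peak_height[0], rel=0.15)
        assert prof[1][:50].mean() == pytest.approx(config.baseline_rate, rel=0.15)
        # broad archetype: lower, wider peak
        assert prof[2][nw // 2] == pytest.approx(
            config.baseline_rate + config.peak_height[1], rel=0.2)
        assert prof[2][nw // 2 - 10] > prof[3][nw // 2 - 10] + 2.0

    def test_counts_bounded_by_window_capacity(self, small_sim):
        config, genome, genes, _ = small_sim
        density = dinucleotide_density_matrix(genome, genes, config.grid, "CG")
        assert density.to_numpy().max() <= config.window // 2
        assert density.to_numpy().min() >= 0


class TestExpression:
    def test_coupling_strong_for_flat_archetype(self, small_sim):
        config, _, _, truth = small_sim
        expr = gen_expression(truth, config)
        mean_log = np.log2(expr).mean(axis=1)
        rho = {}
        for k in (1, 3):
            ids = truth.index[truth["archetype"] == k]
            rho[k] = spearmanr(truth.loc[ids, "central_cg"], mean_log[ids]).statistic
        assert rho[3] > 0.5  # beta = 1.2 against sd 0.5 noise
        assert rho[3] > rho[1]

    def test_zero_beta_decouples(self):
        config = SimulationConfig(n_genes=(0, 0, 200), expr_beta=(0.0, 0.0, 0.0), seed=11)
        _, _, truth = gen_sequences(config)
        expr = gen_expression(truth, config)
        mean_log = np.log2(expr).mean(axis=1)
        rho = spearmanr(truth["central_cg"], mean_log).statistic
        assert abs(rho) < 0.2

    def test_archetype1_broad_archetype3_confined(self, small_sim):
        config, _, _, truth = small_sim
        expr = gen_expression(truth, config)
        s = expr.div(expr.mean(axis=1), axis=0)  # relative expression
        frac_active = (s > 0.5).mean(axis=1)  # fraction of tissues with real expression
        by_arch = frac_active.groupby(truth["archetype"]).mean()
        assert by_arch[1] > 0.9   # housekeeping-like: active everywhere
        assert by_arch[3] < 0.5   # confined to few tissues

    def test_expression_positive(self, small_sim):
        config, _, _, truth = small_sim
        expr = gen_expression(truth, config)
        assert (expr.to_numpy() > 0).all()


@pytest.fixture(scope="module")
def marks(small_sim):
    config, _, genes, truth = small_sim
    expr = gen_expression(truth, config)
    tracks, methylation = gen_marks(genes, truth, expr, config)
    return config, genes, truth, expr, tracks, methylation


class TestMarks:
    def test_track_schema_and_nonnegative(self, marks):
        _, _, _, _, tracks, _ = marks
        for name in ("h3k27me3", "h3k4me3", "mnase"):
            t = tracks[name]
            assert list(t.columns) == ["chrom", "start", "end", "value"]
            assert (t["value"] >= 0).all()
            assert (t["end"] - t["start"] == 40).all()

    def test_methylation_in_unit_interval(self, marks):
        *_, methylation = marks
        assert methylation["beta"].between(0, 1).all()

    def test_repressive_mark_absent_for_flat_archetype(self, marks):
        config, genes, truth, _, tracks, _ = marks
        k27 = tracks["h3k27me3"]
        by_gene = {}
        for g in genes:
            lo, hi = g.tss - 1000, g.tss + 1000
            sel = (k27["chrom"] == g.chrom) & (k27["start"] >= lo) & (k27["end"] <= hi)
            by_gene[g.gene_id] = k27.loc[sel, "value"].mean()
        near_tss = pd.Series(by_gene)
        means = near_tss.groupby(truth["archetype"]).mean()
        # amplitude 0 for archetype 3: only truncated noise remains
        assert means[3] < means[1] < means[2]
        assert means[3] < 0.2

    def test_active_mark_tracks_expression(self, marks):
        config, genes, truth, expr, tracks, _ = marks
        k4 = tracks["h3k4me3"]
        expr_mean = expr.mean(axis=1)
        by_gene = {}
        for g in genes:
            sel = (k4["chrom"] == g.chrom) & (k4["start"] >= g.tss - 200) & (k4["end"] <= g.tss + 200)
            by_gene[g.gene_id] = k4.loc[sel, "value"].mean()
        sig = pd.Series(by_gene)
        for k in (1, 2, 3):
            ids = truth.index[truth["archetype"] == k]
            rho = spearmanr(sig[ids], expr_mean[ids]).statistic
            assert rho > 0.4, f"archetype {k}"


class TestHiC:
    def test_deterministic_and_valid(self):
        config = SimulationConfig(seed=9)
        cm1, t1 = gen_contact_matrix(config)
        cm2, t2 = gen_contact_matrix(config)
        np.testing.assert_array_equal(cm1.matrix, cm2.matrix)
        np.testing.assert_array_equal(t1["compartments"], t2["compartments"])
        assert isinstance(cm1, ContactMatrix)  # validation ran in __post_init__

    def test_insulation_peaks_at_planted_boundary(self):
        config = SimulationConfig(seed=9)
        cm, truth = gen_contact_matrix(config)
        track = insulation_score(cm, 480_000).to_numpy()
        peak = int(np.nanargmax(track))
        (boundary,) = truth["boundaries"]
        assert peak in (boundary - 1, boundary)

    def test_compartments_recovered_without_tads(self):
        # with planted TADs the leading eigenvector mixes domain and
        # compartment structure, so recovery is assessed on a TAD-free matrix
        config = SimulationConfig(seed=9, tad_boundaries=())
        cm, truth = gen_contact_matrix(config)
        labels = call_compartments(cm, truth["orientation"]).to_numpy()
        expected = np.where(truth["compartments"] > 0, "A", "B")
        assert (labels == expected).mean() >= 0.95

    def test_invalid_intensities_raise(self):
        with pytest.raises(ValueError, match="within > between"):
            gen_contact_matrix(SimulationConfig(hic_within=0.1, hic_between=0.5))


class TestDeTable:
    def test_schema_and_archetype_ordering(self, small_sim):
        config, _, _, truth = small_sim
        de = gen_de_table(truth, config)
        assert de["pvalue"].between(0, 1).all()
        part = classify_de(de)
        frac = (part["de"] != "stable").groupby(truth["archetype"]).mean()
        # wider fold-change spread => more DE calls for the flat archetype
        assert frac[3] > frac[1]


class TestSimulateAll:
    def test_writes_complete_file_set(self, tmp_path):
        config = SimulationConfig(n_genes=(4, 4, 4), hic_n_bins=30, seed=1)
        paths = simulate_all(config, tmp_path)
        for key in ("fasta", "tss_bed", "truth", "expression", "h3k27me3",
                    "h3k4me3", "mnase", "methylation", "hic_coo", "hic_bins",
                    "hic_truth", "de_table", "config"):
            assert paths[key].exists(), key
        assert SimulationConfig.from_yaml(paths["config"]) == config

    def test_fasta_roundtrip_preserves_density(self, tmp_path):
        """Featurizing the written FASTA reproduces the in-memory density."""
        import pyfaidx

        from cpgprofiler import read_tss_bed

        config = SimulationConfig(n_genes=(4, 4, 4), hic_n_bins=30, seed=1)
        paths = simulate_all(config, tmp_path)
        genome_mem, genes_mem, _ = gen_sequences(config)
        mem = dinucleotide_density_matrix(genome_mem, genes_mem, config.grid)
        fasta = pyfaidx.Fasta(str(paths["fasta"]))
        genes_file = read_tss_bed(paths["tss_bed"])
        file = dinucleotide_density_matrix(fasta, genes_file, config.grid)
        pd.testing.assert_frame_equal(mem, file)
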