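import numpy as np
import pytest

from nucleoscape.gene_features import cpg_observed_expected
from nucleoscape.genome_io import read_chrom_sizes, read_genes, read_tags, \
    write_chrom_sizes, write_genes, write_tags
from nucleoscape.synthetic_data import (
    CLASS_CPG_OE, SimConfig, simulate_breadth_panel, simulate_genes_and_promoters,
    simulate_genome_fasta, simulate_landscape, simulate_phased_tags, simulate_tags,
    synthesize_cpg_sequence,
)
from nucleoscape.window_profile import count_tags, window_gc


def small_config(seed=0, **kw):
    kw.setdefault("n_chroms", 2)
    kw.setdefault("chrom_length", 1_000_000)
    kw.setdefault("window_size", 20_000)
    kw.setdefault("n_genes", 40)
    return SimConfig(seed=seed, **kw)


class TestSimulateLandscape:
    def test_deterministic_under_seed(self):
        t1 = simulate_landscape(small_config(3))
        t2 = simulate_landscape(small_config(3))
        assert (t1.window_label == t2.window_label).all()
        assert (t1.window_gc == t2.window_gc).all()
        t3 = simulate_landscape(small_config(4))
        assert not (t1.window_label == t3.window_label).all()

    def test_single_window_chromosome(self):
        cfg = SimConfig(seed=0, n_chroms=1, chrom_length=100_000, window_size=100_000)
        truth = simulate_landscape(cfg)
        assert truth.grid.n_windows == 1
        assert truth.window_label[0] in ("LOG", "HOG")

    def test_run_lengths_near_geometric_mean(self):
        """Mean label run length tracks the geometric block-length parameter."""
        runs = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, n_chroms=1, chrom_length=10_000_000,
                            window_size=100_000, block_length_mean=5.0)
            lab = simulate_landscape(cfg).window_label
            change = np.nonzero(lab[1:] != lab[:-1])[0]
            runs.extend(np.diff(np.concatenate([[0], change + 1, [len(lab)]])))
        assert np.mean(runs) == pytest.approx(5.0, rel=0.15)

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length=50_000, window_size=100_000)


class TestSimulateTags:
    def test_zero_log_rate_silences_log_windows(self):
        cfg = small_config(1, log_rate=0.0, gc_coupling=0.0)
        truth = simulate_landscape(cfg)
        counts, _ = count_tags(truth.grid, simulate_tags(truth, "NO", "A"))
        assert counts[truth.window_label == "LOG"].sum() == 0

    def test_hog_total_within_poisson_bounds(self):
        cfg = small_config(2, hog_rate=100.0, gc_coupling=0.0,
                          frac_diff_windows=0.0)
        truth = simulate_landscape(cfg)
        counts, _ = count_tags(truth.grid, simulate_tags(truth, "NO", "A"))
        n_hog = int((truth.window_label == "HOG").sum())
        total = counts[truth.window_label == "HOG"].sum()
        expected = 100.0 * n_hog
        assert abs(total - expected) <= 3 * np.sqrt(expected)

    def test_diff_fold_ratio_recovered(self):
        """Planted fold shows up as the A/B mean count ratio on flagged windows."""
        ratios = []
        for seed in range(8):
            cfg = small_config(seed, frac_diff_windows=0.2, diff_fold=3.0,
                              gc_coupling=0.0)
            truth = simulate_landscape(cfg)
            ca, _ = count_tags(truth.grid, simulate_tags(truth, "NO", "A", seed=seed))
            cb, _ = count_tags(truth.grid, simulate_tags(truth, "NO", "B",
                                                         seed=seed + 1000))
            sel = truth.diff_flag & (truth.diff_direction == "A")
            if sel.any():
                ratios.append(ca[sel].sum() / cb[sel].sum())
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.1)

    def test_label_rate_ordering_always_holds(self):
        for seed in range(5):
            truth = simulate_landscape(small_config(seed))
            counts, _ = count_tags(truth.grid, simulate_tags(truth, "NO", "A"))
            assert counts[truth.window_label == "HOG"].mean() > \
                counts[truth.window_label == "LOG"].mean()

    def test_unknown_tissue_or_channel_rejected(self):
        truth = simulate_landscape(small_config(0))
        with pytest.raises(ValueError):
            simulate_tags(truth, "NO", "C")
        with pytest.raises(ValueError):
            simulate_tags(truth, "ATAC", "A")

    def test_deterministic_under_seed(self):
        truth = simulate_landscape(small_config(0))
        assert simulate_tags(truth, "NO", "A", seed=7) == \
            simulate_tags(truth, "NO", "A", seed=7)


class TestGenesAndPromoters:
    def test_zero_genes_empty(self):
        truth = simulate_landscape(small_config(0, n_genes=0))
        assert simulate_genes_and_promoters(truth) == []

    def test_density_too_high_rejected(self):
        truth = simulate_landscape(small_config(0, n_genes=500))
        with pytest.raises(ValueError, match="overlap|density"):
            simulate_genes_and_promoters(truth)

    def test_realized_oe_near_target(self):
        truth = simulate_landscape(small_config(5))
        simulate_genes_and_promoters(truth)
        by_class = {}
        for gid, cls in truth.gene_class.items():
            oe = truth.gene_realized_oe[gid]
            by_class.setdefault(cls, []).append(oe)
            # single 2.5-kb promoter: allow sampling noise around the target
            assert oe == pytest.approx(CLASS_CPG_OE[cls], abs=0.25)
        for cls, oes in by_class.items():
            assert np.mean(oes) == pytest.approx(CLASS_CPG_OE[cls], abs=0.1)

    def test_planted_runs_recorded_and_cover_genes(self):
        truth = simulate_landscape(small_config(6))
        genes = simulate_genes_and_promoters(truth)
        ids_in_runs = [g for _, ids in truth.gene_class_runs for g in ids]
        assert sorted(ids_in_runs) == sorted(g.gene_id for g in genes)
        for cls, ids in truth.gene_class_runs:
            assert {truth.gene_class[g] for g in ids} == {cls}

    def test_genes_do_not_overlap(self):
        truth = simulate_landscape(small_config(7))
        genes = simulate_genes_and_promoters(truth)
        by_chrom = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            prev = by_chrom.get(g.chrom)
            if prev is not None:
                assert g.tx_start >= prev
            by_chrom[g.chrom] = g.tx_end

    def test_genome_fasta_matches_window_gc_targets(self, tmp_path):
        import pyfaidx
        truth = simulate_landscape(small_config(8, n_genes=0))
        path = tmp_path / "genome.fa"
        simulate_genome_fasta(truth, path)
        gc = window_gc(truth.grid, pyfaidx.Fasta(str(path)))
        np.testing.assert_allclose(gc, truth.window_gc, atol=0.02)

    def test_promoter_fasta_extraction_matches_oriented_sequence(self, tmp_path):
        """Promoters planted in the genome read back identically via TSS extraction."""
        import pyfaidx
        from nucleoscape.gene_features import promoter_sequence
        truth = simulate_landscape(small_config(9))
        genes = simulate_genes_and_promoters(truth)
        simulate_genome_fasta(truth, tmp_path / "genome.fa")
        fasta = pyfaidx.Fasta(str(tmp_path / "genome.fa"))
        for g in genes[:10]:
            assert promoter_sequence(g, fasta).upper() == \
                truth._promoter_seqs[g.gene_id]


class TestBreadthPanel:
    def test_planted_breadth_classes(self):
        truth = simulate_landscape(small_config(10))
        simulate_genes_and_promoters(truth)
        panel = simulate_breadth_panel(truth)
        on = (panel > 1.0).sum(axis=1)
        for gid, cls in truth.gene_breadth_class.items():
            if cls == "HK":
                assert on[gid] >= 18
            else:
                assert on[gid] <= 3

    def test_reproducible(self):
        truth = simulate_landscape(small_config(11))
        simulate_genes_and_promoters(truth)
        p1 = simulate_breadth_panel(truth, seed=5)
        p2 = simulate_breadth_panel(truth, seed=5)
        assert p1.equals(p2)

    def test_too_few_tissues_rejected(self):
        truth = simulate_landscape(small_config(12, n_tissues_breadth=1))
        simulate_genes_and_promoters(truth)
        with pytest.raises(ValueError):
            simulate_breadth_panel(truth)


class TestEmittedFilesRevalidate:
    def test_roundtrip_through_readers(self, tmp_path):
        truth = simulate_landscape(small_config(13))
        genes = simulate_genes_and_promoters(truth)
        tags = simulate_tags(truth, "NO", "A")
        write_chrom_sizes(truth.chrom_sizes, tmp_path / "c.sizes")
        write_genes(genes, tmp_path / "genes.refflat")
        write_tags(tags, tmp_path / "tags.bed")
        cs = read_chrom_sizes(tmp_path / "c.sizes")
        assert cs.sizes == truth.chrom_sizes.sizes
        assert read_genes(tmp_path / "genes.refflat") == genes
        assert read_tags(tmp_path / "tags.bed", cs) == tags


class TestPhasedTags:
    def test_offsets_cluster_at_phase(self):
        truth = simulate_landscape(small_config(14))
        genes = simulate_genes_and_promoters(truth)
        tags = simulate_phased_tags(genes, truth.chrom_sizes, phase_offset=50,
                                    jitter_sd=2.0, background_rate=0.0, seed=3)
        offs = []
        by_id = {g.gene_id: g for g in genes}
        for t in tags:
            # recover the transcription-oriented offset from the nearest gene
            g = min(genes, key=lambda g: abs(t.start - g.tss)
                    if g.chrom == t.chrom else 10 ** 9)
            offs.append((t.start - g.tss) if g.strand == "+" else (g.tss - t.start))
        assert np.median(offs) == pytest.approx(50, abs=1)
        assert np.std(offs) < 5


def test_synthesized_sequence_hits_oe_and_gc_targets(rng):
    for cls, oe_t in CLASS_CPG_OE.items():
        seq = synthesize_cpg_sequence(rng, 20_000, oe_t, 0.5)
        oe, gc = cpg_observed_expected(seq)
        assert oe == pytest.approx(oe_t, abs=0.08)
        assert gc == pytest.approx(0.5, abs=0.02)
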