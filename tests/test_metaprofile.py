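import numpy as np
import pytest

from nucleoscape.genome_io import ChromSizes, GeneModel, ReadTag
from nucleoscape.metaprofile import build_profile, compare_profiles
from nucleoscape.synthetic_data import SimConfig, simulate_genes_and_promoters, \
    simulate_landscape, simulate_phased_tags


def _gene(gene_id="g1", strand="+", start=5000, end=8000, chrom="chr1"):
    return GeneModel(gene_id, chrom, strand, start, end, ((start, end),))


class TestBuildProfile:
    def test_single_tag_lands_in_first_downstream_bin(self):
        g = _gene()
        tags = [ReadTag("chr1", g.tss + 2, g.tss + 38)]
        prof = build_profile([g], tags, "TSS", span=1000, bin_width=5,
                             library_size=10 ** 6)
        assert prof.raw_counts.sum() == 1
        assert int(np.argmax(prof.raw_counts)) == 1000 // 5

    def test_mirrored_minus_strand_identical(self):
        plus = _gene("gp", "+")
        tag_plus = [ReadTag("chr1", plus.tss + 2, plus.tss + 38)]
        minus = _gene("gm", "-")
        tag_minus = [ReadTag("chr1", minus.tss - 2, minus.tss + 34)]
        p1 = build_profile([plus], tag_plus, "TSS", library_size=10 ** 6)
        p2 = build_profile([minus], tag_minus, "TSS", library_size=10 ** 6)
        np.testing.assert_array_equal(p1.raw_counts, p2.raw_counts)

    def test_mass_conservation(self, rng):
        genes = [_gene(f"g{i}", start=int(s), end=int(s) + 2000)
                 for i, s in enumerate(rng.integers(5000, 80_000, size=5))]
        tags = [ReadTag("chr1", int(s), int(s) + 36)
                for s in rng.integers(0, 90_000, size=2000)]
        prof = build_profile(genes, tags, "TSS", span=1000, bin_width=5)
        in_span = sum(1 for t in tags for g in genes
                      if -1000 <= (t.start - g.tss if g.strand == "+"
                                   else g.tss - t.start) < 1000)
        assert prof.raw_counts.sum() == in_span

    def test_translation_equivariance(self, rng):
        genes = [_gene("g1", start=5000, end=7000)]
        starts = rng.integers(4000, 8000, size=200)
        tags = [ReadTag("chr1", int(s), int(s) + 36) for s in starts]
        shift = 10_000
        genes2 = [_gene("g1", start=15_000, end=17_000)]
        tags2 = [ReadTag("chr1", int(s) + shift, int(s) + shift + 36) for s in starts]
        p1 = build_profile(genes, tags, "TSS", library_size=10 ** 6)
        p2 = build_profile(genes2, tags2, "TSS", library_size=10 ** 6)
        np.testing.assert_array_equal(p1.raw_counts, p2.raw_counts)

    def test_strand_flip_of_whole_dataset_invariant(self, rng):
        """Reverse-complement mirroring of genes and tag starts preserves the profile."""
        L = 50_000
        start, end = 20_000, 24_000
        genes = [_gene("g1", "+", start, end)]
        starts = rng.integers(18_000, 26_000, size=300)
        tags = [ReadTag("chr1", int(s), int(s) + 36) for s in starts]
        # mirror: position p -> L - 1 - p; plus gene becomes minus gene
        mgenes = [_gene("g1", "-", L - end, L - start)]
        mtags = [ReadTag("chr1", L - 1 - int(s), L - 1 - int(s) + 36) for s in starts]
        p1 = build_profile(genes, tags, "TSS", library_size=10 ** 6)
        p2 = build_profile(mgenes, mtags, "TSS", library_size=10 ** 6)
        np.testing.assert_array_equal(p1.raw_counts, p2.raw_counts)

    def test_tts_anchor_uses_transcript_end(self):
        g = _gene()
        tags = [ReadTag("chr1", g.tts + 2, g.tts + 38)]
        prof = build_profile([g], tags, "TTS", library_size=10 ** 6)
        assert prof.raw_counts.sum() == 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_profile([], [], "TSS")
        with pytest.raises(ValueError):
            build_profile([_gene()], [], "TSS", span=1000, bin_width=3)
        with pytest.raises(ValueError):
            build_profile([_gene()], [], "middle")


class TestPlantedPhase:
    def test_phase_peak_recovered_within_bins(self):
        cfg = SimConfig(seed=5, n_chroms=2, chrom_length=1_000_000,
                        window_size=20_000, n_genes=50)
        truth = simulate_landscape(cfg)
        genes = simulate_genes_and_promoters(truth)
        tags = simulate_phased_tags(genes, truth.chrom_sizes, phase_offset=50,
                                    jitter_sd=2.0, reads_per_gene=20,
                                    background_rate=2.0, seed=9)
        prof = build_profile(genes, tags, "TSS", span=1000, bin_width=5)
        peak = prof.bin_centers()[int(np.argmax(prof.bins))]
        assert 45 <= peak <= 55


class TestCompareProfiles:
    def _flat(self, value=2.0):
        from nucleoscape.metaprofile import Metaprofile
        bins = np.full(400, value)
        return Metaprofile("TSS", 1000, 5, bins, bins.astype(int), 10, 10 ** 6)

    def test_flat_profile_ratio_one(self):
        res = compare_profiles(self._flat(), self._flat())
        assert res["peak_to_flank_a"] == pytest.approx(1.0)

    def test_delta_profile_ratio_large(self):
        from nucleoscape.metaprofile import Metaprofile
        bins = np.ones(400)
        bins[200] = 100.0
        delta = Metaprofile("TSS", 1000, 5, bins, bins.astype(int), 10, 10 ** 6)
        res = compare_profiles(delta, self._flat())
        assert res["peak_to_flank_a"] > res["peak_to_flank_b"]
        assert res["peak_to_flank_a"] == pytest.approx(100.0)

    def test_zero_flank_flagged_infinite(self):
        from nucleoscape.metaprofile import Metaprofile
        bins = np.zeros(400)
        bins[200] = 1.0
        delta = Metaprofile("TSS", 1000, 5, bins, bins.astype(int), 10, 10 ** 6)
        res = compare_profiles(delta, self._flat())
        assert np.isinf(res["peak_to_flank_a"])
        assert res["flank_zero"]

    def test_binning_mismatch_rejected(self):
        from nucleoscape.metaprofile import Metaprofile
        a = self._flat()
        b = Metaprofile("TSS", 1000, 10, np.ones(200), np.ones(200, int), 10, 10 ** 6)
        with pytest.raises(ValueError):
            compare_profiles(a, b)

    def test_positioned_beats_fuzzy_consistently(self, rng):
        """Phased gene sets keep a sharper peak than uniform ones across simulations."""
        cfg = SimConfig(seed=2, n_chroms=1, chrom_length=1_000_000,
                        window_size=20_000, n_genes=30)
        truth = simulate_landscape(cfg)
        genes = simulate_genes_and_promoters(truth)
        wins = 0
        n_rounds = 20
        for i in range(n_rounds):
            phased = simulate_phased_tags(genes, truth.chrom_sizes, seed=i,
                                          reads_per_gene=20, background_rate=2)
            fuzzy = simulate_phased_tags(genes, truth.chrom_sizes, seed=1000 + i,
                                         reads_per_gene=0, background_rate=22)
            pa = build_profile(genes, phased, "TSS")
            pb = build_profile(genes, fuzzy, "TSS")
            res = compare_profiles(pa, pb)
            if res["peak_to_flank_a"] > res["peak_to_flank_b"]:
                wins += 1
        assert wins >= int(0.95 * n_rounds)
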