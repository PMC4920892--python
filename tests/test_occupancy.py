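"""Metagene profiles, elongation ratios, and site classification."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from enhancerkit import (
    CoverageTrack,
    Gene,
    GenomicInterval,
    Peak,
    classify_context,
    classify_contexts,
    cooccupancy_class,
    elongation_log2_ratio,
    group_mean_tss_profile,
    metagene_profile,
    ranked_signal_curves,
)
from enhancerkit.occupancy import (
    DISTAL_INTERGENIC,
    DISTAL_INTRAGENIC,
    PROXIMAL,
    TSS_AND_INTERGENIC,
    TSS_ONLY,
    context_counts,
)


def gene(chrom, start, end, strand="+", gid="g"):
    return Gene(gid, GenomicInterval(chrom, start, end, strand), strand)


class TestMetagene:
    def test_uniform_track_gives_flat_profile(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 2.5)
        genes = [gene("chr1", 20_000, 30_000, "+", "g1"),
                 gene("chr1", 50_000, 58_000, "-", "g2")]
        p = metagene_profile(t, genes)
        assert np.allclose(p.values, 2.5)

    def test_signal_only_at_tss_bin(self, track_factory):
        vals = np.zeros(100_000)
        vals[20_000:20_050] = 1.0
        t = track_factory({"chr1": vals})
        p = metagene_profile(t, [gene("chr1", 20_000, 30_000)], upstream_bp=2000,
                             downstream_bp=2000, n_body_bins=100)
        nonzero = np.flatnonzero(p.values)
        assert nonzero.tolist() == [p.n_flank_up]  # first body bin only

    def test_length_invariance_two_gene_toy(self, track_factory):
        # two genes of different lengths, identical per-bin densities
        vals = np.zeros(200_000)
        vals[20_000:24_000] = 4.0
        vals[100_000:108_000] = 4.0
        t = track_factory({"chr1": vals})
        genes = [gene("chr1", 20_000, 24_000, "+", "short"),
                 gene("chr1", 100_000, 108_000, "+", "long")]
        p = metagene_profile(t, genes)
        assert np.allclose(p.body, 4.0)

    def test_minus_strand_reversal(self, track_factory):
        vals = np.zeros(100_000)
        vals[29_950:30_000] = 1.0  # at the TSS of a minus-strand gene
        t = track_factory({"chr1": vals})
        p = metagene_profile(t, [gene("chr1", 20_000, 30_000, "-")])
        assert p.values[p.n_flank_up] > 0
        assert p.values[-1] == 0

    def test_short_genes_dropped_and_all_dropped_is_error(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 1.0)
        ok = gene("chr1", 20_000, 30_000, "+", "ok")
        tiny = gene("chr1", 50_000, 50_050, "+", "tiny")
        p = metagene_profile(t, [ok, tiny], n_body_bins=100)
        assert p.n_genes == 1
        with pytest.raises(ValueError):
            metagene_profile(t, [tiny], n_body_bins=100)

    def test_linearity_in_tracks(self, track_factory):
        rng = np.random.default_rng(3)
        a = rng.random(100_000)
        b = rng.random(100_000)
        genes = [gene("chr1", 20_000, 30_000), gene("chr1", 60_000, 64_000, "-", "g2")]
        pa = metagene_profile(track_factory({"chr1": a}), genes)
        pb = metagene_profile(track_factory({"chr1": b}), genes)
        pab = metagene_profile(track_factory({"chr1": a + b}), genes)
        assert np.allclose(pab.values, pa.values + pb.values, atol=1e-9)


class TestElongationRatio:
    def test_identical_profiles_zero(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 1.0)
        genes = [gene("chr1", 20_000, 30_000)]
        p = metagene_profile(t, genes)
        assert np.allclose(elongation_log2_ratio(p, p), 0.0)

    def test_doubling_gives_plus_one(self, uniform_track_factory):
        genes = [gene("chr1", 20_000, 30_000)]
        pa = metagene_profile(uniform_track_factory({"chr1": 100_000}, 8.0), genes)
        pb = metagene_profile(uniform_track_factory({"chr1": 100_000}, 4.0), genes)
        r = elongation_log2_ratio(pa, pb, pseudocount=1e-9)
        assert np.allclose(r, 1.0, atol=1e-6)

    def test_binning_mismatch_rejected(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 1.0)
        genes = [gene("chr1", 20_000, 30_000)]
        pa = metagene_profile(t, genes, n_body_bins=100)
        pb = metagene_profile(t, genes, n_body_bins=50)
        with pytest.raises(ValueError):
            elongation_log2_ratio(pa, pb)

    def test_planted_elongation_contrast_increases_across_body(self):
        """Two conditions differing only in elongation efficiency show a
        monotonically increasing gene-body log2 ratio."""
        from conftest import small_scenario
        from enhancerkit.simulate import simulate

        st_ = simulate(small_scenario("elongation_contrast", seed=55))
        pa = metagene_profile(st_.tracks["pol2_a"], st_.genes)
        pb = metagene_profile(st_.tracks["pol2_b"], st_.genes)
        body = elongation_log2_ratio(pa, pb)[pa.body_slice]
        rho = spearmanr(np.arange(body.size), body).statistic
        assert rho > 0.9
        assert body[-1] > body[0]


class TestSiteContext:
    GENES = [gene("chr1", 50_000, 80_000, "+", "g1"),
             gene("chr1", 200_000, 220_000, "-", "g2")]

    def peak_at(self, pos):
        return Peak(GenomicInterval("chr1", pos - 200, pos + 200))

    def test_proximal_within_2kb(self):
        assert classify_context(self.peak_at(51_500), self.GENES) == PROXIMAL
        # minus-strand TSS is at the right end
        assert classify_context(self.peak_at(219_000), self.GENES) == PROXIMAL

    def test_intragenic_far_from_tss(self):
        assert classify_context(self.peak_at(70_000), self.GENES) == DISTAL_INTRAGENIC

    def test_gene_desert_is_intergenic(self):
        assert classify_context(self.peak_at(150_000), self.GENES) == DISTAL_INTERGENIC

    def test_summit_takes_precedence_over_midpoint(self):
        p = Peak(GenomicInterval("chr1", 140_000, 160_000), summit_offset=100)
        # midpoint is intergenic at 150 kb but summit sits near nothing either;
        # move summit next to the g1 TSS instead
        p2 = Peak(GenomicInterval("chr1", 45_000, 55_000), summit_offset=5_500)
        assert classify_context(p2, self.GENES) == PROXIMAL

    def test_classes_partition_peak_set(self, small_baseline_study):
        st_ = small_baseline_study
        contexts = classify_contexts(st_.sites, st_.genes)
        counts = context_counts(contexts)
        assert counts.sum() == len(st_.sites)
        # planted architecture: enhancer sites intergenic, promoter sites proximal
        assert counts[PROXIMAL] == len(st_.promoter_peaks)
        assert counts[DISTAL_INTERGENIC] == len(st_.enhancer_sites)


class TestCooccupancy:
    def test_tss_only_and_combined_classes(self):
        genes = [gene("chr1", 50_000, 60_000, "+", "g1"),
                 gene("chr1", 300_000, 310_000, "+", "g2")]
        tss_peak = Peak(GenomicInterval("chr1", 49_900, 50_300), name="tss")
        intergenic = Peak(GenomicInterval("chr1", 150_000, 150_400), name="ig")
        out = cooccupancy_class(genes, [tss_peak, intergenic], None)
        # nearest-TSS fallback links the intergenic peak to g1 (100 kb < 150 kb)
        assert out["g1"] == TSS_AND_INTERGENIC
        assert out["g2"] == "none"
        out2 = cooccupancy_class(genes, [tss_peak], None)
        assert out2["g1"] == TSS_ONLY

    def test_combined_implies_tss_occupancy(self, small_baseline_study):
        st_ = small_baseline_study
        out = cooccupancy_class(st_.genes, st_.peaks_for("ptefb"), None)
        tss_occupied = {g for g, c in out.items() if c in (TSS_ONLY, TSS_AND_INTERGENIC)}
        combined = {g for g, c in out.items() if c == TSS_AND_INTERGENIC}
        assert combined <= tss_occupied


class TestRankedCurves:
    def test_constant_track_constant_rows(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 2.0)
        peaks = [Peak(GenomicInterval("chr1", p, p + 400)) for p in (10_000, 50_000)]
        rc = ranked_signal_curves(peaks, [t], half_window=1000)
        assert np.allclose(rc.matrices[0], 2.0)

    def test_impulse_smoothed_to_box(self, track_factory):
        vals = np.zeros(100_000)
        vals[50_000] = 1.0  # unit impulse: 1 read at one bp
        t = track_factory({"chr1": vals})
        p = Peak(GenomicInterval("chr1", 49_800, 50_200))
        rc = ranked_signal_curves([p], [t], half_window=1000, moving_avg_bp=100)
        row = rc.matrices[0][0]
        plateau = row[row > 1e-12]
        assert len(plateau) == 100
        assert np.allclose(plateau, 0.01)  # 1/100 reads/bp * 1e6/1e6

    def test_ranking_is_a_permutation(self, small_baseline_study):
        st_ = small_baseline_study
        peaks = st_.enhancer_sites[:40]
        t = st_.tracks["tbet_a"]
        rc = ranked_signal_curves(peaks, [t, st_.tracks["control"]], half_window=1000)
        unranked = ranked_signal_curves(peaks, [t], half_window=1000)
        assert sorted(map(tuple, rc.matrices[0].round(9))) == sorted(
            map(tuple, unranked.matrices[0][np.argsort(unranked.order)].round(9))
        )
        row_sums = rc.matrices[0].sum(axis=1)
        assert np.all(np.diff(row_sums) <= 1e-6)  # descending by first track


class TestGroupTssProfile:
    def test_single_gene_group_is_that_profile(self, track_factory):
        rng = np.random.default_rng(5)
        vals = rng.random(100_000)
        t = track_factory({"chr1": vals})
        g = gene("chr1", 50_000, 60_000)
        out = group_mean_tss_profile(t, {"solo": [g]}, window=2000, n_bins=40)
        expected = t.binned_means(GenomicInterval("chr1", 48_000, 52_000), 40)
        assert np.allclose(out["solo"], expected)

    def test_uniform_track_identical_flat_profiles(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 3.0)
        groups = {
            "a": [gene("chr1", 20_000, 30_000)],
            "b": [gene("chr1", 50_000, 56_000, "-"), gene("chr1", 70_000, 76_000)],
        }
        out = group_mean_tss_profile(t, groups)
        assert np.allclose(out["a"], 3.0) and np.allclose(out["b"], 3.0)

    def test_empty_group_skipped(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 100_000}, 1.0)
        out = group_mean_tss_profile(t, {"empty": [], "ok": [gene("chr1", 50_000, 56_000)]})
        assert "empty" not in out and "ok" in out
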