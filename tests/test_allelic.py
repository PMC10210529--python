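"""Allele-specific analysis: windows, liftover, bin sums, classification."""
from __future__ import annotations

import copy

import numpy as np
import pytest

from dafca.allelic import (
    AllelicBin,
    SVRecord,
    allele_bin_sums,
    annotate_overlap,
    classify_differential,
    extract_sv_windows,
    lift_positions_to_allele2,
    lift_track_to_allele1,
)
from dafca.types import GenomeInterval, GenomeTrack

from oracles import naive_allele_window_sums


def sv(start, end, svtype="deletion", sid="sv1", zygosity="het", length=None):
    return SVRecord(sid, "chr1", start, end, svtype, zygosity, length)


class TestWindows:
    def test_centered_on_midpoint(self):
        w = extract_sv_windows([sv(1_000_000, 1_005_000)], window=100_000)
        assert (w[0].start, w[0].end) == (952_500, 1_052_500)

    def test_clipped_at_chromosome_start(self):
        w = extract_sv_windows([sv(10_000, 12_000)], window=100_000)
        assert w[0].start == 0

    def test_clipped_at_chromosome_end(self):
        w = extract_sv_windows([sv(190_000, 192_000)], window=100_000,
                               chrom_lengths={"chr1": 200_000})
        assert w[0].end == 200_000

    def test_nearby_windows_merged(self):
        svs = [sv(100_000, 101_000, sid="a"), sv(120_000, 121_000, sid="b")]
        w = extract_sv_windows(svs, window=100_000)
        assert len(w) == 1
        assert (w[0].start, w[0].end) == (50_500, 170_500)

    def test_non_het_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="non-heterozygous"):
            w = extract_sv_windows([sv(1_000, 2_000, zygosity="hom")])
        assert w == []


class TestLiftover:
    def test_deletion_shifts_and_voids(self):
        svs = [sv(1_000, 3_000, "deletion")]
        pos = lift_positions_to_allele2(np.array([500.0, 1_500.0, 4_000.0]), "chr1", svs)
        assert pos[0] == 500.0
        assert np.isnan(pos[1])
        assert pos[2] == 2_000.0

    def test_insertion_shifts_downstream(self):
        svs = [sv(1_000, 1_001, "insertion", length=500)]
        pos = lift_positions_to_allele2(np.array([500.0, 2_000.0]), "chr1", svs)
        assert pos.tolist() == [500.0, 2_500.0]

    def test_inversion_reflects_interior(self):
        svs = [sv(1_000, 2_000, "inversion")]
        pos = lift_positions_to_allele2(np.array([1_000.0, 1_999.0, 2_500.0]), "chr1", svs)
        assert pos.tolist() == [1_999.0, 1_000.0, 2_500.0]

    def test_track_lift_through_deletion(self):
        # allele2 track missing the 1 kb deleted from allele1 coordinates
        svs = [sv(2_000, 3_000, "deletion")]
        v2 = np.arange(9, dtype=float)  # allele2: 9 bins of 500 (4.5 kb)
        lifted = lift_track_to_allele1(GenomeTrack(500, {"chr1": v2}), svs)
        out = lifted.values["chr1"]
        assert out.size == 11  # allele1 is 1 kb longer
        assert out[:4].tolist() == [0, 1, 2, 3]
        assert np.all(np.isnan(out[4:6]))  # deleted interval
        assert out[6:].tolist() == [4, 5, 6, 7, 8]


def track(vals, bin_size=500):
    return GenomeTrack(bin_size, {"chr1": np.asarray(vals, float)})


class TestBinSums:
    def test_identical_tracks_equal_sums(self, rng):
        vals = rng.random(100)
        t = track(vals)
        bins, dropped = allele_bin_sums(t, track(vals.copy()),
                                        [GenomeInterval("chr1", 0, 50_000)])
        assert dropped == 0
        assert all(b.sum_allele1 == b.sum_allele2 for b in bins)

    def test_doubled_track_doubles_ratio(self, rng):
        vals = rng.random(100) + 0.5
        bins, _ = allele_bin_sums(track(vals), track(2 * vals),
                                  [GenomeInterval("chr1", 0, 50_000)])
        classify_differential(bins, pseudocount=1e-12)
        assert all(b.ratio == pytest.approx(2.0) for b in bins)

    def test_missing_in_either_allele_dropped_and_counted(self):
        v1 = np.ones(10)
        v2 = np.ones(10)
        v1[2:4] = np.nan  # whole 1 kb bin missing in allele 1
        bins, dropped = allele_bin_sums(track(v1), track(v2),
                                        [GenomeInterval("chr1", 0, 5_000)])
        assert dropped == 1
        assert len(bins) == 4

    def test_matches_brute_force_oracle(self, rng):
        v1 = rng.random(200)
        v2 = rng.random(200)
        for v in (v1, v2):
            v[rng.random(200) < 0.1] = np.nan
        windows = [GenomeInterval("chr1", 3_000, 42_000),
                   GenomeInterval("chr1", 40_000, 90_000)]
        bins, dropped = allele_bin_sums(track(v1), track(v2), windows)
        oracle = naive_allele_window_sums(v1, v2, [(3_000, 42_000), (40_000, 90_000)],
                                          500, 1_000)
        got = {b.start // 1_000: (b.sum_allele1, b.sum_allele2) for b in bins}
        for b, expected in oracle.items():
            if expected is None:
                assert b not in got
            else:
                assert got[b][0] == pytest.approx(expected[0])
                assert got[b][1] == pytest.approx(expected[1])
        assert dropped == sum(1 for v in oracle.values() if v is None)

    def test_window_on_absent_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            allele_bin_sums(track([1.0]), track([1.0]),
                            [GenomeInterval("chrX", 0, 1_000)])


def abin(s1, s2, start=0):
    return AllelicBin("chr1", start, s1, s2)


class TestClassification:
    def test_twofold_bin_flagged(self):
        bins = [abin(300.0, 150.0)]
        flagged, frac = classify_differential(bins, pseudocount=1e-9)
        assert flagged == bins and frac == 1.0
        assert bins[0].ratio == pytest.approx(2.0)

    def test_exactly_threshold_not_flagged(self):
        """'over 1.5-fold' is strict: ratio exactly 1.5 stays undifferential."""
        bins = [abin(150.0, 100.0)]
        flagged, _ = classify_differential(bins, pseudocount=1e-9)
        assert flagged == []
        assert bins[0].ratio == pytest.approx(1.5)

    def test_empty_bins_guarded_by_pseudocount(self):
        bins = [abin(0.0, 0.0)]
        flagged, _ = classify_differential(bins, pseudocount=1.0)
        assert flagged == []
        assert bins[0].ratio == 1.0

    def test_swap_symmetry(self, rng):
        bins = [abin(a, b, start=i * 1_000)
                for i, (a, b) in enumerate(rng.random((50, 2)) * 3)]
        swapped = [abin(b.sum_allele2, b.sum_allele1, b.start) for b in bins]
        f1, frac1 = classify_differential(bins)
        f2, frac2 = classify_differential(swapped)
        assert frac1 == frac2
        assert [b.differential for b in bins] == [b.differential for b in swapped]
        assert [b.ratio for b in bins] == pytest.approx([b.ratio for b in swapped])

    def test_invariant_to_global_rescaling(self, rng):
        bins = [abin(a, b, start=i * 1_000)
                for i, (a, b) in enumerate(rng.random((50, 2)) * 3)]
        scaled = [abin(7.0 * b.sum_allele1, 7.0 * b.sum_allele2, b.start) for b in bins]
        _, frac1 = classify_differential(bins)
        _, frac2 = classify_differential(scaled)
        assert frac1 == frac2  # default pseudocount scales with the data

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            classify_differential([abin(1.0, 1.0)], pseudocount=0.0)


class TestOverlap:
    def test_bin_inside_gene_counted(self):
        flagged = [abin(2.0, 1.0, start=5_000)]
        out = annotate_overlap(flagged, flagged,
                               genes=[GenomeInterval("chr1", 4_000, 8_000)])
        assert out["genes"]["count"] == 1
        assert out["genes"]["enrichment"] == pytest.approx(1.0)

    def test_one_bp_intersection_counts(self):
        flagged = [abin(2.0, 1.0, start=5_000)]
        out = annotate_overlap(flagged, flagged,
                               genes=[GenomeInterval("chr1", 5_999, 6_001)])
        assert out["genes"]["count"] == 1

    def test_flagged_like_all_gives_unit_enrichment(self, rng):
        all_bins = [abin(1.0, 1.0, start=i * 1_000) for i in range(100)]
        flagged = all_bins[::2]  # evenly spread: same overlap fraction as all bins
        feats = [GenomeInterval("chr1", 0, 50_000)]
        out = annotate_overlap(flagged, all_bins, promoters=feats)
        assert out["promoters"]["enrichment"] == pytest.approx(1.0)

    def test_planted_enrichment_detected(self):
        # flagged bins concentrated in the feature -> enrichment ~2
        all_bins = [abin(1.0, 1.0, start=i * 1_000) for i in range(100)]
        inside = [b for b in all_bins if b.start < 50_000]
        flagged = inside[:40] + [b for b in all_bins if b.start >= 50_000][:10]
        feats = [GenomeInterval("chr1", 0, 50_000)]
        out = annotate_overlap(flagged, all_bins, enhancers=feats)
        assert out["enhancers"]["enrichment"] == pytest.approx((40 / 50) / 0.5)

    def test_empty_feature_class(self):
        flagged = [abin(2.0, 1.0)]
        out = annotate_overlap(flagged, flagged, genes=[])
        assert out["genes"]["count"] == 0
        assert np.isnan(out["genes"]["enrichment"])


class TestSVRecord:
    def test_insertion_point_interval_allowed(self):
        r = sv(100, 101, "insertion", length=5_000)
        assert r.length == 5_000

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            sv(100, 100)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            sv(100, 200, "translocation")
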