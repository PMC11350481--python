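"""Interval model, BED I/O and the interval algebra vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sslineage.intervals import (
    GeneAnnotation,
    GenomicInterval,
    SignalPeak,
    exclude_mask,
    merge_overlapping,
    read_bed,
    stitch_intervals,
    window_query,
    write_bed,
)

from .conftest import random_peaks
from . import oracles


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    @pytest.mark.parametrize("chrom,start,end", [
        ("chr1", 100, 100),   # empty
        ("chr1", 200, 100),   # inverted
        ("chr1", -5, 10),     # negative
        ("", 0, 10),          # no chrom
        ("chr 1", 0, 10),     # whitespace
    ])
    def test_invalid_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_distance_convention(self):
        region = iv("chr1", 1_000_000, 1_010_000)
        assert region.distance_to_point(1_400_000) == 390_000
        assert region.distance_to_point(1_005_000) == 0

    def test_signal_must_be_finite_nonnegative(self):
        with pytest.raises(ValueError):
            SignalPeak(iv("chr1", 0, 10), -1.0)
        with pytest.raises(ValueError):
            SignalPeak(iv("chr1", 0, 10), float("nan"))


class TestBedIO:
    def test_parse_three_lines(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tp1\t10\n"
                     "chr1\t500\t700\tp2\t20\n"
                     "chr2\t5\t50\tp3\t5\n")
        peaks = read_bed(p)
        assert [pk.signal for pk in peaks] == [10, 20, 5]
        assert peaks[1].interval == iv("chr1", 500, 700)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_zero_length_interval_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\tx\t1\nchr1\t100\t100\tx\t1\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            read_bed(p)

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("# header\ntrack name=x\nchr1\t0\t10\tx\t3\n")
        assert len(read_bed(p)) == 1

    def test_round_trip_preserves_coordinates_and_signal(self, tmp_path, rng):
        peaks = random_peaks(rng, 30)
        out = tmp_path / "rt.bed"
        write_bed(peaks, out)
        back = read_bed(out)
        assert [p.interval for p in back] == [p.interval for p in peaks]
        assert np.allclose([p.signal for p in back], [p.signal for p in peaks],
                           rtol=1e-6)


class TestMergeOverlapping:
    def test_forced_union(self):
        merged = merge_overlapping([iv("chr1", 0, 100), iv("chr1", 50, 150)])
        assert merged == [iv("chr1", 0, 150)]

    def test_different_chromosomes_untouched(self):
        merged = merge_overlapping([iv("chr1", 0, 100), iv("chr2", 0, 100)])
        assert len(merged) == 2

    def test_matches_per_base_union_oracle(self, rng):
        ivs = [p.interval for p in random_peaks(rng, 1000)]
        merged = merge_overlapping(ivs)
        assert [(m.chrom, m.start, m.end) for m in merged] == \
            oracles.per_base_union(ivs)

    def test_idempotent(self, rng):
        ivs = [p.interval for p in random_peaks(rng, 200)]
        once = merge_overlapping(ivs)
        assert merge_overlapping(once) == once


class TestStitch:
    def test_gap_within_distance_joins(self):
        peaks = [SignalPeak(iv("chr1", 0, 100), 1),
                 SignalPeak(iv("chr1", 200, 300), 1)]
        joined = stitch_intervals(peaks, 150)
        assert len(joined) == 1
        assert joined[0].interval == iv("chr1", 0, 300)
        assert len(joined[0].constituents) == 2

    def test_gap_beyond_distance_splits(self):
        peaks = [SignalPeak(iv("chr1", 0, 100), 1),
                 SignalPeak(iv("chr1", 200, 300), 1)]
        assert len(stitch_intervals(peaks, 50)) == 2

    def test_matches_padded_union_oracle(self, rng):
        peaks = random_peaks(rng, 500, bound=90_000)
        stitched = stitch_intervals(peaks, 12_500)
        id_of = {id(p): i for i, p in enumerate(peaks)}
        got = {frozenset(id_of[id(c)] for c in s.constituents) for s in stitched}
        assert got == oracles.stitch_partition(peaks, 12_500)

    def test_distance_refinement(self, rng):
        peaks = random_peaks(rng, 150, bound=50_000)
        fine = stitch_intervals(peaks, 500)
        coarse = stitch_intervals(peaks, 5_000)
        for f in fine:
            containing = [c for c in coarse
                          if c.interval.chrom == f.interval.chrom
                          and c.interval.start <= f.interval.start
                          and f.interval.end <= c.interval.end]
            assert len(containing) == 1


class TestWindowQuery:
    ann = [GeneAnnotation("g1", "G1", "chr1", 1_400_000)]
    region = iv("chr1", 1_000_000, 1_010_000)

    def test_within_window_included(self):
        hits = window_query(self.ann, [self.region], 500_000)
        assert [g.gene_id for g in hits[self.region]] == ["g1"]

    def test_outside_window_excluded(self):
        hits = window_query(self.ann, [self.region], 100_000)
        assert hits[self.region] == []

    def test_matches_all_pairs_oracle(self, rng):
        genes = [GeneAnnotation(f"g{i}", f"g{i}",
                                ("chr1", "chr2")[int(rng.integers(2))],
                                int(rng.integers(0, 100_000)))
                 for i in range(200)]
        regions = [p.interval for p in random_peaks(rng, 20, bound=100_000)]
        window = 5_000
        got = window_query(genes, regions, window)
        want = oracles.window_hits(genes, regions, window)
        for r in regions:
            assert [g.gene_id for g in got[r]] == want[(r.chrom, r.start, r.end)]

    def test_monotone_in_window(self, rng):
        genes = [GeneAnnotation(f"g{i}", f"g{i}", "chr1",
                                int(rng.integers(0, 50_000)))
                 for i in range(100)]
        regions = [p.interval for p in random_peaks(rng, 10, bound=50_000,
                                                    chroms=("chr1",))]
        small = window_query(genes, regions, 1_000)
        large = window_query(genes, regions, 10_000)
        for r in regions:
            assert {g.gene_id for g in small[r]} <= {g.gene_id for g in large[r]}


class TestExcludeMask:
    def test_masked_peak_removed(self):
        peaks = [SignalPeak(iv("chr1", 0, 10), 1),
                 SignalPeak(iv("chr1", 100, 200), 1),
                 SignalPeak(iv("chr1", 500, 600), 1)]
        kept = exclude_mask(peaks, [iv("chr1", 150, 160)])
        assert [p.interval.start for p in kept] == [0, 500]

    def test_empty_mask_is_identity(self, rng):
        peaks = random_peaks(rng, 50)
        assert exclude_mask(peaks, []) == peaks

    def test_matches_all_pairs_oracle(self, rng):
        peaks = random_peaks(rng, 300)
        mask = [p.interval for p in random_peaks(rng, 20)]
        kept = exclude_mask(peaks, mask)
        dropped = oracles.overlapping_pairs(peaks, mask)
        assert kept == [p for i, p in enumerate(peaks) if i not in dropped]


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 5_000), st.integers(1, 500)),
                min_size=1, max_size=40))
def test_merge_is_idempotent_and_preserves_bases(pairs):
    ivs = [iv("chr1", s, s + l) for s, l in pairs]
    merged = merge_overlapping(ivs)
    assert merge_overlapping(merged) == merged
    covered = set()
    for r in ivs:
        covered.update(range(r.start, r.end))
    merged_bases = set()
    for r in merged:
        merged_bases.update(range(r.start, r.end))
    assert merged_bases == covered
    starts = [r.start for r in merged]
    assert starts == sorted(starts)
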