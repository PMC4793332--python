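import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainlen import (
    GenomicInterval,
    IntervalTrack,
    assign_nearest_tss,
    overlap_bp,
    read_bed,
    read_bedpe,
    total_overlap_bp,
    write_bed,
)
from domainlen.intervals import BedParseError, merge_instances, write_bedpe

from conftest import random_track


def make_interval(chrom="chr1", start=0, end=100, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestInterval:
    def test_length_is_end_minus_start(self):
        assert make_interval(start=10, end=25).length == 15

    @pytest.mark.parametrize("start,end", [(200, 100), (5, 5)])
    def test_rejects_empty_or_inverted(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)


class TestBedIO:
    def test_read_sorts_by_coordinate(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t50\t150\n")
        track = read_bed(p)
        assert [(iv.start, iv.end) for iv in track] == [(50, 150), (100, 200)]

    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_comment_track_browser_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# header\ntrack name=x\nbrowser position\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    @pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t5"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2:"):
            read_bed(p)

    def test_round_trip_is_coordinate_exact(self, tmp_path):
        track = IntervalTrack("t", [
            make_interval(start=5, end=9), make_interval(start=0, end=3),
            make_interval(chrom="chr2", start=1, end=2),
        ])
        write_bed(track, tmp_path / "t.bed")
        back = read_bed(tmp_path / "t.bed")
        assert [(iv.chrom, iv.start, iv.end) for iv in back] == \
            [(iv.chrom, iv.start, iv.end) for iv in track]

    def test_names_and_scores_round_trip_as_bed5(self, tmp_path):
        track = IntervalTrack("t", [make_interval(name="d1", score=3.5)])
        write_bed(track, tmp_path / "t.bed")
        line = (tmp_path / "t.bed").read_text().strip()
        assert line.split("\t") == ["chr1", "0", "100", "d1", "3.5"]
        back = read_bed(tmp_path / "t.bed")
        assert back[0].name == "d1" and back[0].score == 3.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 10**7), st.integers(1, 10**5)), max_size=30))
    def test_round_trip_property(self, tmp_path_factory, coords):
        track = IntervalTrack("t", [GenomicInterval("chr1", s, s + l) for s, l in coords])
        p = tmp_path_factory.mktemp("rt") / "t.bed"
        write_bed(track, p)
        back = read_bed(p)
        assert [(iv.start, iv.end) for iv in back] == \
            [(iv.start, iv.end) for iv in track]


class TestBedpeIO:
    def test_one_pair_per_line(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t10\tchr1\t500\t510\n")
        pairs = read_bedpe(p)
        assert len(pairs) == 1
        assert pairs[0].anchor1.length == 10 and pairs[0].anchor2.length == 10

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("")
        assert read_bedpe(p) == []

    def test_five_field_line_is_parse_error(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t10\tchr1\t500\n")
        with pytest.raises(BedParseError):
            read_bedpe(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t10\tchr2\t500\t510\tint0\n")
        pairs = read_bedpe(p)
        write_bedpe(pairs, tmp_path / "b.bedpe")
        assert read_bedpe(tmp_path / "b.bedpe") == pairs


class TestOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 100), (50, 150), 50),
        ((0, 100), (100, 200), 0),   # half-open: abutting intervals
        ((10, 20), (0, 100), 10),    # nested
        ((0, 5), (900, 950), 0),
    ])
    def test_pairwise_overlap(self, a, b, expected):
        assert overlap_bp(make_interval(start=a[0], end=a[1]),
                          make_interval(start=b[0], end=b[1])) == expected

    def test_different_chromosomes_never_overlap(self):
        assert overlap_bp(make_interval(), make_interval(chrom="chr2")) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.integers(1, 500),
           st.integers(0, 1000), st.integers(1, 500))
    def test_overlap_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert overlap_bp(a, b) == overlap_bp(b, a)
        assert 0 <= overlap_bp(a, b) <= min(a.length, b.length)

    def test_sum_rule_counts_overlapping_instances_twice(self):
        domain = make_interval(start=0, end=100)
        track = IntervalTrack("t", [make_interval(start=10, end=30),
                                    make_interval(start=20, end=40)])
        assert total_overlap_bp(domain, track) == 40

    def test_no_overlap_and_full_cover(self):
        domain = make_interval(start=0, end=100)
        assert total_overlap_bp(domain, IntervalTrack("t", [make_interval(start=500, end=600)])) == 0
        assert total_overlap_bp(domain, IntervalTrack("t", [make_interval(start=0, end=1000)])) == 100

    def test_sum_rule_at_least_union_overlap(self):
        """Per-base counting oracle: the sum rule >= the union rule, with
        equality iff overlapping-with-domain instances are pairwise disjoint."""
        rng = np.random.default_rng(42)
        domain = make_interval(start=0, end=1000)
        for _ in range(20):
            track = random_track(rng, "t", rng.integers(1, 10), span=1000)
            per_base = np.zeros(1000, dtype=int)
            for iv in track:
                per_base[max(0, iv.start):min(1000, iv.end)] += 1
            assert total_overlap_bp(domain, track) == per_base.sum()
            union = total_overlap_bp(domain, merge_instances(track))
            assert union == (per_base > 0).sum()
            assert total_overlap_bp(domain, track) >= union

    def test_agrees_with_bedtools_intersect(self, tmp_path):
        """Independent oracle: summed overlap bp must match bedtools."""
        rng = np.random.default_rng(3)
        domains = IntervalTrack("d", [make_interval(start=int(s), end=int(s) + 500)
                                      for s in range(0, 5000, 1000)])
        track = random_track(rng, "t", 30, span=5500)
        write_bed(domains, tmp_path / "d.bed")
        write_bed(track, tmp_path / "t.bed")
        out = subprocess.run(
            ["bedtools", "intersect", "-a", str(tmp_path / "d.bed"),
             "-b", str(tmp_path / "t.bed"), "-wo"],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = {}
        for line in out.strip().splitlines():
            f = line.split("\t")
            key = (int(f[1]), int(f[2]))
            expected[key] = expected.get(key, 0) + int(f[-1])
        for d in domains:
            assert total_overlap_bp(d, track) == expected.get((d.start, d.end), 0)


class TestNearestTss:
    def tss(self, positions, chrom="chr1"):
        return IntervalTrack("tss", [
            GenomicInterval(chrom, p, p + 1, name=f"g{p}") for p in positions])

    def test_contained_point_wins(self):
        domains = IntervalTrack("d", [make_interval(start=100, end=200, name="d0")])
        assert assign_nearest_tss(domains, self.tss([150, 500]))[domains[0]] == "g150"

    def test_distance_measured_from_nearest_edge(self):
        domains = IntervalTrack("d", [make_interval(start=100, end=200, name="d0")])
        # 90 is 10 bp from the start edge; 250 is 50 bp past the end edge
        assert assign_nearest_tss(domains, self.tss([250, 90]))[domains[0]] == "g90"

    def test_tie_breaks_toward_smaller_coordinate(self):
        domains = IntervalTrack("d", [make_interval(start=100, end=200)])
        assert assign_nearest_tss(domains, self.tss([90, 210]))[domains[0]] == "g90"

    def test_chromosome_without_tss_is_unassigned(self):
        domains = IntervalTrack("d", [make_interval(chrom="chrX")])
        assert assign_nearest_tss(domains, self.tss([50]))[domains[0]] == "unassigned"

    def test_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(5)
        positions = sorted(rng.choice(10_000, size=20, replace=False).tolist())
        domains = IntervalTrack("d", [
            make_interval(start=int(s), end=int(s) + int(l), name=f"d{i}")
            for i, (s, l) in enumerate(zip(rng.integers(0, 9000, 15),
                                           rng.integers(1, 800, 15)))])
        got = assign_nearest_tss(domains, self.tss(positions))
        for d in domains:
            def dist(p):
                return 0 if d.start <= p < d.end else min(abs(p - d.start), abs(p - d.end))
            best = min(positions, key=lambda p: (dist(p), p))
            assert got[d] == f"g{best}"
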