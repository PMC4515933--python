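"""Coverage track parsing, gap detection and the exon/gene reports."""

import numpy as np
import pytest

from varcurate.coverage_qc import (
    CoverageInterval,
    CoverageTrack,
    Exon,
    exon_report,
    find_gaps,
    gene_report,
    lower_median,
    read_exon_bed,
    read_per_base_coverage,
)
from varcurate.errors import ParseError


def track(*intervals, sample_id="s1"):
    return CoverageTrack(
        sample_id,
        [CoverageInterval(c, s, e, np.array(d, dtype=np.int64)) for c, s, e, d in intervals],
    )


def brute_force_gaps(track_, threshold):
    """Per-base scan oracle: every maximal run of depth < threshold."""
    gaps = []
    for iv in track_.intervals:
        run_start = None
        for i, depth in enumerate(list(iv.depths) + [threshold]):  # sentinel
            if depth < threshold and run_start is None:
                run_start = i
            elif depth >= threshold and run_start is not None:
                gaps.append((iv.chrom, iv.start + run_start, iv.start + i))
                run_start = None
    return sorted(gaps)


class TestReadPerBaseCoverage:
    def test_single_interval_assembled(self, tmp_path):
        lines = [
            f"chr1\t100\t106\tG_exon1\t{i + 1}\t{d}"
            for i, d in enumerate([10, 10, 3, 4, 10, 2])
        ]
        p = tmp_path / "cov.tsv"
        p.write_text("\n".join(lines) + "\n")
        t = read_per_base_coverage(p)
        assert len(t.intervals) == 1
        iv = t.intervals[0]
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 106)
        assert list(iv.depths) == [10, 10, 3, 4, 10, 2]

    def test_intervals_sorted_across_chromosomes(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text(
            "chr2\t10\t12\tB\t1\t5\nchr2\t10\t12\tB\t2\t5\n"
            "chr1\t50\t51\tA\t1\t9\n"
        )
        t = read_per_base_coverage(p)
        assert [(iv.chrom, iv.start) for iv in t.intervals] == [("chr1", 50), ("chr2", 10)]

    def test_missing_offset_is_parse_error(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text(
            "chr1\t0\t6\tA\t1\t9\nchr1\t0\t6\tA\t2\t9\nchr1\t0\t6\tA\t4\t9\n"
        )
        with pytest.raises(ParseError, match="offset"):
            read_per_base_coverage(p)

    def test_truncated_interval_is_parse_error(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("chr1\t0\t6\tA\t1\t9\nchr1\t0\t6\tA\t2\t9\n")
        with pytest.raises(ParseError, match="2 of 6"):
            read_per_base_coverage(p)

    def test_negative_depth_is_parse_error(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("chr1\t0\t1\tA\t1\t-4\n")
        with pytest.raises(ParseError, match="negative"):
            read_per_base_coverage(p)

    def test_five_column_format_accepted(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text("chr1\t0\t2\t1\t7\nchr1\t0\t2\t2\t8\n")
        t = read_per_base_coverage(p)
        assert list(t.intervals[0].depths) == [7, 8]


class TestFindGaps:
    def test_worked_example(self):
        t = track(("chr1", 100, 106, [10, 10, 3, 4, 10, 2]))
        gaps = find_gaps(t, 5)
        assert [(g.chrom, g.start, g.end, g.length, g.min_depth) for g in gaps] == [
            ("chr1", 102, 104, 2, 3),
            ("chr1", 105, 106, 1, 2),
        ]

    def test_all_covered_no_gaps(self):
        assert find_gaps(track(("chr1", 0, 4, [5, 6, 7, 8])), 5) == []

    def test_all_below_single_spanning_gap(self):
        gaps = find_gaps(track(("chr1", 10, 14, [1, 0, 2, 3])), 5)
        assert [(g.start, g.end) for g in gaps] == [(10, 14)]

    def test_depth_equal_to_threshold_is_covered(self):
        gaps = find_gaps(track(("chr1", 0, 3, [5, 4, 5])), 5)
        assert [(g.start, g.end) for g in gaps] == [(1, 2)]

    def test_gap_annotated_with_overlapping_exon(self):
        t = track(("chr1", 0, 10, [0] * 10))
        exons = [Exon("chr1", 0, 10, "MYH7", 3)]
        (gap,) = find_gaps(t, 5, exons)
        assert gap.gene == "MYH7" and gap.exon_rank == 3

    def test_random_tracks_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            depths = rng.integers(0, 30, size=int(rng.integers(1, 200)))
            threshold = int(rng.integers(1, 30))
            start = int(rng.integers(0, 1000))
            t = track(("chr1", start, start + len(depths), depths))
            got = sorted((g.chrom, g.start, g.end) for g in find_gaps(t, threshold))
            assert got == brute_force_gaps(t, threshold)

    def test_raising_threshold_never_shrinks_gaps(self):
        rng = np.random.default_rng(6)
        depths = rng.integers(0, 30, size=300)
        t = track(("chr1", 0, 300, depths))
        low = find_gaps(t, 10)
        high = find_gaps(t, 20)
        low_bases = set()
        for g in low:
            low_bases |= set(range(g.start, g.end))
        high_bases = set()
        for g in high:
            high_bases |= set(range(g.start, g.end))
        assert low_bases <= high_bases

    def test_gap_median_uses_lower_median(self):
        (gap,) = find_gaps(track(("chr1", 0, 4, [1, 2, 3, 4])), 5)
        assert gap.median_depth == 2


class TestExonReport:
    def test_fully_covered_exon(self):
        t = track(("chr1", 0, 10, [20] * 10))
        (row,) = exon_report(t, [Exon("chr1", 0, 10, "G", 1)], 15)
        assert row.status == "FULL" and row.fraction_below_threshold == 0.0

    def test_half_covered_exon_matches_per_base_recount(self):
        depths = [20] * 5 + [3] * 5
        t = track(("chr1", 0, 10, depths))
        (row,) = exon_report(t, [Exon("chr1", 0, 10, "G", 1)], 15)
        assert row.status == "PARTIAL"
        assert row.fraction_below_threshold == pytest.approx(0.5)
        assert row.n_below == sum(1 for d in depths if d < 15)

    def test_exon_absent_from_track_is_none_with_warning(self):
        t = track(("chr1", 0, 10, [20] * 10))
        with pytest.warns(UserWarning, match="depth 0"):
            (row,) = exon_report(t, [Exon("chr2", 0, 10, "G", 1)], 15)
        assert row.status == "NONE" and row.fraction_below_threshold == 1.0

    def test_gap_exon_conservation_identity(self):
        """Per exon, summed overlapping gap lengths equal the exon's
        below-threshold base count — an exact integer identity."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            length = int(rng.integers(20, 120))
            depths = rng.integers(0, 25, size=length)
            start = int(rng.integers(0, 500))
            exon = Exon("chr1", start, start + length, "G", 1)
            t = track(("chr1", start, start + length, depths))
            threshold = int(rng.integers(1, 25))
            (row,) = exon_report(t, [exon], threshold)
            gap_sum = sum(
                min(g.end, exon.end) - max(g.start, exon.start)
                for g in find_gaps(t, threshold)
            )
            assert gap_sum == row.n_below


class TestGeneReport:
    def make(self, depth_map, threshold=15, **kw):
        """depth_map: gene -> list of exon depth lists (contiguous)."""
        exons, intervals = [], []
        cursor = 0
        for gene, exon_depths in depth_map.items():
            for i, depths in enumerate(exon_depths, start=1):
                exons.append(Exon("chr1", cursor, cursor + len(depths), gene, i))
                intervals.append(("chr1", cursor, cursor + len(depths), depths))
                cursor += len(depths) + 10
        return gene_report(track(*intervals), exons, threshold, **kw)

    def test_all_full_is_green(self):
        (row,) = self.make({"G": [[20] * 50, [30] * 50]})
        assert row.colour == "GREEN" and row.fraction_targeted_bases_ok == 1.0

    def test_uncovered_exon_vetoes_green(self):
        # 97% of bases fine overall, but one exon entirely uncovered
        (row,) = self.make({"G": [[20] * 97, [0] * 3]})
        assert row.fraction_targeted_bases_ok == pytest.approx(0.97)
        assert row.colour == "AMBER"

    def test_half_covered_is_red(self):
        (row,) = self.make({"G": [[20] * 50, [0] * 50]})
        assert row.colour == "RED"

    def test_green_boundary_inclusive(self):
        # 97% ok in a single PARTIAL exon -> GREEN (no NONE veto applies)
        (row,) = self.make({"G": [[20] * 95 + [0] * 3 + [20, 20]]})
        assert row.fraction_targeted_bases_ok == pytest.approx(0.97)
        assert row.colour == "GREEN"
        # exactly at the amber bound -> AMBER
        (row,) = self.make({"G": [[20] * 80 + [0] * 20]})
        assert row.fraction_targeted_bases_ok == pytest.approx(0.80)
        assert row.colour == "AMBER"

    def test_exon_counts(self):
        (row,) = self.make({"G": [[20] * 10, [3] * 10, [20] * 5 + [3] * 5]})
        assert row.n_exons == 3 and row.n_exons_partial_or_none == 2


class TestLowerMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([5], 5), ([1, 2], 1), ([1, 2, 3], 2), ([1, 2, 3, 4], 2), ([], 0)],
    )
    def test_documented_lower_median(self, values, expected):
        assert lower_median(np.array(values, dtype=np.int64)) == expected


class TestReadExonBed:
    def test_named_ranks_parsed(self, tmp_path):
        p = tmp_path / "exons.bed"
        p.write_text("chr1\t10\t20\tMYH7_exon2\t0\t+\nchr1\t30\t40\tMYH7_exon3\t0\t+\n")
        exons = read_exon_bed(p)
        assert [(e.gene, e.rank) for e in exons] == [("MYH7", 2), ("MYH7", 3)]

    def test_bare_gene_names_get_positional_ranks(self, tmp_path):
        p = tmp_path / "exons.bed"
        p.write_text("chr1\t30\t40\tTTN\nchr1\t10\t20\tTTN\n")
        exons = read_exon_bed(p)
        assert [(e.start, e.rank) for e in exons] == [(10, 1), (30, 2)]
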