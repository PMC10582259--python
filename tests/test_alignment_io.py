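"""Alignment filtering, clip extraction and pileup construction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clipqc.alignment_io import (
    NGS,
    SMS,
    ClipEvent,
    ClipPileup,
    FilteredAlignment,
    build_pileup,
    coverage_stats,
    detect_gaps,
    extract_clip_events,
    load_filtered_alignments,
)

from conftest import write_bam


def _aln(contig="ctg1", start=0, end=100, cigar=((0, 100),), tech=NGS,
         read_length=None, name="r"):
    if read_length is None:
        read_length = sum(l for op, l in cigar if op in (0, 1, 4, 5, 7, 8))
    return FilteredAlignment(
        read_id=name, contig=contig, ref_start=start, ref_end=end,
        mapq=60, read_length=read_length, tech=tech, cigar=tuple(cigar),
    )


class TestFiltering:
    def test_flag_and_mapq_filters(self, tmp_path):
        """MAPQ<20 and -F 1796 flag bits drop records; clean primaries pass."""
        bam = write_bam(
            tmp_path / "t.bam",
            {"ctg1": 1000},
            [
                {"name": "low_mapq", "contig": "ctg1", "pos": 0,
                 "cigar": [(0, 100)], "mapq": 10},
                {"name": "secondary", "contig": "ctg1", "pos": 10,
                 "cigar": [(0, 100)], "flag": 256},
                {"name": "duplicate", "contig": "ctg1", "pos": 20,
                 "cigar": [(0, 100)], "flag": 1024},
                {"name": "good", "contig": "ctg1", "pos": 30, "cigar": [(0, 100)]},
            ],
        )
        kept = list(load_filtered_alignments(bam, NGS))
        assert [a.read_id for a in kept] == ["good"]
        assert kept[0].mapq == 60 and kept[0].ref_start == 30

    def test_raising_min_mapq_is_monotone(self, tmp_path):
        bam = write_bam(
            tmp_path / "t.bam",
            {"ctg1": 1000},
            [{"name": f"r{q}", "contig": "ctg1", "pos": q, "cigar": [(0, 50)],
              "mapq": q} for q in (0, 10, 20, 30, 60)],
        )
        counts = [len(list(load_filtered_alignments(bam, NGS, min_mapq=q)))
                  for q in (0, 10, 20, 30, 60, 61)]
        assert counts == sorted(counts, reverse=True)

    def test_missing_file_and_missing_index_fail(self, tmp_path):
        with pytest.raises(IOError):
            list(load_filtered_alignments(tmp_path / "absent.bam", NGS))
        bam = write_bam(tmp_path / "t.bam", {"ctg1": 100},
                        [{"name": "r", "contig": "ctg1", "pos": 0, "cigar": [(0, 50)]}])
        (tmp_path / "t.bam.bai").unlink()
        with pytest.raises(IOError):
            list(load_filtered_alignments(bam, NGS))


class TestClipExtraction:
    def test_left_soft_clip(self):
        aln = _aln(start=1000, end=1100, cigar=[(4, 50), (0, 100)])
        events = extract_clip_events(aln)
        assert len(events) == 1
        ev = events[0]
        assert (ev.side, ev.position, ev.clip_length) == ("left", 1000, 50)

    def test_unclipped_read_yields_nothing(self):
        assert extract_clip_events(_aln(cigar=[(0, 100)])) == []

    def test_both_ends_and_hard_clips(self):
        aln = _aln(start=500, end=580, cigar=[(5, 20), (4, 10), (0, 80), (4, 5)])
        events = extract_clip_events(aln)
        assert [(e.side, e.position, e.clip_length) for e in events] == [
            ("left", 500, 30), ("right", 580, 5)]

    def test_sms_short_clip_suppressed(self):
        """An SMS clip under 10% of the read length is a mapping artifact."""
        aln = _aln(start=0, end=9500, cigar=[(4, 500), (0, 9500)], tech=SMS,
                   read_length=10000)
        assert extract_clip_events(aln) == []
        long_clip = _aln(start=0, end=8000, cigar=[(4, 2000), (0, 8000)],
                         tech=SMS, read_length=10000)
        assert len(extract_clip_events(long_clip)) == 1

    def test_malformed_cigar_rejected(self):
        bad = _aln(cigar=[(0, 50), (4, 5), (0, 45)])
        with pytest.raises(ValueError):
            extract_clip_events(bad)

    @given(
        lclip=st.integers(0, 200), alen=st.integers(1, 500), rclip=st.integers(0, 200),
        start=st.integers(0, 10_000),
    )
    def test_events_sit_on_alignment_boundaries(self, lclip, alen, rclip, start):
        cigar = [(4, lclip)] if lclip else []
        cigar.append((0, alen))
        if rclip:
            cigar.append((4, rclip))
        aln = _aln(start=start, end=start + alen, cigar=cigar)
        for ev in extract_clip_events(aln):
            assert ev.position in (aln.ref_start, aln.ref_end)


def naive_pileup(alignments, events, contig_lengths):
    """Per-base brute-force recount used as the oracle."""
    depth = {(c, t): np.zeros(l, dtype=int)
             for c, l in contig_lengths.items() for t in (NGS, SMS)}
    clip = {k: np.zeros_like(v) for k, v in depth.items()}
    for a in alignments:
        for p in range(a.ref_start, a.ref_end):
            depth[(a.contig, a.tech)][p] += 1
    for e in events:
        if 0 < e.position < contig_lengths[e.contig]:
            clip[(e.contig, e.tech)][e.position] += 1
    return depth, clip


class TestPileup:
    def test_single_read_block(self):
        pileup = build_pileup([_aln(start=0, end=100)], [], {"ctg1": 500})
        depth = pileup.depth("ctg1", NGS)
        assert depth[:100].tolist() == [1] * 100
        assert depth[100:].sum() == 0

    def test_overlap_counts(self):
        alns = [_aln(start=0, end=100, name="a"), _aln(start=50, end=150, name="b")]
        depth = build_pileup(alns, [], {"ctg1": 500}).depth("ctg1", NGS)
        assert depth[60] == 2 and depth[10] == 1 and depth[120] == 1

    def test_random_instance_matches_bruteforce(self):
        """Pileup equivalence: arrays equal a naive per-base recount."""
        rng = np.random.default_rng(42)
        contig_lengths = {"ctg1": 10_000}
        alns, events = [], []
        for i in range(100):
            start = int(rng.integers(0, 9800))
            end = start + int(rng.integers(20, 200))
            end = min(end, 10_000)
            aln = _aln(start=start, end=end, name=f"r{i}",
                       cigar=[(4, 7), (0, end - start)])
            alns.append(aln)
            events.extend(extract_clip_events(aln))
        pileup = build_pileup(alns, events, contig_lengths)
        ndepth, nclip = naive_pileup(alns, events, contig_lengths)
        np.testing.assert_array_equal(pileup.depth("ctg1", NGS), ndepth[("ctg1", NGS)])
        np.testing.assert_array_equal(pileup.clip("ctg1", NGS), nclip[("ctg1", NGS)])

    def test_clipped_bases_do_not_add_depth(self):
        aln = _aln(start=100, end=200, cigar=[(4, 50), (0, 100)])
        pileup = build_pileup([aln], extract_clip_events(aln), {"ctg1": 500})
        assert pileup.depth("ctg1", NGS)[:100].sum() == 0
        assert pileup.clip("ctg1", NGS)[100] == 1

    def test_out_of_bounds_event_fatal(self):
        pileup = ClipPileup({"ctg1": 100})
        with pytest.raises(ValueError):
            pileup.add_clip_event(
                ClipEvent("ctg1", 200, "left", 5, "r", NGS))


class TestGapsAndCoverage:
    def test_exact_gap_recovered(self):
        depth = np.ones(500, dtype=np.int32)
        depth[100:150] = 0
        pileup = ClipPileup.from_arrays({"ctg1": 500}, {("ctg1", NGS): depth})
        gaps = detect_gaps(pileup)
        assert [(g.start, g.end) for g in gaps] == [(100, 150)]

    def test_positive_depth_yields_no_gaps(self):
        pileup = ClipPileup.from_arrays(
            {"ctg1": 300}, {("ctg1", NGS): np.ones(300, dtype=np.int32)})
        assert detect_gaps(pileup) == []

    def test_gap_touching_contig_end(self):
        depth = np.ones(200, dtype=np.int32)
        depth[150:] = 0
        pileup = ClipPileup.from_arrays({"ctg1": 200}, {("ctg1", NGS): depth})
        assert [(g.start, g.end) for g in detect_gaps(pileup)] == [(150, 200)]

    def test_gap_flanks_are_covered(self):
        rng = np.random.default_rng(3)
        depth = rng.integers(0, 3, size=1000).astype(np.int32)
        pileup = ClipPileup.from_arrays({"ctg1": 1000}, {("ctg1", NGS): depth})
        for g in detect_gaps(pileup):
            assert (depth[g.start:g.end] == 0).all()
            if g.start > 0:
                assert depth[g.start - 1] > 0
            if g.end < 1000:
                assert depth[g.end] > 0

    def test_uniform_coverage_stats(self):
        pileup = ClipPileup.from_arrays(
            {"ctg1": 1000}, {("ctg1", NGS): np.full(1000, 30, dtype=np.int32)})
        summary = coverage_stats(pileup)
        assert summary.mean_depth[NGS] == 30.0
        assert summary.coverage_rate[NGS] == 1.0

    def test_half_covered(self):
        depth = np.zeros(1000, dtype=np.int32)
        depth[:500] = 2
        pileup = ClipPileup.from_arrays({"ctg1": 1000}, {("ctg1", NGS): depth})
        summary = coverage_stats(pileup)
        assert summary.mean_depth[NGS] == 1.0
        assert summary.coverage_rate[NGS] == 0.5

    def test_stats_match_bruteforce(self):
        rng = np.random.default_rng(9)
        depth = rng.integers(0, 5, size=2000).astype(np.int32)
        pileup = ClipPileup.from_arrays({"ctg1": 2000}, {("ctg1", NGS): depth})
        summary = coverage_stats(pileup)
        assert summary.mean_depth[NGS] == pytest.approx(depth.sum() / 2000)
        assert summary.coverage_rate[NGS] == pytest.approx((depth > 0).mean())
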