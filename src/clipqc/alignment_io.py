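"""Alignment input, filtering, clip extraction and per-position pileups.

The evidence the whole pipeline runs on is collected here: which alignments
survive the quality filter, where their clipped ends fall, and how read depth
and clip counts distribute along each contig, kept separately for short-read
(NGS) and long-read (SMS) data.

Coordinates are 0-based half-open throughout. A left clip's breakpoint is the
first aligned base of the record (``ref_start``); a right clip's breakpoint is
one past the last aligned base (``ref_end``), so breakpoints are directly
BED-compatible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

NGS = "NGS"
SMS = "SMS"
TECHS = (NGS, SMS)

DEFAULT_MIN_MAPQ = 20
#: unmapped + secondary + QC-fail + duplicate (samtools -F 1796)
DEFAULT_EXCLUDE_FLAGS = 1796
DEFAULT_SMS_MIN_CLIP_FRAC = 0.1

# CIGAR operation codes (BAM encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S, _CIGAR_H = 0, 1, 2, 3, 4, 5
_CIGAR_EQ, _CIGAR_X = 7, 8
_CLIP_OPS = (_CIGAR_S, _CIGAR_H)
_REF_OPS = (_CIGAR_M, _CIGAR_D, _CIGAR_N, _CIGAR_EQ, _CIGAR_X)


class ConsistencyError(ValueError):
    """Inputs disagree with each other (e.g. contig missing from assembly)."""


@dataclass(frozen=True)
class FilteredAlignment:
    """One alignment record that passed the mapping-quality/flag filter."""

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    mapq: int
    read_length: int
    tech: str
    cigar: Tuple[Tuple[int, int], ...]
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError(
                f"empty aligned block {self.ref_start}-{self.ref_end} for {self.read_id}"
            )


@dataclass(frozen=True)
class ClipEvent:
    """A clipped alignment end: candidate breakpoint evidence.

    ``position`` equals ``ref_start`` of the source alignment for a left clip
    and ``ref_end`` for a right clip.
    """

    contig: str
    position: int
    side: str  # "left" | "right"
    clip_length: int
    read_id: str
    tech: str


@dataclass(frozen=True)
class GapInterval:
    """Maximal zero-coverage run [start, end) for one technology."""

    contig: str
    start: int
    end: int
    tech: str = NGS


@dataclass(frozen=True)
class CoverageSummary:
    """Genome-wide mean depth and breadth of coverage, per technology."""

    mean_depth: Dict[str, float]
    coverage_rate: Dict[str, float]


class ClipPileup:
    """Per-contig, per-tech integer arrays of read depth and clip counts.

    ``depth[p]`` counts accepted alignments whose aligned reference span
    covers ``p`` (clipped read portions contribute nothing). ``clip[p]``
    counts clip events whose breakpoint is ``p``.
    """

    def __init__(self, contig_lengths: Mapping[str, int]):
        if not contig_lengths:
            raise ValueError("empty assembly: no contigs")
        self.contig_lengths: Dict[str, int] = dict(contig_lengths)
        # depth is built as a boundary-difference array (length L+1), then
        # finalized by cumulative sum; clip counts are direct.
        self._diff: Dict[Tuple[str, str], np.ndarray] = {}
        self._clip: Dict[Tuple[str, str], np.ndarray] = {}
        self._depth: Dict[Tuple[str, str], np.ndarray] = {}
        for contig, length in self.contig_lengths.items():
            if length <= 0:
                raise ValueError(f"contig {contig} has non-positive length")
            for tech in TECHS:
                self._diff[(contig, tech)] = np.zeros(length + 1, dtype=np.int32)
                self._clip[(contig, tech)] = np.zeros(length, dtype=np.int32)
        self._finalized = False

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        contig_lengths: Mapping[str, int],
        depth: Mapping[Tuple[str, str], np.ndarray] = (),
        clip: Mapping[Tuple[str, str], np.ndarray] = (),
    ) -> "ClipPileup":
        """Build a pileup directly from (contig, tech) -> array mappings.

        Arrays not supplied default to zero. Intended for constructing
        controlled scenarios; lengths must match the contig lengths.
        """
        pileup = cls(contig_lengths)
        for key, arr in dict(depth).items():
            arr = np.asarray(arr, dtype=np.int32)
            if len(arr) != pileup.contig_lengths[key[0]]:
                raise ValueError(f"depth array length mismatch for {key}")
            pileup._depth[key] = arr
        for key, arr in dict(clip).items():
            arr = np.asarray(arr, dtype=np.int32)
            if len(arr) != pileup.contig_lengths[key[0]]:
                raise ValueError(f"clip array length mismatch for {key}")
            pileup._clip[key] = arr
        for contig, length in pileup.contig_lengths.items():
            for tech in TECHS:
                if (contig, tech) not in pileup._depth:
                    pileup._depth[(contig, tech)] = np.zeros(length, dtype=np.int32)
        pileup._finalized = True
        return pileup

    def add_alignment(self, aln: FilteredAlignment) -> None:
        key = (aln.contig, aln.tech)
        if key not in self._diff:
            raise ConsistencyError(f"contig {aln.contig!r} absent from assembly")
        length = self.contig_lengths[aln.contig]
        if aln.ref_end > length:
            raise ConsistencyError(
                f"alignment end {aln.ref_end} beyond contig {aln.contig} ({length} bp)"
            )
        self._diff[key][aln.ref_start] += 1
        self._diff[key][aln.ref_end] -= 1
        self._finalized = False

    def add_clip_event(self, event: ClipEvent, drop_terminal: bool = True) -> None:
        key = (event.contig, event.tech)
        if key not in self._clip:
            raise ConsistencyError(f"contig {event.contig!r} absent from assembly")
        length = self.contig_lengths[event.contig]
        if event.position < 0 or event.position > length:
            raise ConsistencyError(
                f"clip position {event.position} outside contig {event.contig}"
            )
        # Contig termini clip trivially (every read hanging off an end is
        # clipped there); terminal events carry no error signal.
        if drop_terminal and (event.position == 0 or event.position == length):
            return
        if event.position == length:  # right clip exactly at the end
            return
        self._clip[key][event.position] += 1

    def _finalize(self) -> None:
        for key, diff in self._diff.items():
            self._depth[key] = np.cumsum(diff[:-1], dtype=np.int64).astype(np.int32)
        self._finalized = True

    # -- access ------------------------------------------------------------
    def depth(self, contig: str, tech: str) -> np.ndarray:
        if not self._finalized:
            self._finalize()
        return self._depth[(contig, tech)]

    def clip(self, contig: str, tech: str) -> np.ndarray:
        return self._clip[(contig, tech)]

    @property
    def assembly_size(self) -> int:
        return sum(self.contig_lengths.values())

    def contigs(self) -> List[str]:
        return list(self.contig_lengths)


def _check_index(path: str) -> None:
    """BAM inputs must be indexed; SAM text is accepted for small fixtures."""
    if str(path).endswith(".bam"):
        for ext in (".bai", ".csi"):
            if os.path.exists(str(path) + ext):
                return
        base = str(path)[:-4]
        if os.path.exists(base + ".bai"):
            return
        raise IOError(f"missing BAM index for {path} (run samtools index)")


def load_filtered_alignments(
    bam_path,
    tech: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
    keep_supplementary: bool = True,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> Iterator[FilteredAlignment]:
    """Stream accepted alignments from a coordinate-sorted BAM/SAM file.

    Records with ``mapq < min_mapq`` or any bit of ``exclude_flags`` set are
    dropped (defaults reproduce ``samtools view -F 1796 -q 20``).
    Supplementary alignments (flag 2048) are not in that mask and are kept
    unless ``keep_supplementary=False``.
    """
    if tech not in TECHS:
        raise ValueError(f"unknown tech {tech!r}")
    if not os.path.exists(str(bam_path)):
        raise IOError(f"alignment file not found: {bam_path}")
    _check_index(bam_path)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.flag & exclude_flags:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            if not keep_supplementary and rec.is_supplementary:
                continue
            contig = rec.reference_name
            if contig_lengths is not None and contig not in contig_lengths:
                raise ConsistencyError(f"contig {contig!r} absent from assembly")
            read_length = rec.infer_read_length()
            if read_length is None:
                read_length = rec.query_length
            yield FilteredAlignment(
                read_id=rec.query_name,
                contig=contig,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                mapq=rec.mapping_quality,
                read_length=int(read_length),
                tech=tech,
                cigar=tuple(rec.cigartuples),
                is_supplementary=rec.is_supplementary,
            )


def _terminal_clip(cigar: Sequence[Tuple[int, int]], reverse: bool) -> int:
    """Summed length of the run of clip operators at one CIGAR end."""
    ops = reversed(cigar) if reverse else iter(cigar)
    total = 0
    for op, length in ops:
        if op in _CLIP_OPS:
            total += length
        else:
            break
    return total


def _validate_cigar(cigar: Sequence[Tuple[int, int]]) -> None:
    seen_internal = False
    n = len(cigar)
    for i, (op, length) in enumerate(cigar):
        if length <= 0:
            raise ValueError(f"malformed CIGAR: non-positive op length at {i}")
        if op in _CLIP_OPS:
            head = all(o in _CLIP_OPS for o, _ in cigar[:i])
            tail = all(o in _CLIP_OPS for o, _ in cigar[i + 1 :])
            if not (head or tail):
                raise ValueError("malformed CIGAR: clip operator in the interior")
        else:
            seen_internal = True
    if n and not seen_internal:
        raise ValueError("malformed CIGAR: no aligned block")


def extract_clip_events(
    aln: FilteredAlignment,
    sms_min_clip_frac: float = DEFAULT_SMS_MIN_CLIP_FRAC,
) -> List[ClipEvent]:
    """Clip events (soft S or hard H) at either end of one alignment.

    Hard clips count as evidence with their CIGAR length even though the
    bases are absent from the record. For SMS reads, clips shorter than
    ``sms_min_clip_frac`` of the full read length are routine mapping
    artifacts of noisy long reads and are suppressed; NGS clips are kept at
    any length.
    """
    _validate_cigar(aln.cigar)
    events: List[ClipEvent] = []
    for side, reverse, position in (
        ("left", False, aln.ref_start),
        ("right", True, aln.ref_end),
    ):
        clip_len = _terminal_clip(aln.cigar, reverse)
        if clip_len == 0:
            continue
        if aln.tech == SMS and aln.read_length > 0:
            if clip_len < sms_min_clip_frac * aln.read_length:
                continue
        events.append(
            ClipEvent(
                contig=aln.contig,
                position=position,
                side=side,
                clip_length=clip_len,
                read_id=aln.read_id,
                tech=aln.tech,
            )
        )
    return events


def build_pileup(
    alignments: Iterable[FilteredAlignment],
    clip_events: Iterable[ClipEvent],
    contig_lengths: Mapping[str, int],
) -> ClipPileup:
    """Accumulate depth and clip-count arrays from pre-extracted streams."""
    pileup = ClipPileup(contig_lengths)
    for aln in alignments:
        pileup.add_alignment(aln)
    for event in clip_events:
        pileup.add_clip_event(event)
    return pileup


def pileup_from_bams(
    contig_lengths: Mapping[str, int],
    ngs_bam=None,
    sms_bam=None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
    keep_supplementary: bool = True,
    sms_min_clip_frac: float = DEFAULT_SMS_MIN_CLIP_FRAC,
) -> ClipPileup:
    """Single-pass convenience: filter, extract clips and pile up per tech."""
    pileup = ClipPileup(contig_lengths)
    for tech, path in ((NGS, ngs_bam), (SMS, sms_bam)):
        if path is None:
            continue
        for aln in load_filtered_alignments(
            path,
            tech,
            min_mapq=min_mapq,
            exclude_flags=exclude_flags,
            keep_supplementary=keep_supplementary,
            contig_lengths=contig_lengths,
        ):
            pileup.add_alignment(aln)
            for event in extract_clip_events(aln, sms_min_clip_frac=sms_min_clip_frac):
                pileup.add_clip_event(event)
    return pileup


def detect_gaps(pileup: ClipPileup, tech: str = NGS, min_len: int = 1) -> List[GapInterval]:
    """Maximal runs of zero depth with length >= ``min_len``, per contig."""
    gaps: List[GapInterval] = []
    for contig in pileup.contigs():
        depth = pileup.depth(contig, tech)
        zero = depth == 0
        if not zero.any():
            continue
        padded = np.concatenate(([False], zero, [False]))
        change = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = change[::2], change[1::2]
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                gaps.append(GapInterval(contig=contig, start=int(s), end=int(e), tech=tech))
    return gaps


def coverage_stats(pileup: ClipPileup) -> CoverageSummary:
    """Mean depth (aligned bases / assembly length) and covered fraction."""
    total = pileup.assembly_size
    if total == 0:
        raise ValueError("empty assembly")
    mean_depth: Dict[str, float] = {}
    rate: Dict[str, float] = {}
    for tech in TECHS:
        bases = 0
        covered = 0
        for contig in pileup.contigs():
            depth = pileup.depth(contig, tech)
            bases += int(depth.sum(dtype=np.int64))
            covered += int(np.count_nonzero(depth))
        mean_depth[tech] = bases / total
        rate[tech] = covered / total
    return CoverageSummary(mean_depth=mean_depth, coverage_rate=rate)
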