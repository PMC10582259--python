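"""Synthetic benchmark: genomes, planted defects, emulated alignments, scoring.

The generator reproduces a desk-scale version of the standard benchmarking
protocol for assembly evaluators: take a clean genome, plant (a) heterozygous
variants, which exist in one of the two donor haplotypes and must NOT be
called errors, and (b) assembly errors, which corrupt the assembly-under-test
relative to both haplotypes; then sequence both haplotypes and ask the caller
to recover exactly the planted defects.

Read alignments are emulated analytically instead of running an aligner: read
start positions are sampled uniformly over the assembly and each read's
alignment record is derived from the planted truth. A read crossing a
structural junction is soft-clipped exactly at the junction coordinate; a
short read crossing a regional defect clips at the defect anchor while long
reads span it; reads elsewhere align full length. This makes the truth->clip
mapping exact and the whole pipeline hermetic (no aligner, no downloads)
while exercising every downstream contract on valid, indexed BAM files.

By default each sampled fragment is sequenced once from each haplotype
(``mirrored_haplotypes``), so heterozygous loci carry an exactly balanced
allele fraction; independent per-read haplotype sampling is available via
``mirrored_haplotypes=False``.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .aqi_report import f1_score
from .corrector import SplitRecord
from .error_classifier import CRE, CRH, CSE, CSH, ErrorCall

# defect categories
HET_SMALL = "het_small_indel"
HET_SV = "het_sv"
REG_INDEL = "regional_indel"
REPEAT_CE = "repeat_collapse_expansion"
FRAG_INDEL = "fragment_indel"
MISJOIN = "misjoin"
INVERSION = "inversion"
LARGE_REPEAT = "large_repeat"

EXPECTED_CALL = {
    HET_SMALL: CRH,
    HET_SV: CSH,
    REG_INDEL: CRE,
    REPEAT_CE: CRE,
    FRAG_INDEL: CSE,
    MISJOIN: CSE,
    INVERSION: CSE,
    LARGE_REPEAT: CSE,
}

#: categories whose junctions clip long (SMS) reads as well as short reads
_SMS_CLIP_CATS = frozenset({FRAG_INDEL, MISJOIN, INVERSION, LARGE_REPEAT, HET_SV})
#: categories that clip only reads from the variant haplotype
_HET_CATS = frozenset({HET_SMALL, HET_SV})
_ERROR_CATS = frozenset({REG_INDEL, REPEAT_CE, FRAG_INDEL, MISJOIN, INVERSION, LARGE_REPEAT})

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TruthRecord:
    """One planted defect, in assembly-under-test coordinates."""

    category: str
    contig: str
    start: int
    end: int
    size: int
    expected_call: str


@dataclass
class SimSpec:
    """Conditions of the scaled-down benchmark simulation.

    Defaults are the desk-scale protocol: a 2-Mb diploid genome carrying 300
    heterozygous variants (270 small indels, 30 SVs larger than a long read)
    and an assembly with 150 regional errors (120 small indels, 30 repeat
    collapses/expansions) and 40 structural errors (8 fragment indels, 16
    misjoin junctions, 16 inversions), sequenced at 40x short-read and 30x
    long-read emulated coverage.
    """

    genome_length: int = 2_000_000
    n_contigs: int = 2
    seed: int = 1
    # defect counts
    n_het_small: int = 270
    n_het_sv: int = 30
    n_regional_indel: int = 120
    n_repeat_ce: int = 30
    n_fragment_indel: int = 8
    n_misjoin: int = 16
    n_inversion: int = 16
    n_large_repeat: int = 0
    # defect size ranges (bp, inclusive)
    size_het_small: Tuple[int, int] = (1, 40)
    size_het_sv: Tuple[int, int] = (15_000, 40_000)
    size_regional_indel: Tuple[int, int] = (1, 40)
    size_repeat_ce: Tuple[int, int] = (20, 100)
    size_fragment_indel: Tuple[int, int] = (100, 1000)
    size_misjoin: Tuple[int, int] = (2000, 8000)
    size_inversion: Tuple[int, int] = (1000, 5000)
    size_large_repeat: Tuple[int, int] = (5000, 20_000)
    # sequencing
    ngs_depth: float = 40.0
    sms_depth: float = 30.0
    ngs_read_len: int = 150
    sms_len_mean: int = 10_000
    sms_len_sd: int = 2000
    sms_len_min: int = 1000
    sms_len_max: int = 60_000
    het_fraction_reads: float = 0.5
    mirrored_haplotypes: bool = True
    ngs_error_rate: float = 0.001
    sms_error_rate: float = 0.005
    # placement geometry: junctions that clip long reads must sit further
    # apart than a read length so their clipping ratios stay independent
    wide_sep: int = 15_000
    wide_margin: int = 20_000
    base_sep: int = 600
    base_margin: int = 1000

    def counts(self) -> Dict[str, int]:
        return {
            HET_SMALL: self.n_het_small,
            HET_SV: self.n_het_sv,
            REG_INDEL: self.n_regional_indel,
            REPEAT_CE: self.n_repeat_ce,
            FRAG_INDEL: self.n_fragment_indel,
            MISJOIN: self.n_misjoin,
            INVERSION: self.n_inversion,
            LARGE_REPEAT: self.n_large_repeat,
        }

    def size_range(self, category: str) -> Tuple[int, int]:
        return {
            HET_SMALL: self.size_het_small,
            HET_SV: self.size_het_sv,
            REG_INDEL: self.size_regional_indel,
            REPEAT_CE: self.size_repeat_ce,
            FRAG_INDEL: self.size_fragment_indel,
            MISJOIN: self.size_misjoin,
            INVERSION: self.size_inversion,
            LARGE_REPEAT: self.size_large_repeat,
        }[category]


@dataclass(frozen=True)
class _Locus:
    """A planned defect in genome coordinates (pre-edit)."""

    category: str
    contig: str
    pos: int
    size: int
    is_insertion: bool = False
    partner_pos: int = -1  # misjoin: the exchanged segment's start


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_genome(
    length: int,
    seed: int,
    repeat_fraction: float = 0.0,
    return_repeats: bool = False,
):
    """Random A/C/G/T sequence, optionally with planted tandem repeats.

    Deterministic for a given seed. With ``repeat_fraction > 0``, tandem
    arrays (unit 100-500 bp, 3-10 copies) are overwritten onto the random
    background until they occupy approximately the requested fraction.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length)
    repeats: List[Tuple[int, int]] = []
    planted = 0
    while planted < repeat_fraction * length:
        unit_len = int(rng.integers(100, 501))
        copies = int(rng.integers(3, 11))
        span = unit_len * copies
        if span >= length:
            break
        start = int(rng.integers(0, length - span))
        unit = rng.choice(_BASES, size=unit_len)
        arr[start : start + span] = np.tile(unit, copies)
        repeats.append((start, start + span))
        planted += span
    seq = arr.tobytes().decode()
    if return_repeats:
        return seq, repeats
    return seq


# ---------------------------------------------------------------------------
# defect placement


class _PlacementError(RuntimeError):
    pass


def _plan_loci(
    spec: SimSpec,
    contig_lengths: Mapping[str, int],
    rng: np.random.Generator,
    categories: Optional[Sequence[str]] = None,
) -> List[_Locus]:
    """Sample non-overlapping defect loci satisfying the separation rules.

    Wide categories (junctions that clip long reads) keep ``wide_sep``
    between one another and ``wide_margin`` from contig ends; all loci keep
    ``base_sep`` between their footprints.
    """
    contigs = list(contig_lengths)
    lengths = np.array([contig_lengths[c] for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    intervals: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    wide_pos: Dict[str, List[int]] = {c: [] for c in contigs}

    def fits(contig: str, pos: int, footprint: int, wide: bool) -> bool:
        L = contig_lengths[contig]
        margin = spec.wide_margin if wide else spec.base_margin
        margin = min(margin, max(L // 10, 1))
        if pos < margin or pos + footprint > L - margin:
            return False
        ivs = intervals[contig]
        i = bisect.bisect_left(ivs, (pos, pos + footprint))
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if not (pos + footprint + spec.base_sep <= s or e + spec.base_sep <= pos):
                    return False
        if wide:
            wp = wide_pos[contig]
            k = bisect.bisect_left(wp, pos)
            for j in (k - 1, k):
                if 0 <= j < len(wp) and abs(wp[j] - pos) < spec.wide_sep:
                    return False
        return True

    def accept(contig: str, pos: int, footprint: int, wide: bool) -> None:
        bisect.insort(intervals[contig], (pos, pos + footprint))
        if wide:
            bisect.insort(wide_pos[contig], pos)

    def sample_one(contig: str, footprint: int, wide: bool, tries: int = 2000):
        L = contig_lengths[contig]
        for _ in range(tries):
            pos = int(rng.integers(0, max(1, L - footprint)))
            if fits(contig, pos, footprint, wide):
                return pos
        return None

    counts = spec.counts()
    if categories is not None:
        counts = {c: n for c, n in counts.items() if c in categories}
    loci: List[_Locus] = []

    # misjoins are placed in pairs on the same contig (exchanged segments)
    n_misjoin = counts.pop(MISJOIN, 0)
    for _ in range(n_misjoin // 2):
        size = int(rng.integers(*_incl(spec.size_range(MISJOIN))))
        placed = False
        for _ in range(200):
            contig = contigs[int(rng.choice(len(contigs), p=weights))]
            p1 = sample_one(contig, size, wide=True)
            if p1 is None:
                continue
            accept(contig, p1, size, wide=True)
            p2 = sample_one(contig, size, wide=True)
            if p2 is None:
                intervals[contig].remove((p1, p1 + size))
                wide_pos[contig].remove(p1)
                continue
            accept(contig, p2, size, wide=True)
            loci.append(_Locus(MISJOIN, contig, p1, size, partner_pos=p2))
            loci.append(_Locus(MISJOIN, contig, p2, size, partner_pos=p1))
            placed = True
            break
        if not placed:
            raise _PlacementError("cannot place misjoin pair; genome too crowded")
    if n_misjoin % 2:
        # odd leftover: realized as an in-place transposition of two halves
        counts[INVERSION] = counts.get(INVERSION, 0)  # keep counts untouched
        size = int(rng.integers(*_incl(spec.size_range(MISJOIN))))
        for _ in range(200):
            contig = contigs[int(rng.choice(len(contigs), p=weights))]
            p1 = sample_one(contig, size, wide=True)
            if p1 is not None:
                accept(contig, p1, size, wide=True)
                loci.append(_Locus(MISJOIN, contig, p1, size, partner_pos=-1))
                break
        else:
            raise _PlacementError("cannot place misjoin; genome too crowded")

    order = [HET_SV, LARGE_REPEAT, INVERSION, FRAG_INDEL, REPEAT_CE, REG_INDEL, HET_SMALL]
    for category in order:
        n = counts.get(category, 0)
        lo, hi = spec.size_range(category)
        wide = category in _SMS_CLIP_CATS
        for _ in range(n):
            size = int(rng.integers(lo, hi + 1))
            is_ins = bool(rng.integers(0, 2))
            if category == HET_SV or category == LARGE_REPEAT:
                is_ins = True  # insertions: no assembly footprint beyond the junction
            footprint = 1 if is_ins else size
            if category in (INVERSION, MISJOIN):
                footprint = size
            placed = False
            for _ in range(200):
                contig = contigs[int(rng.choice(len(contigs), p=weights))]
                pos = sample_one(contig, footprint, wide)
                if pos is not None:
                    accept(contig, pos, footprint, wide)
                    loci.append(_Locus(category, contig, pos, size, is_insertion=is_ins))
                    placed = True
                    break
            if not placed:
                raise _PlacementError(
                    f"cannot place {category} locus; genome too crowded"
                )
    loci.sort(key=lambda l: (l.contig, l.pos))
    return loci


def _incl(rng_pair: Tuple[int, int]) -> Tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# edit application


def _as_dict(genome: Union[str, Mapping[str, str]]) -> Dict[str, str]:
    if isinstance(genome, str):
        return {"ctg1": genome}
    return dict(genome)


def _apply_haplotype_edits(
    genome: Mapping[str, str], loci: Sequence[_Locus], rng: np.random.Generator
) -> Dict[str, str]:
    """Variant haplotype: genome with the heterozygous edits applied."""
    hap: Dict[str, str] = {}
    for contig, seq in genome.items():
        parts: List[str] = []
        cursor = 0
        for locus in [l for l in loci if l.contig == contig and l.category in _HET_CATS]:
            parts.append(seq[cursor : locus.pos])
            if locus.is_insertion:
                parts.append(_random_bases(rng, locus.size))
                cursor = locus.pos
            else:
                cursor = locus.pos + locus.size  # deletion in the variant haplotype
        parts.append(seq[cursor:])
        hap[contig] = "".join(parts)
    return hap


def _apply_assembly_edits(
    genome: Mapping[str, str], loci: Sequence[_Locus], rng: np.random.Generator
) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Assembly-under-test plus the full truth table in assembly coordinates.

    Heterozygous loci do not edit the assembly but are walked together with
    the error loci so that their coordinates are lifted through every
    upstream insertion/deletion.
    """
    assembly: Dict[str, str] = {}
    truth: List[TruthRecord] = []
    for contig, seq in genome.items():
        parts: List[str] = []
        alen = 0
        cursor = 0
        for locus in [l for l in loci if l.contig == contig]:
            gap = seq[cursor : locus.pos]
            parts.append(gap)
            alen += len(gap)
            cursor = locus.pos
            a = alen  # assembly coordinate of the defect anchor
            cat = locus.category
            if cat in _HET_CATS:
                end = a + (1 if locus.is_insertion else locus.size)
                truth.append(
                    TruthRecord(cat, contig, a, end, locus.size, EXPECTED_CALL[cat])
                )
                continue
            if cat in (REG_INDEL, REPEAT_CE, FRAG_INDEL):
                if locus.is_insertion:
                    if cat == REPEAT_CE and locus.pos >= locus.size:
                        ins = seq[locus.pos - locus.size : locus.pos]  # local expansion
                    else:
                        ins = _random_bases(rng, locus.size)
                    parts.append(ins)
                    alen += locus.size
                    truth.append(
                        TruthRecord(cat, contig, a, a + locus.size, locus.size, EXPECTED_CALL[cat])
                    )
                else:
                    cursor = locus.pos + locus.size  # collapse/deletion
                    truth.append(
                        TruthRecord(cat, contig, a, a + 1, locus.size, EXPECTED_CALL[cat])
                    )
            elif cat == INVERSION:
                parts.append(revcomp(seq[locus.pos : locus.pos + locus.size]))
                alen += locus.size
                cursor = locus.pos + locus.size
                truth.append(
                    TruthRecord(cat, contig, a, a + locus.size, locus.size, EXPECTED_CALL[cat])
                )
            elif cat == MISJOIN:
                if locus.partner_pos >= 0:
                    donor = seq[locus.partner_pos : locus.partner_pos + locus.size]
                else:  # unpaired: transpose the segment's two halves
                    half = locus.size // 2
                    seg = seq[locus.pos : locus.pos + locus.size]
                    donor = seg[half:] + seg[:half]
                parts.append(donor)
                alen += locus.size
                cursor = locus.pos + locus.size
                truth.append(
                    TruthRecord(cat, contig, a, a + locus.size, locus.size, EXPECTED_CALL[cat])
                )
            elif cat == LARGE_REPEAT:
                src = int(rng.integers(0, max(1, len(seq) - locus.size)))
                parts.append(seq[src : src + locus.size])
                alen += locus.size
                truth.append(
                    TruthRecord(cat, contig, a, a + locus.size, locus.size, EXPECTED_CALL[cat])
                )
            else:  # pragma: no cover
                raise ValueError(f"unknown category {cat}")
        parts.append(seq[cursor:])
        assembly[contig] = "".join(parts)
    truth.sort(key=lambda t: (t.contig, t.start))
    return assembly, truth


# ---------------------------------------------------------------------------
# public construction API


@dataclass
class SimResult:
    spec: SimSpec
    genome: Dict[str, str]
    haplotype: Dict[str, str]
    assembly: Dict[str, str]
    truth: List[TruthRecord]

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.assembly.items()}


def inject_heterozygous_variants(
    genome: Union[str, Mapping[str, str]], spec: SimSpec, seed: int
) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Plant heterozygous variants only; the assembly itself is unchanged.

    Returns the variant haplotype and truth records (which, with no assembly
    errors, are in genome == assembly coordinates).
    """
    genome = _as_dict(genome)
    rng = np.random.default_rng(seed)
    lengths = {c: len(s) for c, s in genome.items()}
    loci = _plan_loci(spec, lengths, rng, categories=_HET_CATS)
    hap = _apply_haplotype_edits(genome, loci, np.random.default_rng(seed + 1))
    _, truth = _apply_assembly_edits(genome, loci, np.random.default_rng(seed + 2))
    return hap, truth


def inject_assembly_errors(
    genome: Union[str, Mapping[str, str]], spec: SimSpec, seed: int
) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Plant assembly errors only; returns the erroneous assembly and truth."""
    genome = _as_dict(genome)
    rng = np.random.default_rng(seed)
    lengths = {c: len(s) for c, s in genome.items()}
    loci = _plan_loci(spec, lengths, rng, categories=_ERROR_CATS)
    return _apply_assembly_edits(genome, loci, np.random.default_rng(seed + 1))


def simulate(spec: SimSpec, seed: Optional[int] = None) -> SimResult:
    """Full construction: genome, variant haplotype, assembly and truth."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    base = spec.genome_length // spec.n_contigs
    genome: Dict[str, str] = {}
    for i in range(spec.n_contigs):
        length = base if i < spec.n_contigs - 1 else spec.genome_length - base * (
            spec.n_contigs - 1
        )
        genome[f"ctg{i + 1}"] = generate_genome(length, int(rng.integers(2**31)))
    lengths = {c: len(s) for c, s in genome.items()}
    loci = _plan_loci(spec, lengths, rng)
    haplotype = _apply_haplotype_edits(genome, loci, rng)
    assembly, truth = _apply_assembly_edits(genome, loci, rng)
    return SimResult(
        spec=spec, genome=genome, haplotype=haplotype, assembly=assembly, truth=truth
    )


# ---------------------------------------------------------------------------
# alignment emulation


def _anchor_arrays(
    truth: Sequence[TruthRecord], contig: str
) -> Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]]:
    """Clip-anchor coordinates per tech and haplotype.

    Each entry is ``(positions, two_sided)``: at a two-sided junction
    (assembly errors, which break reads of both haplotypes) a crossing read
    aligns its longer portion and clips the shorter one, on either side of
    the junction. At a one-sided anchor (variant-haplotype reads at a
    heterozygous locus) reads align downstream of the anchor with a left
    clip, so they keep supporting depth at the anchor itself and the
    clipping ratio stays at the allele fraction.
    """
    sel = [t for t in truth if t.contig == contig]

    def arr(categories) -> List[Tuple[int, bool]]:
        return [
            (t.start, t.category not in _HET_CATS)
            for t in sel
            if t.category in categories
        ]

    out: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    for tech, cats_a, cats_b in (
        ("NGS", _ERROR_CATS, _ERROR_CATS | _HET_CATS),
        (
            "SMS",
            _ERROR_CATS & _SMS_CLIP_CATS,
            (_ERROR_CATS & _SMS_CLIP_CATS) | {HET_SV},
        ),
    ):
        out[tech] = {}
        for hap, cats in (("A", cats_a), ("B", cats_b)):
            pairs = sorted(arr(cats))
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            two_sided = np.array([s for _, s in pairs], dtype=bool)
            out[tech][hap] = (pos, two_sided)
    return out


def _emulate_read(
    seq: str,
    start: int,
    length: int,
    anchors: np.ndarray,
    two_sided: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[int, List[Tuple[int, int]], str]:
    """Alignment position, CIGAR and SEQ for one emulated read.

    The read is clipped at the first truth junction strictly inside its
    span (the clipped bases no longer match the assembly there). At a
    two-sided junction the longer portion aligns; otherwise the downstream
    portion aligns (left clip), and is right-clipped at the next junction
    if the span crosses a second one.
    """
    end = start + length
    i = int(np.searchsorted(anchors, start + 1))
    b1 = -1
    if i < len(anchors) and anchors[i] <= end - 1:
        b1 = int(anchors[i])
    if b1 < 0:
        return start, [(0, length)], seq[start:end]
    if two_sided[i] and (b1 - start) > length // 2:
        # longer portion is upstream: align [start, b1), clip the tail
        rclip = end - b1
        return (
            start,
            [(0, b1 - start), (4, rclip)],
            seq[start:b1] + _random_bases(rng, rclip),
        )
    aligned_end = end
    if i + 1 < len(anchors) and anchors[i + 1] <= end - 1:
        aligned_end = int(anchors[i + 1])
    lclip = b1 - start
    alen = aligned_end - b1
    rclip = end - aligned_end
    cigar: List[Tuple[int, int]] = [(4, lclip), (0, alen)]
    if rclip:
        cigar.append((4, rclip))
    read_seq = (
        _random_bases(rng, lclip) + seq[b1:aligned_end] + _random_bases(rng, rclip)
    )
    return b1, cigar, read_seq


def _mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    if n <= 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n):
        chars[pos] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def emulate_alignments(
    assembly: Mapping[str, str],
    truth: Sequence[TruthRecord],
    spec: SimSpec,
    seed: int,
    out_ngs,
    out_sms,
) -> Tuple[str, str]:
    """Write coordinate-sorted, indexed NGS and SMS BAMs for the assembly.

    Reads are sampled uniformly at the requested depths; for heterozygous
    simulation half of the reads carry the variant haplotype (exactly half
    under mirrored sampling). MAPQ is 60 and strand is random; clipped
    portions carry random bases so they do not match the assembly.
    """
    rng = np.random.default_rng(seed)
    contigs = list(assembly)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(assembly[c])} for c in contigs],
        }
    )
    paths = {"NGS": str(out_ngs), "SMS": str(out_sms)}
    for tech, depth in (("NGS", spec.ngs_depth), ("SMS", spec.sms_depth)):
        with pysam.AlignmentFile(paths[tech], "wb", header=header) as bam:
            for ci, contig in enumerate(contigs):
                seq = assembly[contig]
                L = len(seq)
                anchors = _anchor_arrays(truth, contig)[tech]
                records = _emulate_contig_reads(
                    seq, L, anchors, tech, depth, spec, rng
                )
                records.sort(key=lambda r: r[0])
                for idx, (pos, cigar, read_seq, flag) in enumerate(records):
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{tech}_{contig}_{idx}"
                    a.flag = flag
                    a.reference_id = ci
                    a.reference_start = pos
                    a.mapping_quality = 60
                    a.cigartuples = cigar
                    a.query_sequence = read_seq
                    bam.write(a)
        pysam.index(paths[tech])
    return paths["NGS"], paths["SMS"]


def _emulate_contig_reads(
    seq: str,
    L: int,
    anchors: Dict[str, np.ndarray],
    tech: str,
    depth: float,
    spec: SimSpec,
    rng: np.random.Generator,
) -> List[Tuple[int, List[Tuple[int, int]], str, int]]:
    if tech == "NGS":
        rl = spec.ngs_read_len
        if L <= rl:
            return []
        per_hap = depth / 2.0
        n_starts = int(round(per_hap * (L - rl + 1) / rl))
        err_rate = spec.ngs_error_rate
        lengths = np.full(n_starts, rl, dtype=np.int64)
        starts = rng.integers(0, L - rl + 1, size=n_starts)
    else:
        mean = spec.sms_len_mean
        n_starts = int(round(depth * L / (2.0 * mean)))
        err_rate = spec.sms_error_rate
        lengths = np.clip(
            rng.normal(mean, spec.sms_len_sd, size=n_starts),
            spec.sms_len_min,
            min(spec.sms_len_max, L - 1),
        ).astype(np.int64)
        starts = (rng.random(n_starts) * (L - lengths)).astype(np.int64)

    if spec.mirrored_haplotypes:
        plan = [(int(s), int(l), hap) for s, l in zip(starts, lengths) for hap in "AB"]
        plan_lengths = np.repeat(lengths, 2)
    else:
        haps = np.where(rng.random(2 * n_starts) < spec.het_fraction_reads, "B", "A")
        starts2 = np.concatenate([starts, rng.integers(0, L - lengths + 1)])
        plan_lengths = np.concatenate([lengths, lengths])
        plan = [
            (int(s), int(l), h) for s, l, h in zip(starts2, plan_lengths, haps)
        ]

    n_err = (
        rng.poisson(err_rate * plan_lengths)
        if err_rate > 0
        else np.zeros(len(plan), dtype=np.int64)
    )
    flags = rng.integers(0, 2, size=len(plan)) * 16
    records = []
    for k, (start, length, hap) in enumerate(plan):
        pos_arr, two_sided = anchors[hap]
        pos, cigar, read_seq = _emulate_read(
            seq, start, length, pos_arr, two_sided, rng
        )
        if n_err[k]:
            read_seq = _mutate(read_seq, int(n_err[k]), rng)
        records.append((pos, cigar, read_seq, int(flags[k])))
    return records


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ClassMetrics:
    n_truth: int
    n_calls: int
    n_matched: int

    @property
    def recall(self) -> float:
        return 100.0 if self.n_truth == 0 else 100.0 * self.n_matched / self.n_truth

    @property
    def precision(self) -> float:
        return 100.0 if self.n_calls == 0 else 100.0 * self.n_matched / self.n_calls

    @property
    def f1(self) -> float:
        return f1_score(self.recall, self.precision)


@dataclass
class BenchmarkResult:
    per_class: Dict[str, ClassMetrics]
    overall: ClassMetrics
    matched: List[Tuple[int, int]]  # (truth index, call index)
    unmatched_truth: List[int]
    unmatched_calls: List[int]


def evaluate_calls(
    calls: Sequence[ErrorCall],
    truth: Sequence[TruthRecord],
    tolerance: int = 50,
    class_map: Optional[Mapping[str, str]] = None,
) -> BenchmarkResult:
    """Match calls against truth within the locus or +-tolerance of a boundary.

    Each call matches at most one truth record of its own class; pairs are
    assigned greedily by distance (ties resolved leftward). ``class_map``
    optionally merges classes before matching (e.g. CRH and CSH into one
    heterozygosity family).
    """

    def mapped(cls: str) -> str:
        return class_map.get(cls, cls) if class_map else cls

    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if c.contig != t.contig or mapped(c.type) != mapped(t.expected_call):
                continue
            dist = max(0, t.start - c.position, c.position - (t.end - 1))
            if dist <= tolerance:
                pairs.append((dist, c.position, t.start, ti, ci))
    pairs.sort()
    used_t: set = set()
    used_c: set = set()
    matched: List[Tuple[int, int]] = []
    for _, _, _, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matched.append((ti, ci))

    classes = sorted(
        {mapped(t.expected_call) for t in truth} | {mapped(c.type) for c in calls}
    )
    per_class: Dict[str, ClassMetrics] = {}
    for cls in classes:
        t_idx = [i for i, t in enumerate(truth) if mapped(t.expected_call) == cls]
        c_idx = [i for i, c in enumerate(calls) if mapped(c.type) == cls]
        n_matched = sum(1 for ti, ci in matched if ti in set(t_idx))
        per_class[cls] = ClassMetrics(len(t_idx), len(c_idx), n_matched)
    overall = ClassMetrics(len(truth), len(calls), len(matched))
    return BenchmarkResult(
        per_class=per_class,
        overall=overall,
        matched=matched,
        unmatched_truth=[i for i in range(len(truth)) if i not in used_t],
        unmatched_calls=[i for i in range(len(calls)) if i not in used_c],
    )


def lift_truth(
    truth: Sequence[TruthRecord], records: Sequence[SplitRecord]
) -> List[TruthRecord]:
    """Map truth records into the coordinates of a corrected (split) assembly.

    A record is assigned to the part containing its anchor (start); spans
    running past a cut are truncated at the part boundary. A structural
    junction that coincides with a cut becomes a contig start, where no read
    can cross it any more — exactly the point of splitting.
    """
    by_source: Dict[str, List[SplitRecord]] = {}
    for r in records:
        by_source.setdefault(r.source_contig, []).append(r)
    for parts in by_source.values():
        parts.sort(key=lambda r: r.source_start)
    lifted: List[TruthRecord] = []
    for t in truth:
        parts = by_source.get(t.contig)
        if parts is None:
            lifted.append(t)
            continue
        for part in parts:
            if part.source_start <= t.start < part.source_end:
                start = t.start - part.source_start
                end = min(t.end, part.source_end) - part.source_start
                lifted.append(
                    replace(t, contig=part.new_name, start=start, end=max(end, start + 1))
                )
                break
    return lifted


# ---------------------------------------------------------------------------
# text I/O

_TRUTH_COLUMNS = ["category", "contig", "start", "end", "size", "expected_call"]


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.category}\t{t.contig}\t{t.start}\t{t.end}\t{t.size}\t{t.expected_call}\n"
            )


def read_truth(path) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    with open(str(path)) as fh:
        fh.readline()
        for line in fh:
            cat, contig, start, end, size, exp = line.rstrip("\n").split("\t")
            out.append(TruthRecord(cat, contig, int(start), int(end), int(size), exp))
    return out


def write_fasta(sequences: Mapping[str, str], path, line_width: int = 60) -> None:
    with open(str(path), "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
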