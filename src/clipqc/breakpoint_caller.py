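"""Per-position classification of clipped sites.

At a clipped position the clipping ratio (clipped reads / total depth) is the
discriminating statistic: about 0.5 means half the reads carry the alternate
haplotype (a heterozygous locus), while a ratio near 1 means essentially every
read refuses to align through, the signature of an assembly breakpoint.

Labels, in increasing order of clip evidence:

``none`` < ``het`` < ``ambiguous`` < ``breakpoint``

with ``excluded`` for positions whose depth is too low or too high to trust.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .alignment_io import NGS, SMS, ClipPileup, coverage_stats

LABEL_NONE = "none"
LABEL_HET = "het"
LABEL_AMBIGUOUS = "ambiguous"
LABEL_BREAKPOINT = "breakpoint"
LABEL_EXCLUDED = "excluded"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the position classifier.

    h_low, h_high
        Heterozygosity band for the clipping ratio (closed interval).
    f
        Breakpoint cutoff: ratio >= f is a mapping breakpoint.
    min_cov
        Minimum depth m below which a position is excluded.
    max_cov_mult
        High-coverage multiplier M: positions deeper than M * mean depth
        are excluded (collapsed-repeat pileups are untrustworthy).
    sms_cluster_radius
        Merge radius (bp) for noisy SMS clip positions.
    sms_min_clip_frac
        Minimum SMS clip length as a fraction of the read length.
    """

    h_low: float = 0.4
    h_high: float = 0.6
    f: float = 0.75
    min_cov: int = 2
    max_cov_mult: float = 5.0
    sms_cluster_radius: int = 20
    sms_min_clip_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.h_low < self.h_high < self.f <= 1):
            raise ValueError("need 0 <= h_low < h_high < f <= 1")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if self.max_cov_mult <= 1:
            raise ValueError("max_cov_mult must be > 1")


@dataclass(frozen=True)
class PositionCall:
    contig: str
    position: int
    tech: str
    clip_count: int
    depth: int
    ratio: float
    label: str


@dataclass(frozen=True)
class LowConfidenceRegion:
    contig: str
    start: int
    end: int
    reason: str  # "low_coverage" | "high_coverage"


def classify_position(
    clip_count: int,
    depth: int,
    params: CallerParams,
    mean_depth: float,
) -> str:
    """Label one position from its clip count and depth (total function)."""
    if depth < params.min_cov or depth > params.max_cov_mult * mean_depth:
        return LABEL_EXCLUDED
    ratio = clip_count / depth
    if ratio >= params.f:
        return LABEL_BREAKPOINT
    if ratio > params.h_high:
        return LABEL_AMBIGUOUS
    if ratio >= params.h_low:
        return LABEL_HET
    return LABEL_NONE


def call_positions(
    pileup: ClipPileup,
    params: CallerParams,
    mean_depth: Optional[Dict[str, float]] = None,
    per_contig_mean: bool = False,
) -> List[PositionCall]:
    """One call per clipped position per tech; label ``none`` is omitted.

    The high-coverage filter uses the genome-wide mean depth of the matching
    technology by default; ``per_contig_mean=True`` switches the reference
    mean to each contig's own.
    """
    if mean_depth is None:
        mean_depth = coverage_stats(pileup).mean_depth
    calls: List[PositionCall] = []
    for contig in pileup.contigs():
        for tech in (NGS, SMS):
            clip = pileup.clip(contig, tech)
            positions = np.flatnonzero(clip)
            if positions.size == 0:
                continue
            depth = pileup.depth(contig, tech)
            mean = (
                float(depth.mean()) if per_contig_mean else mean_depth[tech]
            )
            for pos in positions:
                c = int(clip[pos])
                d = int(depth[pos])
                label = classify_position(c, d, params, mean)
                if label == LABEL_NONE:
                    continue
                calls.append(
                    PositionCall(
                        contig=contig,
                        position=int(pos),
                        tech=tech,
                        clip_count=c,
                        depth=d,
                        ratio=c / d if d else 0.0,
                        label=label,
                    )
                )
    calls.sort(key=lambda c: (c.contig, c.position, c.tech))
    return calls


def cluster_sms_breakpoints(
    calls: Sequence[PositionCall],
    params: CallerParams,
    mean_depth: float,
    radius: Optional[int] = None,
) -> List[PositionCall]:
    """Merge SMS calls lying within ``radius`` bp of each other.

    Long-read clip coordinates wobble by a few bases around a junction;
    transitively merging nearby positions restores a single-nucleotide
    representative. The representative is the member with the largest clip
    count (ties go left); the merged clip count is the cluster sum, depth is
    the representative's, and the label is recomputed from the merged ratio.
    Idempotent: clustering an already clustered list is a no-op.
    """
    if radius is None:
        radius = params.sms_cluster_radius
    out: List[PositionCall] = []
    by_contig: Dict[str, List[PositionCall]] = {}
    for call in calls:
        if call.tech != SMS:
            raise ValueError("cluster_sms_breakpoints expects SMS calls only")
        by_contig.setdefault(call.contig, []).append(call)
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda c: c.position)
        cluster: List[PositionCall] = []
        for call in members:
            if cluster and call.position - cluster[-1].position > radius:
                out.append(_merge_cluster(cluster, params, mean_depth))
                cluster = []
            cluster.append(call)
        if cluster:
            out.append(_merge_cluster(cluster, params, mean_depth))
    out.sort(key=lambda c: (c.contig, c.position))
    return out


def _merge_cluster(
    cluster: List[PositionCall], params: CallerParams, mean_depth: float
) -> PositionCall:
    if len(cluster) == 1:
        return cluster[0]
    rep = max(cluster, key=lambda c: (c.clip_count, -c.position))
    total_clip = sum(c.clip_count for c in cluster)
    label = classify_position(total_clip, rep.depth, params, mean_depth)
    return replace(
        rep,
        clip_count=total_clip,
        ratio=total_clip / rep.depth if rep.depth else 0.0,
        label=label,
    )


def find_low_confidence_regions(
    pileup: ClipPileup,
    params: CallerParams,
    min_len: int = 100,
    mean_depth: Optional[float] = None,
) -> List[LowConfidenceRegion]:
    """NGS depth runs below ``min_cov`` or above M * mean, length >= min_len.

    Error calls falling inside these regions are reported but flagged and do
    not enter the quality index.
    """
    if mean_depth is None:
        mean_depth = coverage_stats(pileup).mean_depth[NGS]
    high_cut = params.max_cov_mult * mean_depth
    regions: List[LowConfidenceRegion] = []
    for contig in pileup.contigs():
        depth = pileup.depth(contig, NGS)
        for reason, mask in (
            ("low_coverage", depth < params.min_cov),
            ("high_coverage", depth > high_cut),
        ):
            if not mask.any():
                continue
            padded = np.concatenate(([False], mask, [False]))
            change = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in zip(change[::2], change[1::2]):
                if e - s >= min_len:
                    regions.append(
                        LowConfidenceRegion(
                            contig=contig, start=int(s), end=int(e), reason=reason
                        )
                    )
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions


def in_regions(
    contig: str, position: int, regions: Sequence[LowConfidenceRegion]
) -> bool:
    return any(
        r.contig == contig and r.start <= position < r.end for r in regions
    )
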