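"""Integration of NGS and SMS evidence into typed error/heterozygosity calls.

Four final call types:

CRE
    regional error — short reads break (clip or vanish) but long reads span
    the locus cleanly; typically a small indel or local consensus problem.
CSE
    structural error — long reads clip too, corroborated by a short-read
    breakpoint or a short-read coverage gap within the flank; implies a
    misjoin-scale defect.
CRH / CSH
    regional / structural heterozygosity — about half the reads clip,
    i.e. the alternate haplotype, not an error.

Decision rules are applied in priority order (structural evidence subsumes
regional evidence at the same junction); every junction yields at most one
call because a structural call consumes the short-read evidence it matched.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import NGS, SMS, ClipPileup, GapInterval
from .breakpoint_caller import (
    LABEL_AMBIGUOUS,
    LABEL_BREAKPOINT,
    LABEL_HET,
    CallerParams,
    LowConfidenceRegion,
    PositionCall,
    in_regions,
)

CRE = "CRE"
CSE = "CSE"
CRH = "CRH"
CSH = "CSH"
ERROR_TYPES = (CRE, CSE)
HET_TYPES = (CRH, CSH)
CALL_TYPES = ERROR_TYPES + HET_TYPES


@dataclass(frozen=True)
class ClassifierParams:
    """Windows and cutoffs of the CRE/CSE decision rules.

    cse_flank
        Half-width (bp) of the corroboration window around a breakpoint.
    cre_flank / cre_window
        Span and sliding-window width (bp) of the SMS coverage-discrepancy
        test around an NGS breakpoint.
    d
        Coverage-discrepancy cutoff for CRE calls; 0 disables the test so
        that spanning long reads alone validate a regional error.
    csh_depth_drop
        NGS depth drop (fraction, vs. flanking means) that corroborates a
        structural heterozygosity call when no NGS het site is present;
        approximates one missing haplotype.
    error_region
        When on, each call additionally carries the enclosing NGS
        zero-coverage interval as its error region.
    """

    cse_flank: int = 100
    cre_flank: int = 200
    cre_window: int = 20
    d: float = 0.0
    csh_depth_drop: float = 0.4
    error_region: bool = False

    def __post_init__(self) -> None:
        if self.cre_window > self.cre_flank:
            raise ValueError("cre_window must not exceed cre_flank")
        if not (0 <= self.d <= 1):
            raise ValueError("d must be in [0, 1]")


@dataclass(frozen=True)
class ErrorCall:
    """A typed call at a single-nucleotide breakpoint."""

    contig: str
    position: int
    type: str
    ngs_evidence: str  # breakpoint | gap | het | coverage_drop
    sms_evidence: str  # spanning | breakpoint | het
    clip_count: int
    depth: int
    ratio: float
    region: Optional[Tuple[int, int]] = None
    low_confidence: bool = False


def coverage_discrepancy(
    sms_depth: np.ndarray,
    position: int,
    flank: int = 200,
    window: int = 20,
) -> float:
    """Relative spread of windowed SMS coverage around a breakpoint.

    Tiles the +-flank region with ``window``-bp windows (truncated at contig
    edges), takes each window's mean depth and returns
    (max - min) / max; 1.0 when the maximum is zero. A collapsed or expanded
    segment shows up as a large discrepancy between the two sides.
    """
    length = len(sms_depth)
    lo = max(0, position - flank)
    hi = min(length, position + flank)
    means: List[float] = []
    start = lo
    while start < hi:
        end = min(start + window, hi)
        if end > start:
            means.append(float(sms_depth[start:end].mean()))
        start = end
    if not means:
        return 0.0
    mx = max(means)
    if mx == 0:
        return 1.0
    return (mx - min(means)) / mx


class _ContigEvidence:
    """Sorted per-contig evidence indexes for windowed queries."""

    def __init__(
        self,
        contig: str,
        ngs_calls: Sequence[PositionCall],
        sms_calls: Sequence[PositionCall],
        gaps: Sequence[GapInterval],
    ):
        self.contig = contig
        self.ngs_bp = sorted(
            (c for c in ngs_calls if c.label == LABEL_BREAKPOINT),
            key=lambda c: c.position,
        )
        self.ngs_het = sorted(
            (c for c in ngs_calls if c.label == LABEL_HET), key=lambda c: c.position
        )
        self.sms_bp = sorted(
            (c for c in sms_calls if c.label == LABEL_BREAKPOINT),
            key=lambda c: c.position,
        )
        self.sms_het = sorted(
            (c for c in sms_calls if c.label == LABEL_HET), key=lambda c: c.position
        )
        self.ngs_bp_pos = [c.position for c in self.ngs_bp]
        self.ngs_het_pos = [c.position for c in self.ngs_het]
        self.sms_bp_pos = [c.position for c in self.sms_bp]
        self.sms_het_pos = [c.position for c in self.sms_het]
        self.gaps = sorted(gaps, key=lambda g: g.start)

    @staticmethod
    def _any_within(sorted_pos: List[int], lo: int, hi: int) -> bool:
        i = bisect.bisect_left(sorted_pos, lo)
        return i < len(sorted_pos) and sorted_pos[i] <= hi

    @staticmethod
    def _indices_within(sorted_pos: List[int], lo: int, hi: int) -> range:
        return range(
            bisect.bisect_left(sorted_pos, lo), bisect.bisect_right(sorted_pos, hi)
        )

    def gap_overlapping(self, lo: int, hi: int) -> Optional[int]:
        """Index of a gap intersecting [lo, hi], else None."""
        for i, g in enumerate(self.gaps):
            if g.start <= hi and g.end > lo:
                return i
            if g.start > hi:
                break
        return None


def _window_min(depth: np.ndarray, position: int, flank: int) -> float:
    lo = max(0, position - flank)
    hi = min(len(depth), position + flank + 1)
    if hi <= lo:
        return 0.0
    return float(depth[lo:hi].min())


def classify_all(
    ngs_calls: Sequence[PositionCall],
    sms_calls: Sequence[PositionCall],
    gaps: Sequence[GapInterval],
    pileup: ClipPileup,
    params: ClassifierParams,
    caller_params: CallerParams,
    low_confidence: Sequence[LowConfidenceRegion] = (),
) -> Tuple[List[ErrorCall], List[PositionCall]]:
    """Apply the decision rules to every candidate exactly once.

    Returns the typed calls (sorted by contig, position) and the ambiguous
    position track (ratios between h_high and f, never counted as errors).

    Rule order per contig:

    1. SMS breakpoint + NGS breakpoint or NGS zero coverage within the flank
       -> CSE at the SMS position (matched NGS breakpoints and gaps are
       consumed).
    2. Remaining NGS breakpoint spanned by SMS reads (depth >= min_cov across
       the flank, no SMS breakpoint nearby) -> CRE; optional coverage
       discrepancy test when d > 0.
    3. Remaining gaps, clear of existing calls, spanned by SMS -> CRE
       anchored at the gap start.
    4. NGS het with cleanly spanning SMS and no SMS het/breakpoint nearby
       -> CRH.
    5. SMS het corroborated by an NGS het or an NGS depth drop -> CSH.
    """
    flank = params.cse_flank
    ambiguous = [
        c for c in list(ngs_calls) + list(sms_calls) if c.label == LABEL_AMBIGUOUS
    ]
    calls: List[ErrorCall] = []

    ngs_by_contig: Dict[str, List[PositionCall]] = {}
    sms_by_contig: Dict[str, List[PositionCall]] = {}
    gaps_by_contig: Dict[str, List[GapInterval]] = {}
    for c in ngs_calls:
        ngs_by_contig.setdefault(c.contig, []).append(c)
    for c in sms_calls:
        sms_by_contig.setdefault(c.contig, []).append(c)
    for g in gaps:
        gaps_by_contig.setdefault(g.contig, []).append(g)

    for contig in pileup.contigs():
        ev = _ContigEvidence(
            contig,
            ngs_by_contig.get(contig, ()),
            sms_by_contig.get(contig, ()),
            gaps_by_contig.get(contig, ()),
        )
        sms_depth = pileup.depth(contig, SMS)
        ngs_depth = pileup.depth(contig, NGS)
        consumed_ngs_bp: set = set()
        consumed_gaps: set = set()
        contig_calls: List[ErrorCall] = []

        # (1) structural errors
        for call in ev.sms_bp:
            lo, hi = call.position - flank, call.position + flank
            matched_bp = list(ev._indices_within(ev.ngs_bp_pos, lo, hi))
            gap_idx = ev.gap_overlapping(lo, hi)
            if not matched_bp and gap_idx is None:
                continue  # SMS-only breakpoint: no short-read corroboration
            consumed_ngs_bp.update(matched_bp)
            if gap_idx is not None:
                consumed_gaps.update(
                    i
                    for i, g in enumerate(ev.gaps)
                    if g.start <= hi and g.end > lo
                )
            contig_calls.append(
                ErrorCall(
                    contig=contig,
                    position=call.position,
                    type=CSE,
                    ngs_evidence="breakpoint" if matched_bp else "gap",
                    sms_evidence="breakpoint",
                    clip_count=call.clip_count,
                    depth=call.depth,
                    ratio=call.ratio,
                )
            )

        # (2) regional errors at NGS breakpoints
        for i, call in enumerate(ev.ngs_bp):
            if i in consumed_ngs_bp:
                continue
            lo, hi = call.position - flank, call.position + flank
            if ev._any_within(ev.sms_bp_pos, lo, hi):
                continue
            if _window_min(sms_depth, call.position, flank) < caller_params.min_cov:
                continue
            if params.d > 0:
                disc = coverage_discrepancy(
                    sms_depth, call.position, params.cre_flank, params.cre_window
                )
                if disc < params.d:
                    continue
            contig_calls.append(
                ErrorCall(
                    contig=contig,
                    position=call.position,
                    type=CRE,
                    ngs_evidence="breakpoint",
                    sms_evidence="spanning",
                    clip_count=call.clip_count,
                    depth=call.depth,
                    ratio=call.ratio,
                )
            )

        # (3) regional errors at uncorroborated gaps
        call_positions = sorted(c.position for c in contig_calls)
        for i, gap in enumerate(ev.gaps):
            if i in consumed_gaps:
                continue
            lo, hi = gap.start - flank, gap.end - 1 + flank
            if ev._any_within(call_positions, lo, hi):
                continue  # junction already explained by a call
            if ev._any_within(ev.sms_bp_pos, lo, hi):
                continue
            if (
                _window_min(sms_depth, gap.start, flank) < caller_params.min_cov
                or _window_min(sms_depth, gap.end - 1, flank) < caller_params.min_cov
            ):
                continue
            if params.d > 0:
                disc = coverage_discrepancy(
                    sms_depth, gap.start, params.cre_flank, params.cre_window
                )
                if disc < params.d:
                    continue
            contig_calls.append(
                ErrorCall(
                    contig=contig,
                    position=gap.start,
                    type=CRE,
                    ngs_evidence="gap",
                    sms_evidence="spanning",
                    clip_count=0,
                    depth=0,
                    ratio=0.0,
                    region=(gap.start, gap.end),
                )
            )

        # (4) regional heterozygosity
        for call in ev.ngs_het:
            lo, hi = call.position - flank, call.position + flank
            if ev._any_within(ev.sms_bp_pos, lo, hi):
                continue
            if ev._any_within(ev.sms_het_pos, lo, hi):
                continue  # structural het takes over (rule 5)
            if _window_min(sms_depth, call.position, flank) < caller_params.min_cov:
                continue
            contig_calls.append(
                ErrorCall(
                    contig=contig,
                    position=call.position,
                    type=CRH,
                    ngs_evidence="het",
                    sms_evidence="spanning",
                    clip_count=call.clip_count,
                    depth=call.depth,
                    ratio=call.ratio,
                )
            )

        # (5) structural heterozygosity
        for call in ev.sms_het:
            lo, hi = call.position - flank, call.position + flank
            if ev._any_within(ev.ngs_het_pos, lo, hi):
                ngs_ev = "het"
            elif _ngs_depth_drop(ngs_depth, call.position, flank) >= params.csh_depth_drop:
                ngs_ev = "coverage_drop"
            else:
                continue
            contig_calls.append(
                ErrorCall(
                    contig=contig,
                    position=call.position,
                    type=CSH,
                    ngs_evidence=ngs_ev,
                    sms_evidence="het",
                    clip_count=call.clip_count,
                    depth=call.depth,
                    ratio=call.ratio,
                )
            )

        calls.extend(contig_calls)

    if low_confidence:
        calls = [
            replace(c, low_confidence=in_regions(c.contig, c.position, low_confidence))
            for c in calls
        ]
    if params.error_region:
        gaps_list = list(gaps)
        calls = [refine_error_region(c, gaps_list, pileup) for c in calls]
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls, ambiguous


def _ngs_depth_drop(ngs_depth: np.ndarray, position: int, flank: int) -> float:
    """Depth drop in +-flank vs. the surrounding 2*flank on each side."""
    n = len(ngs_depth)
    lo, hi = max(0, position - flank), min(n, position + flank + 1)
    inner = float(ngs_depth[lo:hi].mean()) if hi > lo else 0.0
    left = ngs_depth[max(0, position - 3 * flank) : lo]
    right = ngs_depth[hi : min(n, position + 3 * flank + 1)]
    outer_vals = np.concatenate([left, right]) if (len(left) or len(right)) else None
    if outer_vals is None or len(outer_vals) == 0:
        return 0.0
    outer = float(outer_vals.mean())
    if outer <= 0:
        return 0.0
    return max(0.0, 1.0 - inner / outer)


def refine_error_region(
    call: ErrorCall, gaps: Sequence[GapInterval], pileup: ClipPileup
) -> ErrorCall:
    """Attach the enclosing NGS zero-coverage interval as the error region.

    Long-read junction neighbourhoods are noisy; when short reads leave a
    mapping gap there, the gap delimits where the true breakpoint lies. The
    single-nucleotide position is unchanged; without an enclosing gap the
    region degenerates to one base.
    """
    if call.region is not None:
        return call
    for g in gaps:
        if g.contig == call.contig and g.start <= call.position < g.end:
            return replace(call, region=(g.start, g.end))
    return replace(call, region=(call.position, call.position + 1))


def classify_candidate(
    candidate,
    ngs_calls: Sequence[PositionCall],
    sms_calls: Sequence[PositionCall],
    gaps: Sequence[GapInterval],
    pileup: ClipPileup,
    params: ClassifierParams,
    caller_params: CallerParams,
) -> Optional[ErrorCall]:
    """Classify a single candidate position or gap (convenience wrapper).

    Runs the full rule set and returns the call emitted at the candidate's
    position (a gap candidate is matched on its interval), or None.
    """
    calls, _ = classify_all(
        ngs_calls, sms_calls, gaps, pileup, params, caller_params
    )
    if isinstance(candidate, GapInterval):
        for c in calls:
            if c.contig == candidate.contig and (
                c.position == candidate.start
                or (c.region or (None, None))[0] == candidate.start
            ):
                return c
        return None
    for c in calls:
        if c.contig == candidate.contig and c.position == candidate.position:
            return c
    return None
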