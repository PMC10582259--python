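"""End-to-end orchestration: BAMs in, typed calls and quality report out."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pyfaidx

from . import alignment_io as aio
from .alignment_io import NGS, SMS, ClipPileup, CoverageSummary, GapInterval
from .aqi_report import AQIReport, DEFAULT_WINDOW_FRAC, summarize, write_outputs
from .breakpoint_caller import (
    CallerParams,
    LowConfidenceRegion,
    PositionCall,
    call_positions,
    cluster_sms_breakpoints,
    find_low_confidence_regions,
)
from .error_classifier import ClassifierParams, ErrorCall, classify_all


@dataclass
class PipelineResult:
    calls: List[ErrorCall]
    ambiguous: List[PositionCall]
    low_confidence: List[LowConfidenceRegion]
    gaps: List[GapInterval]
    coverage: CoverageSummary
    report: AQIReport
    pileup: ClipPileup


def contig_lengths_from_fasta(path) -> Dict[str, int]:
    fasta = pyfaidx.Fasta(str(path))
    return {name: len(fasta[name]) for name in fasta.keys()}


def run_calling(
    ngs_bam,
    sms_bam,
    assembly_fasta=None,
    contig_lengths: Optional[Mapping[str, int]] = None,
    caller_params: Optional[CallerParams] = None,
    classifier_params: Optional[ClassifierParams] = None,
    min_mapq: int = aio.DEFAULT_MIN_MAPQ,
    exclude_flags: int = aio.DEFAULT_EXCLUDE_FLAGS,
    keep_supplementary: bool = True,
    gap_min_len: int = 1,
    low_conf_min_len: int = 100,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    per_contig_mean: bool = False,
) -> PipelineResult:
    """Run filter -> pileup -> position calls -> classification -> report.

    Contig lengths come from the assembly FASTA (``.fai``-indexed) when
    given, else from the BAM header of the NGS file.
    """
    if contig_lengths is None:
        if assembly_fasta is not None:
            contig_lengths = contig_lengths_from_fasta(assembly_fasta)
        else:
            import pysam

            with pysam.AlignmentFile(str(ngs_bam), check_sq=False) as af:
                contig_lengths = dict(zip(af.references, af.lengths))
    caller_params = caller_params or CallerParams()
    classifier_params = classifier_params or ClassifierParams()

    pileup = aio.pileup_from_bams(
        contig_lengths,
        ngs_bam=ngs_bam,
        sms_bam=sms_bam,
        min_mapq=min_mapq,
        exclude_flags=exclude_flags,
        keep_supplementary=keep_supplementary,
        sms_min_clip_frac=caller_params.sms_min_clip_frac,
    )
    coverage = aio.coverage_stats(pileup)
    position_calls = call_positions(
        pileup, caller_params, mean_depth=coverage.mean_depth,
        per_contig_mean=per_contig_mean,
    )
    ngs_calls = [c for c in position_calls if c.tech == NGS]
    sms_calls = cluster_sms_breakpoints(
        [c for c in position_calls if c.tech == SMS],
        caller_params,
        coverage.mean_depth[SMS],
    )
    gaps = aio.detect_gaps(pileup, tech=NGS, min_len=gap_min_len)
    low_conf = find_low_confidence_regions(
        pileup, caller_params, min_len=low_conf_min_len,
        mean_depth=coverage.mean_depth[NGS],
    )
    calls, ambiguous = classify_all(
        ngs_calls,
        sms_calls,
        gaps,
        pileup,
        classifier_params,
        caller_params,
        low_confidence=low_conf,
    )
    report = summarize(
        calls,
        coverage,
        contig_lengths,
        ambiguous=ambiguous,
        low_confidence=low_conf,
        frac=window_frac,
    )
    return PipelineResult(
        calls=calls,
        ambiguous=ambiguous,
        low_confidence=low_conf,
        gaps=gaps,
        coverage=coverage,
        report=report,
        pileup=pileup,
    )
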