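"""Window-normalized error counts and assembly quality indexes (AQI).

Raw error counts overweight pathological regions (peri-centromeres pile up
hundreds of breakpoints); counts are therefore damped per window with the
partial harmonic sum

    Nw = sum_{i=1..m} 1/i      (m errors in the window -> Nw; 3 -> 1.83)

over non-overlapping windows of width 0.0001 x assembly size, and converted
to a score in (0, 100]:

    R-AQI = 100 * exp(-0.1 * N / L)        (regional errors)
    S-AQI = 100 * exp(-0.1 * 10 * N / L)   (structural errors, tenfold penalty)

with N the cumulative normalized count and L the assembly length in Mb.
A structural error implies a misjoin, hence the heavier rate.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .alignment_io import CoverageSummary, NGS, SMS
from .breakpoint_caller import LowConfidenceRegion, PositionCall
from .error_classifier import CALL_TYPES, CRE, CRH, CSE, CSH, ErrorCall

REGIONAL_RATE = 0.1
STRUCTURAL_PENALTY = 10.0
DEFAULT_WINDOW_FRAC = 0.0001


@dataclass(frozen=True)
class WindowStat:
    """One window's raw (m) and harmonic-normalized (Nw) error count."""

    contig: str
    window_index: int
    start: int
    end: int
    m: int
    nw: float


@dataclass
class FragmentStat:
    name: str
    length: int
    n_cre: float = 0.0
    n_cse: float = 0.0
    n_crh: float = 0.0
    n_csh: float = 0.0
    r_aqi: float = 100.0
    s_aqi: float = 100.0
    cre_per_mb: float = 0.0
    cse_per_mb: float = 0.0
    crh_per_mb: float = 0.0
    csh_per_mb: float = 0.0


@dataclass
class AQIReport:
    """Genome-wide summary plus per-fragment rows."""

    assembly_size: int
    n_cre: float
    n_cse: float
    n_crh: float
    n_csh: float
    r_aqi: float
    s_aqi: float
    cre_per_mb: float
    cse_per_mb: float
    crh_per_mb: float
    csh_per_mb: float
    coverage_rate: Dict[str, float]
    mean_depth: Dict[str, float]
    n_low_confidence: int
    n_ambiguous: int
    fragments: List[FragmentStat] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AQIReport":
        data = dict(data)
        data["fragments"] = [FragmentStat(**f) for f in data.get("fragments", [])]
        return cls(**data)


def harmonic_weight(m: int) -> float:
    """Partial harmonic sum over 1..m; 0 for an empty window."""
    if m < 0:
        raise ValueError("window count must be non-negative")
    return float(sum(1.0 / i for i in range(1, int(m) + 1)))


def window_width(assembly_size: int, frac: float = DEFAULT_WINDOW_FRAC) -> int:
    if assembly_size <= 0:
        raise ValueError("assembly size must be positive")
    return max(1, round(frac * assembly_size))


def window_normalize(
    calls: Sequence[ErrorCall],
    call_type: str,
    assembly_size: int,
    contig_lengths: Mapping[str, int],
    frac: float = DEFAULT_WINDOW_FRAC,
    include_low_confidence: bool = False,
) -> List[WindowStat]:
    """Harmonic-normalized per-window counts of one call type.

    Contigs are tiled independently with non-overlapping windows of width
    0.0001 x total assembly size (last window truncated); a sliding window
    would count every error several times and ΣNw would no longer be a
    well-defined total. Only occupied windows are returned.
    """
    w = window_width(assembly_size, frac)
    counts: Dict[Tuple[str, int], int] = {}
    for call in calls:
        if call.type != call_type:
            continue
        if call.low_confidence and not include_low_confidence:
            continue
        counts[(call.contig, call.position // w)] = (
            counts.get((call.contig, call.position // w), 0) + 1
        )
    stats = []
    for (contig, idx), m in sorted(counts.items()):
        length = contig_lengths[contig]
        stats.append(
            WindowStat(
                contig=contig,
                window_index=idx,
                start=idx * w,
                end=min((idx + 1) * w, length),
                m=m,
                nw=harmonic_weight(m),
            )
        )
    return stats


def compute_aqi(n: float, length_mb: float, kind: str) -> float:
    """Quality score from a cumulative normalized count and a length in Mb."""
    if n < 0:
        raise ValueError("normalized count must be non-negative")
    if length_mb <= 0:
        raise ValueError("length must be positive")
    if kind == "regional":
        rate = REGIONAL_RATE
    elif kind == "structural":
        rate = REGIONAL_RATE * STRUCTURAL_PENALTY
    else:
        raise ValueError(f"unknown AQI kind {kind!r}")
    return 100.0 * math.exp(-rate * n / length_mb)


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision on the percent scale."""
    if recall < 0 or precision < 0:
        raise ValueError("recall/precision must be non-negative")
    if recall == 0 and precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def summarize(
    calls: Sequence[ErrorCall],
    coverage: CoverageSummary,
    contig_lengths: Mapping[str, int],
    ambiguous: Sequence[PositionCall] = (),
    low_confidence: Sequence[LowConfidenceRegion] = (),
    frac: float = DEFAULT_WINDOW_FRAC,
) -> AQIReport:
    """Per-fragment and genome-wide quality report.

    Per-fragment scores use the fragment's own length (which may be well
    under 1 Mb); the genome-wide cumulative count is by construction the sum
    of the per-fragment counts. Heterozygosity densities use the same
    harmonic windowing as errors. Low-confidence calls are excluded from
    every N but reported in the counts.
    """
    assembly_size = sum(contig_lengths.values())
    windows = {
        t: window_normalize(calls, t, assembly_size, contig_lengths, frac)
        for t in CALL_TYPES
    }
    totals = {t: sum(ws.nw for ws in windows[t]) for t in CALL_TYPES}
    per_contig: Dict[str, Dict[str, float]] = {
        name: {t: 0.0 for t in CALL_TYPES} for name in contig_lengths
    }
    for t in CALL_TYPES:
        for ws in windows[t]:
            per_contig[ws.contig][t] += ws.nw

    fragments = []
    for name, length in contig_lengths.items():
        mb = length / 1e6
        n = per_contig[name]
        fragments.append(
            FragmentStat(
                name=name,
                length=length,
                n_cre=n[CRE],
                n_cse=n[CSE],
                n_crh=n[CRH],
                n_csh=n[CSH],
                r_aqi=compute_aqi(n[CRE], mb, "regional"),
                s_aqi=compute_aqi(n[CSE], mb, "structural"),
                cre_per_mb=n[CRE] / mb,
                cse_per_mb=n[CSE] / mb,
                crh_per_mb=n[CRH] / mb,
                csh_per_mb=n[CSH] / mb,
            )
        )

    total_mb = assembly_size / 1e6
    return AQIReport(
        assembly_size=assembly_size,
        n_cre=totals[CRE],
        n_cse=totals[CSE],
        n_crh=totals[CRH],
        n_csh=totals[CSH],
        r_aqi=compute_aqi(totals[CRE], total_mb, "regional"),
        s_aqi=compute_aqi(totals[CSE], total_mb, "structural"),
        cre_per_mb=totals[CRE] / total_mb,
        cse_per_mb=totals[CSE] / total_mb,
        crh_per_mb=totals[CRH] / total_mb,
        csh_per_mb=totals[CSH] / total_mb,
        coverage_rate=dict(coverage.coverage_rate),
        mean_depth=dict(coverage.mean_depth),
        n_low_confidence=len(low_confidence),
        n_ambiguous=len(ambiguous),
        fragments=fragments,
    )


# ---------------------------------------------------------------------------
# serialization

_TSV_COLUMNS = [
    "contig",
    "position",
    "type",
    "ngs_evidence",
    "sms_evidence",
    "clip_count",
    "depth",
    "ratio",
    "region_start",
    "region_end",
    "low_confidence",
]


def write_outputs(
    report: AQIReport,
    calls: Sequence[ErrorCall],
    ambiguous: Sequence[PositionCall],
    low_confidence: Sequence[LowConfidenceRegion],
    out_dir,
) -> Dict[str, str]:
    """Write the report, breakpoint files and low-confidence track.

    summary.txt / summary.json      human- and machine-readable report
    errors.bed / errors.tsv         CRE/CSE breakpoints (BED name=type,
                                    score=round(100*ratio))
    heterozygosity.bed / .tsv       CRH/CSH loci
    ambiguous.tsv                   positions between h_high and f
    low_confidence.bed              coverage-filtered regions

    BED/TSV coordinates are 0-based half-open; re-reading summary.json and
    the TSVs reproduces the in-memory objects exactly.
    """
    os.makedirs(str(out_dir), exist_ok=True)
    paths: Dict[str, str] = {}

    def _p(name: str) -> str:
        path = os.path.join(str(out_dir), name)
        paths[name] = path
        return path

    with open(_p("summary.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    with open(_p("summary.txt"), "w") as fh:
        fh.write(format_summary(report))

    err = [c for c in calls if c.type in ("CRE", "CSE")]
    het = [c for c in calls if c.type in ("CRH", "CSH")]
    for name, subset in (("errors", err), ("heterozygosity", het)):
        with open(_p(name + ".bed"), "w") as fh:
            for c in subset:
                start, end = c.region if c.region else (c.position, c.position + 1)
                fh.write(
                    f"{c.contig}\t{start}\t{end}\t{c.type}\t{round(100 * c.ratio)}\t.\n"
                )
        with open(_p(name + ".tsv"), "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for c in subset:
                rs, re_ = c.region if c.region else ("", "")
                fh.write(
                    f"{c.contig}\t{c.position}\t{c.type}\t{c.ngs_evidence}\t"
                    f"{c.sms_evidence}\t{c.clip_count}\t{c.depth}\t{c.ratio!r}\t"
                    f"{rs}\t{re_}\t{int(c.low_confidence)}\n"
                )

    with open(_p("ambiguous.tsv"), "w") as fh:
        fh.write("contig\tposition\ttech\tclip_count\tdepth\tratio\n")
        for c in ambiguous:
            fh.write(
                f"{c.contig}\t{c.position}\t{c.tech}\t{c.clip_count}\t"
                f"{c.depth}\t{c.ratio!r}\n"
            )

    with open(_p("low_confidence.bed"), "w") as fh:
        for r in low_confidence:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.reason}\t0\t.\n")

    return paths


def read_summary(path) -> AQIReport:
    with open(str(path)) as fh:
        return AQIReport.from_dict(json.load(fh))


def read_calls_tsv(path) -> List[ErrorCall]:
    calls: List[ErrorCall] = []
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            region = None
            if parts[idx["region_start"]] != "":
                region = (int(parts[idx["region_start"]]), int(parts[idx["region_end"]]))
            calls.append(
                ErrorCall(
                    contig=parts[idx["contig"]],
                    position=int(parts[idx["position"]]),
                    type=parts[idx["type"]],
                    ngs_evidence=parts[idx["ngs_evidence"]],
                    sms_evidence=parts[idx["sms_evidence"]],
                    clip_count=int(parts[idx["clip_count"]]),
                    depth=int(parts[idx["depth"]]),
                    ratio=float(parts[idx["ratio"]]),
                    region=region,
                    low_confidence=bool(int(parts[idx["low_confidence"]])),
                )
            )
    return calls


def format_summary(report: AQIReport) -> str:
    lines = [
        "assembly quality summary",
        "========================",
        f"assembly size (bp)      {report.assembly_size}",
        f"coverage rate NGS       {report.coverage_rate.get(NGS, float('nan')):.4f}",
        f"coverage rate SMS       {report.coverage_rate.get(SMS, float('nan')):.4f}",
        f"mean depth NGS          {report.mean_depth.get(NGS, float('nan')):.2f}",
        f"mean depth SMS          {report.mean_depth.get(SMS, float('nan')):.2f}",
        f"normalized CRE (sum Nw) {report.n_cre:.3f}",
        f"normalized CSE (sum Nw) {report.n_cse:.3f}",
        f"CRE per Mb              {report.cre_per_mb:.3g}",
        f"CSE per Mb              {report.cse_per_mb:.3g}",
        f"CRH per Mb              {report.crh_per_mb:.3g}",
        f"CSH per Mb              {report.csh_per_mb:.3g}",
        f"R-AQI                   {report.r_aqi:.1f}",
        f"S-AQI                   {report.s_aqi:.1f}",
        f"low-confidence regions  {report.n_low_confidence}",
        f"ambiguous positions     {report.n_ambiguous}",
        "",
        "fragment\tlength\tR-AQI\tS-AQI\tCRE/Mb\tCSE/Mb",
    ]
    for f in report.fragments:
        lines.append(
            f"{f.name}\t{f.length}\t{f.r_aqi:.1f}\t{f.s_aqi:.1f}"
            f"\t{f.cre_per_mb:.3g}\t{f.cse_per_mb:.3g}"
        )
    return "\n".join(lines) + "\n"
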