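"""Splitting misjoined contigs at structural-error breakpoints.

A structural (CSE) breakpoint marks a junction where two unlinked segments
were erroneously concatenated; cutting there before scaffolding prevents the
misjoin from propagating. The cut convention assigns the breakpoint base to
the downstream part: a contig of length L with one CSE at position p becomes
parts [0, p) and [p, L).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from .error_classifier import CSE, ErrorCall


@dataclass(frozen=True)
class SplitRecord:
    """Provenance of one corrected part within its source contig."""

    source_contig: str
    part_index: int  # 1-based
    source_start: int
    source_end: int
    new_name: str
    short: bool = False  # flagged when the part is under min_fragment


def split_contigs(
    assembly: Mapping[str, str],
    cse_calls: Sequence[ErrorCall],
    min_fragment: int = 1000,
    include_low_confidence: bool = False,
) -> Tuple[Dict[str, str], List[SplitRecord]]:
    """Cut every contig at its high-confidence CSE breakpoints.

    Fragments shorter than ``min_fragment`` are still emitted but flagged.
    Contigs without breakpoints pass through byte-identical under their
    original name; split parts are named ``<source>_<part_index>``.
    """
    cuts: Dict[str, List[int]] = {}
    for call in cse_calls:
        if call.type != CSE:
            continue
        if call.low_confidence and not include_low_confidence:
            continue
        if call.contig not in assembly:
            raise ValueError(f"CSE contig {call.contig!r} absent from assembly")
        length = len(assembly[call.contig])
        if not (0 < call.position < length):
            if call.position in (0, length):
                continue  # terminal breakpoint: nothing to split
            raise ValueError(
                f"CSE breakpoint {call.position} outside contig {call.contig}"
            )
        cuts.setdefault(call.contig, []).append(call.position)

    corrected: Dict[str, str] = {}
    records: List[SplitRecord] = []
    for name, seq in assembly.items():
        positions = sorted(set(cuts.get(name, [])))
        if not positions:
            corrected[name] = seq
            records.append(
                SplitRecord(
                    source_contig=name,
                    part_index=1,
                    source_start=0,
                    source_end=len(seq),
                    new_name=name,
                )
            )
            continue
        bounds = [0] + positions + [len(seq)]
        for k in range(len(bounds) - 1):
            start, end = bounds[k], bounds[k + 1]
            new_name = f"{name}_{k + 1}"
            corrected[new_name] = seq[start:end]
            records.append(
                SplitRecord(
                    source_contig=name,
                    part_index=k + 1,
                    source_start=start,
                    source_end=end,
                    new_name=new_name,
                    short=(end - start) < min_fragment,
                )
            )
    return corrected, records


def write_corrected(
    corrected: Mapping[str, str],
    records: Sequence[SplitRecord],
    out_dir,
    line_width: int = 60,
) -> Dict[str, str]:
    """Corrected FASTA, AGP v2.1 component map and a split table.

    AGP coordinates are 1-based inclusive per the standard; each corrected
    part is one AGP object built from a single W component of its source
    contig, so re-assembling components per AGP reproduces the sources.
    """
    os.makedirs(str(out_dir), exist_ok=True)
    fasta_path = os.path.join(str(out_dir), "corrected.fasta")
    agp_path = os.path.join(str(out_dir), "corrected.agp")
    tsv_path = os.path.join(str(out_dir), "splits.tsv")

    with open(fasta_path, "w") as fh:
        for name, seq in corrected.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")

    with open(agp_path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in records:
            length = r.source_end - r.source_start
            fh.write(
                f"{r.new_name}\t1\t{length}\t1\tW\t{r.source_contig}\t"
                f"{r.source_start + 1}\t{r.source_end}\t+\n"
            )

    with open(tsv_path, "w") as fh:
        fh.write("new_name\tsource_contig\tpart_index\tsource_start\tsource_end\tshort\n")
        for r in records:
            fh.write(
                f"{r.new_name}\t{r.source_contig}\t{r.part_index}\t"
                f"{r.source_start}\t{r.source_end}\t{int(r.short)}\n"
            )

    return {"fasta": fasta_path, "agp": agp_path, "tsv": tsv_path}
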