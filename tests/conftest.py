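"""Shared fixtures: a small end-to-end simulation and BAM construction helpers."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

from clipqc.pipeline import PipelineResult, run_calling
from clipqc.synthetic_data import SimResult, SimSpec, emulate_alignments, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: desk-scale end-to-end scenario shared across pipeline-level tests
SMALL_SPEC = SimSpec(
    genome_length=300_000,
    n_contigs=2,
    n_het_small=20,
    n_het_sv=4,
    n_regional_indel=12,
    n_repeat_ce=4,
    n_fragment_indel=2,
    n_misjoin=4,
    n_inversion=2,
)
SMALL_SEED = 11


@dataclass
class SimulationRun:
    spec: SimSpec
    sim: SimResult
    ngs_bam: str
    sms_bam: str
    result: PipelineResult


def run_simulation(spec: SimSpec, seed: int, directory) -> SimulationRun:
    sim = simulate(spec, seed)
    ngs, sms = emulate_alignments(
        sim.assembly,
        sim.truth,
        spec,
        seed + 1,
        str(directory / "ngs.bam"),
        str(directory / "sms.bam"),
    )
    result = run_calling(ngs, sms, contig_lengths=sim.contig_lengths)
    return SimulationRun(spec=spec, sim=sim, ngs_bam=ngs, sms_bam=sms, result=result)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> SimulationRun:
    return run_simulation(SMALL_SPEC, SMALL_SEED, tmp_path_factory.mktemp("small_sim"))


def write_bam(path, contig_lengths: Dict[str, int], records: List[dict]) -> str:
    """Write a small coordinate-sorted, indexed BAM from record dicts.

    Each record dict: name, contig, pos, cigar (tuples), optional mapq/flag/seq.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in contig_lengths.items()],
        }
    )
    contigs = list(contig_lengths)
    records = sorted(records, key=lambda r: (contigs.index(r["contig"]), r["pos"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec["name"]
            a.flag = rec.get("flag", 0)
            a.reference_id = contigs.index(rec["contig"])
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigartuples = rec["cigar"]
            read_len = sum(l for op, l in rec["cigar"] if op in (0, 1, 4, 7, 8))
            a.query_sequence = rec.get("seq", "A" * read_len)
            bam.write(a)
    pysam.index(str(path))
    return str(path)
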