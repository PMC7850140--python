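"""Shared fixtures: in-memory read factory, BAM construction, and one
session-scoped end-to-end simulation shared by the regression tests."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
import pytest
from hypothesis import settings

from clipcall.alignment_io import AlignedRead, parse_cigar

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_read(
    name: str = "r1",
    chrom: str = "chr1",
    pos: int = 1000,
    cigar: str = "150M",
    seq: str | None = None,
    quals: list[int] | None = None,
    mapq: int = 60,
    tlen: int = 400,
    reverse: bool = False,
    mate_reverse: bool = True,
    mate_chrom: str | None = "chr1",
    mate_pos: int | None = 1250,
    paired: bool = True,
    read1: bool = True,
    proper_pair: bool = True,
    duplicate: bool = False,
    secondary: bool = False,
    supplementary: bool = False,
    unmapped: bool = False,
    mate_unmapped: bool = False,
    sa_tag=(),
) -> AlignedRead:
    parsed = parse_cigar(cigar)
    qlen = sum(n for op, n in parsed if op in "MIS=X")
    if seq is None:
        seq = ("ACGT" * (qlen // 4 + 1))[:qlen]
    if quals is None:
        quals = [35] * len(seq)
    return AlignedRead(
        name=name,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=parsed,
        seq=seq,
        quals=tuple(quals),
        paired=paired,
        read1=read1,
        proper_pair=proper_pair,
        reverse=reverse,
        mate_reverse=mate_reverse,
        secondary=secondary,
        supplementary=supplementary,
        duplicate=duplicate,
        unmapped=unmapped,
        mate_unmapped=mate_unmapped,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
        tlen=tlen,
        sa_tag=tuple(sa_tag),
    )


def build_bam(
    path: Path,
    records: list[dict],
    references: dict[str, int],
) -> Path:
    """Write record dicts (pysam AlignedSegment keyword subsets) to a
    coordinate-sorted, indexed BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in references.items()
        ],
    }
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.get("name", "r")
            a.query_sequence = rec.get("seq")
            a.flag = rec.get("flag", 0)
            a.reference_id = rec.get("tid", 0)
            a.reference_start = rec.get("pos", 0)
            a.mapping_quality = rec.get("mapq", 60)
            if rec.get("cigar"):
                a.cigarstring = rec["cigar"]
            if rec.get("quals") is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec["quals"])
                )
            elif rec.get("seq"):
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec["seq"])
                )
            a.next_reference_id = rec.get("mtid", -1)
            a.next_reference_start = rec.get("mpos", -1)
            a.template_length = rec.get("tlen", 0)
            for tag, value in rec.get("tags", {}).items():
                a.set_tag(tag, value)
            out.write(a)
    pysam.sort("-o", str(path), str(tmp))
    tmp.unlink()
    pysam.index(str(path))
    return path


@dataclass
class E2ERun:
    """One seeded simulate -> align -> call -> evaluate round."""

    calls: list
    truth: list
    manifest: object
    genome: object
    bam: Path
    reference: Path
    workdir: Path


def run_end_to_end(
    workdir: Path,
    seed: int,
    n_chroms: int = 2,
    chrom_len: int = 1_000_000,
    n_del: int = 40,
    n_ins: int = 40,
    n_inv: int = 10,
    coverage: float = 30.0,
    error_rate: float = 0.002,
    del_size_range=(100, 5000),
    ins_size_range=(60, 800),
    inv_len_range=(50, 10_000),
) -> E2ERun:
    from clipcall.caller import run_caller
    from clipcall.mapping import align_reads
    from clipcall.sv_simulator import (
        generate_events,
        random_reference,
        simulate_inversions,
        simulate_reads,
        spike_svs,
        truth_to_calls,
        write_genome,
    )

    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reference = random_reference(n_chroms, chrom_len, rng)
    events = generate_events(
        reference,
        rng,
        n_del=n_del,
        n_ins=n_ins,
        del_size_range=del_size_range,
        ins_size_range=ins_size_range,
    )
    genome = spike_svs(reference, events, seed=seed)
    if n_inv:
        simulate_inversions(genome, rng, n=n_inv, len_range=inv_len_range)
    paths = write_genome(genome, workdir)
    simulate_reads(
        genome,
        workdir / "r1.fq",
        workdir / "r2.fq",
        rng,
        coverage_per_hap=coverage / 2,
        error_rate=error_rate,
    )
    bam = align_reads(
        paths["reference"], workdir / "r1.fq", workdir / "r2.fq", workdir / "aln.bam"
    )
    calls, manifest = run_caller(
        bam, paths["reference"], out_vcf=workdir / "calls.vcf"
    )
    return E2ERun(
        calls=calls,
        truth=truth_to_calls(genome.truth),
        manifest=manifest,
        genome=genome,
        bam=bam,
        reference=paths["reference"],
        workdir=workdir,
    )


@pytest.fixture(scope="session")
def e2e(tmp_path_factory) -> E2ERun:
    """The seeded 2 Mb regression run (40 DEL, 40 INS, 10 INV, 30x)."""
    return run_end_to_end(tmp_path_factory.mktemp("e2e"), seed=1)
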