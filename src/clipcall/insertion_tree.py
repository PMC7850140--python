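"""Tree-based decision rules for insertion detection.

Each clip-supported candidate breakpoint is pushed through four nodes in
order, terminating at the first that resolves it:

1. CIGAR   — insertions visible directly in read alignments (I ops); small
             indel support explains the candidate away.
2. SPLICED — short insertions from read extension + spliced alignment.
3. ASSEMBLY — local de Bruijn assembly; fully (exact size) or partially
             (breakpoint only) assembled insertions.
4. COMPLEX — rescue from high-confidence clips whose mates are unmapped or
             on other chromosomes, excluded near DEL/INV/TRA calls.
"""

from __future__ import annotations

import bisect
import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from clipcall.alignment_io import AlignedRead, InsertSizeStats
from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.local_assembly import (
    assemble_pooled,
    call_from_contigs,
    collect_assembly_reads,
)
from clipcall.signal_scan import BreakpointCandidate, ClippedRead
from clipcall.spliced_caller import spliced_align
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)

NODE_ORDER = ("CIGAR", "SPLICED", "ASSEMBLY", "COMPLEX")


@dataclass(frozen=True)
class ExplainedAsIndel:
    """Terminal outcome of node 1: the candidate is a small (<50 bp) indel."""

    chrom: str
    pos: int
    size: int
    support: int
    svtype: str  # DEL | INS


@dataclass
class TreeContext:
    """Everything the decision nodes need for one chunk."""

    bam_path: str | Path
    reference: str | Path
    stats: InsertSizeStats
    x_support: int
    clips: list[ClippedRead]
    spliced_ins_calls: list[SVCall]
    del_calls: list[SVCall]
    inv_calls: list[SVCall]
    tra_calls: list[SVCall]
    bam_indel_evidence: list[tuple[int, str, int, str]] = field(
        default_factory=list
    )  # sorted (pos, svtype, size, read_name)
    config: CallerConfig = DEFAULT_CONFIG
    backend: str = "builtin"
    node_counters: Counter = field(default_factory=Counter)

    def exclusion_calls(self) -> list[SVCall]:
        return self.del_calls + self.inv_calls + self.tra_calls


def bam_indel_evidence(
    reads: Sequence[AlignedRead],
) -> list[tuple[int, str, int, str]]:
    """All I/D CIGAR ops of primary reads as (pos, svtype, size, read_name),
    sorted by position — the substrate of decision node 1."""
    out: list[tuple[int, str, int, str]] = []
    for r in reads:
        if not r.primary or r.duplicate:
            continue
        name = f"{r.name}/{'1' if r.read1 else '2'}"
        ref = r.pos
        for op, n in r.cigar:
            if op in ("M", "=", "X"):
                ref += n
            elif op in ("D", "N"):
                out.append((ref, "DEL", n, name))
                ref += n
            elif op == "I":
                out.append((ref, "INS", n, name))
    out.sort()
    return out


def _overlaps_exclusion(
    candidate: BreakpointCandidate,
    calls: Sequence[SVCall],
    radius: int,
) -> bool:
    for c in calls:
        if c.chrom == candidate.chrom and (
            c.pos - radius <= candidate.pos <= c.end + radius
        ):
            return True
        if (
            c.svtype == "TRA"
            and c.chrom2 == candidate.chrom
            and c.pos2 is not None
            and abs(c.pos2 - candidate.pos) <= radius
        ):
            return True
    return False


def _node_cigar(
    candidate: BreakpointCandidate, ctx: TreeContext
) -> Union[SVCall, ExplainedAsIndel, None]:
    tol = ctx.config.merge_pos_tol
    ev = ctx.bam_indel_evidence
    lo = bisect.bisect_left(ev, (candidate.pos - tol,))
    hi = bisect.bisect_right(ev, (candidate.pos + tol + 1,))
    large_ins: list[tuple[int, int, str]] = []
    small: list[tuple[str, int, str]] = []
    for pos, svtype, size, name in ev[lo:hi]:
        if svtype == "INS" and size >= ctx.config.min_sv:
            large_ins.append((pos, size, name))
        elif size < ctx.config.min_sv:
            small.append((svtype, size, name))
    if len({n for _p, _s, n in large_ins}) >= ctx.x_support:
        return SVCall(
            "INS",
            candidate.chrom,
            round(statistics.median(p for p, _s, _n in large_ins)),
            size=round(statistics.median(s for _p, s, _n in large_ins)),
            support=len({n for _p, _s, n in large_ins}),
            evidence="CIGAR",
        )
    small_reads = {n for _t, _s, n in small}
    if len(small_reads) >= ctx.x_support:
        sizes = [s for _t, s, _n in small]
        types = Counter(t for t, _s, _n in small)
        return ExplainedAsIndel(
            chrom=candidate.chrom,
            pos=candidate.pos,
            size=round(statistics.median(sizes)),
            support=len(small_reads),
            svtype=types.most_common(1)[0][0],
        )
    return None


def _node_spliced(
    candidate: BreakpointCandidate, ctx: TreeContext
) -> Optional[SVCall]:
    radius = ctx.config.exclusion_radius
    best: Optional[SVCall] = None
    for c in ctx.spliced_ins_calls:
        if c.chrom == candidate.chrom and abs(c.pos - candidate.pos) <= radius:
            if best is None or abs(c.pos - candidate.pos) < abs(
                best.pos - candidate.pos
            ):
                best = c
    if best is None:
        return None
    return SVCall(
        "INS",
        best.chrom,
        best.pos,
        size=best.size,
        support=best.support,
        evidence="SPLICED",
        inserted_seq=best.inserted_seq,
    )


def _node_assembly(
    candidate: BreakpointCandidate, ctx: TreeContext
) -> Optional[SVCall]:
    job = collect_assembly_reads(
        ctx.bam_path, candidate, ctx.config.assembly_window, ctx.config
    )
    if not job.reads:
        return None
    contigs = assemble_pooled(job.reads, ctx.config.kmers)
    if not contigs:
        return None
    queries = [
        (f"contig_{i}_k{c.kmer}", c.seq) for i, c in enumerate(contigs)
    ]
    anchors = [(candidate.chrom, candidate.pos)] * len(queries)
    alns = spliced_align(
        queries, ctx.reference, anchors, backend="builtin", config=ctx.config
    )
    alns = [a for a in alns if a.mapq >= 10]
    call = call_from_contigs(
        alns,
        candidate,
        ctx.config,
        contig_seqs=dict(queries),
    )
    if call is None:
        return None
    if call.imprecise and _overlaps_exclusion(
        candidate, ctx.exclusion_calls(), ctx.config.exclusion_radius
    ):
        # a partially assembled "insertion" at a known DEL/INV/TRA breakpoint
        # is that event's clip signal, not an insertion
        return None
    return call


def complex_alignment_node(
    candidate: BreakpointCandidate,
    clips: Sequence[ClippedRead],
    exclusion: Sequence[SVCall],
    x_support: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> Optional[SVCall]:
    """Rescue node: insertions whose reads cannot align across the junction.

    Counts clipped reads at the candidate whose alignment is high-confidence
    (mapq >= 50 and mapped-region high-quality ratio >= 0.8) while the mate
    is unmapped or on another chromosome.  Mates on other chromosomes with
    low mapping quality still qualify (they fail the translocation test, so
    no double counting).  The candidate must not lie within 200 bp of any
    DEL/INV/TRA call.
    """
    qualifying: set[str] = set()
    for c in clips:
        if c.read.chrom != candidate.chrom or abs(c.bp - candidate.pos) > 5:
            continue
        if c.read.mapq < config.complex_mapq:
            continue
        if c.mapped_hq_ratio < config.complex_hq_ratio:
            continue
        if not c.read.paired:
            continue
        if c.read.mate_unmapped or (
            c.read.mate_chrom is not None
            and c.read.mate_chrom != c.read.chrom
        ):
            qualifying.add(f"{c.read.name}/{'1' if c.read.read1 else '2'}")
    if len(qualifying) < x_support:
        return None
    if _overlaps_exclusion(candidate, exclusion, config.exclusion_radius):
        return None
    return SVCall(
        "INS",
        candidate.chrom,
        candidate.pos,
        size=None,
        support=len(qualifying),
        evidence="COMPLEX",
    )


def resolve_insertion(
    candidate: BreakpointCandidate, ctx: TreeContext
) -> Union[SVCall, ExplainedAsIndel, None]:
    """Run the decision nodes in order, terminating at the first success."""
    ctx.node_counters["CIGAR"] += 1
    outcome = _node_cigar(candidate, ctx)
    if outcome is not None:
        return outcome
    ctx.node_counters["SPLICED"] += 1
    call = _node_spliced(candidate, ctx)
    if call is not None:
        return call
    ctx.node_counters["ASSEMBLY"] += 1
    call = _node_assembly(candidate, ctx)
    if call is not None:
        return call
    ctx.node_counters["COMPLEX"] += 1
    return complex_alignment_node(
        candidate,
        ctx.clips,
        ctx.exclusion_calls(),
        ctx.x_support,
        ctx.config,
    )
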