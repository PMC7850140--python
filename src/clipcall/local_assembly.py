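"""Local de Bruijn assembly around a candidate breakpoint and insertion
calling from contig alignments.

Reads near the breakpoint (clipped reads and improper pairs plus their
mates, including unmapped mates) are assembled with three k-mer sizes; the
pooled contigs are spliced-aligned back to the reference window.  A contig
whose CIGAR carries a >=50 bp I op near the breakpoint resolves the
insertion fully (exact size and sequence); a contig clipped by >50 bp near
the breakpoint resolves it partially (breakpoint only, size unknown).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.signal_scan import BreakpointCandidate
from clipcall.spliced_caller import SplicedAlignment
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AssemblyJob:
    """Reads selected for local assembly of one candidate breakpoint."""

    breakpoint: BreakpointCandidate
    window_start: int
    window_end: int
    reads: list[tuple[str, str, tuple[int, ...]]]  # (name, seq, quals)


@dataclass(frozen=True)
class Contig:
    """An assembled contig with the k that produced it."""

    seq: str
    kmer: int
    mean_kmer_coverage: float

    def __post_init__(self) -> None:
        if len(self.seq) < self.kmer:
            raise ValueError("contig shorter than its k-mer size")


# ---------------------------------------------------------------------------
# read collection


def collect_assembly_reads(
    bam_path: str | Path,
    breakpoint: BreakpointCandidate,
    window: int = 1200,
    config: CallerConfig = DEFAULT_CONFIG,
) -> AssemblyJob:
    """Select clipped reads and improper pairs (mapq >= 20) in the window
    around the breakpoint, plus both mates of every selected pair.

    Unmapped mates are stored in the BAM at their mate's position, so the
    window fetch picks them up; mates mapped elsewhere are fetched at their
    recorded coordinates.
    """
    half = window // 2
    start = max(0, breakpoint.pos - half)
    end = breakpoint.pos + half
    selected: dict[tuple[str, bool], tuple[str, str, tuple[int, ...]]] = {}
    wanted_mates: list[tuple[str, bool, str, int]] = []

    def keep(rec: "pysam.AlignedSegment") -> None:
        if rec.query_sequence is None:
            return
        key = (rec.query_name or "", rec.is_read1)
        if key in selected:
            return
        quals = tuple(rec.query_qualities or [20] * len(rec.query_sequence))
        selected[key] = (rec.query_name or "", rec.query_sequence, quals)

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if breakpoint.chrom not in bam.references:
            return AssemblyJob(breakpoint, start, end, [])
        for rec in bam.fetch(breakpoint.chrom, start, end):
            if rec.is_duplicate or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                keep(rec)  # unmapped mate placed here by the aligner
                continue
            clipped = any(
                op in (4, 5) and n > config.min_clip
                for op, n in (rec.cigartuples or ())
            )
            improper = rec.is_paired and not rec.is_proper_pair
            if not (clipped or improper):
                continue
            if rec.mapping_quality < config.min_mapq:
                continue
            keep(rec)
            if rec.is_paired and not rec.mate_is_unmapped:
                mkey = (rec.query_name or "", not rec.is_read1)
                if mkey not in selected and rec.next_reference_name:
                    wanted_mates.append(
                        (
                            rec.query_name or "",
                            not rec.is_read1,
                            rec.next_reference_name,
                            rec.next_reference_start,
                        )
                    )
        for name, is_read1, chrom, pos in wanted_mates:
            if (name, is_read1) in selected or chrom not in bam.references:
                continue
            for rec in bam.fetch(chrom, max(0, pos), pos + 1):
                if (
                    rec.query_name == name
                    and rec.is_read1 == is_read1
                    and not rec.is_secondary
                    and not rec.is_supplementary
                ):
                    keep(rec)
                    break
    return AssemblyJob(breakpoint, start, end, list(selected.values()))


# ---------------------------------------------------------------------------
# de Bruijn assembly


def _unitigs(
    kmers: dict[str, int], k: int
) -> list[tuple[str, float, str, str]]:
    """Maximal non-branching paths of the k-mer graph.

    Returns ``(sequence, mean_kmer_coverage, first_node, last_node)`` where
    the nodes are the flanking (k-1)-mers (used for tip/bubble detection).
    """
    out_edges: dict[str, list[str]] = defaultdict(list)
    in_edges: dict[str, list[str]] = defaultdict(list)
    for km in kmers:
        out_edges[km[:-1]].append(km)
        in_edges[km[1:]].append(km)

    def is_junction(node: str) -> bool:
        return len(out_edges.get(node, ())) != 1 or len(in_edges.get(node, ())) != 1

    unitigs: list[tuple[str, float, str, str]] = []
    visited: set[str] = set()
    starts = [
        km
        for km in kmers
        if is_junction(km[:-1]) or len(in_edges.get(km[:-1], ())) == 0
    ]
    # fallback for pure cycles: any unvisited k-mer can start
    for seed in starts + list(kmers):
        if seed in visited:
            continue
        path = [seed]
        visited.add(seed)
        node = seed[1:]
        while not is_junction(node):
            nxt = out_edges[node][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            node = nxt[1:]
        seq = path[0] + "".join(km[-1] for km in path[1:])
        cov = sum(kmers[km] for km in path) / len(path)
        unitigs.append((seq, cov, path[0][:-1], path[-1][1:]))
    return unitigs


def _kmer_set(seqs: Iterable[str], k: int, min_count: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for s in seqs:
        s = s.upper()
        for strand in (s, revcomp(s)):
            for i in range(len(strand) - k + 1):
                km = strand[i : i + k]
                if "N" not in km:
                    counts[km] += 1
    return {km: c for km, c in counts.items() if c >= min_count}


def _drop_unitig(kmers: dict[str, int], seq: str, k: int) -> None:
    for i in range(len(seq) - k + 1):
        kmers.pop(seq[i : i + k], None)


def debruijn_assemble(
    reads: Sequence[tuple[str, str, tuple[int, ...]]] | Sequence[str],
    k: int,
    min_count: int = 2,
) -> list[Contig]:
    """Assemble reads (and their reverse complements) at one k-mer size.

    Velvet-like cleaning: k-mers seen fewer than ``min_count`` times are
    pruned, dead-end unitigs shorter than 2k are clipped, and simple
    bubbles are popped keeping the higher-coverage arm.  Output contigs
    are maximal non-branching paths of length >= k.
    """
    seqs = [r if isinstance(r, str) else r[1] for r in reads]
    kmers = _kmer_set(seqs, k, min_count)
    if not kmers:
        return []

    for _ in range(4):  # tip clipping until stable (bounded)
        unitigs = _unitigs(kmers, k)
        out_deg: Counter[str] = Counter()
        in_deg: Counter[str] = Counter()
        for km in kmers:
            out_deg[km[:-1]] += 1
            in_deg[km[1:]] += 1
        tips = [
            (seq, cov)
            for seq, cov, first, last in unitigs
            if len(seq) < 2 * k
            and (in_deg.get(first, 0) == 0 or out_deg.get(last, 0) == 0)
            and not (in_deg.get(first, 0) == 0 and out_deg.get(last, 0) == 0)
        ]
        if not tips:
            break
        for seq, _cov in tips:
            _drop_unitig(kmers, seq, k)
        if not kmers:
            return []

    # simple bubble popping: parallel unitigs sharing both junction nodes
    unitigs = _unitigs(kmers, k)
    groups: dict[tuple[str, str], list[tuple[str, float]]] = defaultdict(list)
    for seq, cov, first, last in unitigs:
        groups[(first, last)].append((seq, cov))
    popped = False
    for (first, last), arms in groups.items():
        if first == last or len(arms) < 2:
            continue
        arms.sort(key=lambda a: (-a[1], a[0]))
        for seq, _cov in arms[1:]:
            _drop_unitig(kmers, seq, k)
            popped = True
    if popped:
        unitigs = _unitigs(kmers, k)

    return [
        Contig(seq, k, cov)
        for seq, cov, _f, _l in unitigs
        if len(seq) >= k
    ]


def assemble_pooled(
    reads: Sequence[tuple[str, str, tuple[int, ...]]] | Sequence[str],
    kmers: Sequence[int] = (41, 61, 81),
) -> list[Contig]:
    """Run the assembler for each k and pool the contigs (no deduplication;
    downstream clustering absorbs redundancy)."""
    contigs: list[Contig] = []
    min_len = min((len(r if isinstance(r, str) else r[1]) for r in reads), default=0)
    for k in kmers:
        if k >= min_len and min_len > 0:
            continue
        contigs.extend(debruijn_assemble(reads, k))
    return contigs


# ---------------------------------------------------------------------------
# insertion calling from contig alignments


def call_from_contigs(
    contig_alignments: Sequence[SplicedAlignment],
    breakpoint: BreakpointCandidate,
    config: CallerConfig = DEFAULT_CONFIG,
    support: Optional[int] = None,
    contig_seqs: Optional[dict[str, str]] = None,
) -> Optional[SVCall]:
    """Insertion decision from aligned contigs near one breakpoint.

    FULL: an I op >= 50 bp within 200 bp of the breakpoint -> exact size.
    PARTIAL: a contig clipped by > 50 bp with the clip boundary within
    200 bp of the breakpoint -> size unknown, imprecise.  FULL wins when
    both exist; among several FULL hits the one closest to the breakpoint
    wins.
    """
    radius = config.exclusion_radius
    # (dist, pos, size, qname, qpos) per candidate I op
    full_hits: list[tuple[int, int, int, str, int]] = []
    partial_hits: list[tuple[int, int]] = []  # (dist, pos)
    for aln in contig_alignments:
        if aln.chrom != breakpoint.chrom:
            continue
        ref = aln.pos
        qpos = 0
        for op, n in aln.cigar:
            if op == "I":
                dist = abs(ref - breakpoint.pos)
                if n >= config.min_sv and dist <= radius:
                    full_hits.append((dist, ref, n, aln.query_name, qpos))
                qpos += n
            elif op in ("M", "=", "X"):
                ref += n
                qpos += n
            elif op in ("D", "N"):
                ref += n
            elif op in ("S", "H"):
                boundary = aln.pos if qpos == 0 else ref
                dist = abs(boundary - breakpoint.pos)
                if n > config.min_sv and dist <= radius:
                    partial_hits.append((dist, boundary))
                if op == "S":
                    qpos += n
    n_support = support if support is not None else breakpoint.support
    if full_hits:
        full_hits.sort()
        _dist, pos, size, qname, qpos = full_hits[0]
        seq = None
        if contig_seqs and qname in contig_seqs:
            seq = contig_seqs[qname][qpos : qpos + size]
        return SVCall(
            "INS",
            breakpoint.chrom,
            pos,
            size=size,
            support=n_support,
            evidence="ASSEMBLY_FULL",
            inserted_seq=seq,
        )
    if partial_hits:
        partial_hits.sort()
        return SVCall(
            "INS",
            breakpoint.chrom,
            partial_hits[0][1],
            size=None,
            support=n_support,
            evidence="ASSEMBLY_PARTIAL",
        )
    return None
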