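"""Classify imperfect alignments into SV signal categories and collect
candidate breakpoints from clipped reads.

A read that is not perfectly aligned can carry several signals at once:
terminal soft/hard clips, a supplementary alignment (split read), an
oversized insert (discordant pair), a mate on another chromosome
(translocation pair), a mate with identical orientation (inversion pair),
or an unmapped mate.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from clipcall.alignment_io import (
    AlignedRead,
    InsertSizeStats,
    high_quality_base_ratio,
)
from clipcall.config import CallerConfig, DEFAULT_CONFIG


class SignalCategory(enum.Flag):
    """SV signal classes a single read can carry (combinable)."""

    CLIPPED = enum.auto()
    SPLIT = enum.auto()
    DISCORDANT = enum.auto()
    TRANSLOCATION_PAIR = enum.auto()
    INVERSION_PAIR = enum.auto()
    MATE_UNMAPPED = enum.auto()


@dataclass(frozen=True)
class ClippedRead:
    """A clipped alignment annotated with clip side and breakpoint.

    ``side`` is ``"MS"`` when the 3' end of the aligned query is clipped
    (read begins matched) and ``"SM"`` when the 5' end is clipped.  ``bp``
    is the 0-based reference coordinate of the clip boundary: one past the
    last aligned base for MS, the first aligned base for SM.
    """

    read: AlignedRead
    side: str  # "MS" | "SM"
    bp: int
    clip_len: int
    clipped_seq: str  # empty for hard clips
    mapped_hq_ratio: float
    clipped_hq_ratio: float

    def __post_init__(self) -> None:
        if self.side not in ("MS", "SM"):
            raise ValueError(f"invalid clip side {self.side!r}")
        if self.clip_len < 1:
            raise ValueError("clip_len must be >= 1")


@dataclass(frozen=True)
class BreakpointCandidate:
    """A clip-supported candidate SV position (representative of a 5 bp cluster)."""

    chrom: str
    pos: int
    support: int
    ms_support: int = 0
    sm_support: int = 0


def classify_read(
    read: AlignedRead,
    stats: InsertSizeStats,
    config: CallerConfig = DEFAULT_CONFIG,
) -> SignalCategory:
    """Assign SV signal categories to one primary, non-duplicate read.

    Discordance uses the capped insert-size test
    ``|TLEN| > min(mean + sd, mean + 300)`` and applies only to same-
    chromosome pairs; cross-chromosome pairs are translocation signal,
    same-orientation same-chromosome pairs inversion signal.
    """
    cats = SignalCategory(0)
    if read.unmapped:
        return cats
    if any(
        n > config.min_clip and op in ("S", "H") for op, n in read.cigar
    ):
        cats |= SignalCategory.CLIPPED
    if read.sa_tag:
        cats |= SignalCategory.SPLIT
    if read.paired:
        if read.mate_unmapped:
            cats |= SignalCategory.MATE_UNMAPPED
        elif read.mate_chrom is not None and read.mate_chrom != read.chrom:
            cats |= SignalCategory.TRANSLOCATION_PAIR
        else:
            threshold = min(
                stats.mean + stats.sd, stats.mean + config.discordant_pad
            )
            if read.tlen != 0 and abs(read.tlen) > threshold:
                cats |= SignalCategory.DISCORDANT
            if read.reverse == read.mate_reverse:
                cats |= SignalCategory.INVERSION_PAIR
    return cats


def extract_clips(
    read: AlignedRead, config: CallerConfig = DEFAULT_CONFIG
) -> list[ClippedRead]:
    """Extract 0-2 clipped ends (clip strictly longer than ``min_clip``).

    The breakpoint of an MS clip is the read start plus the reference span
    of the CIGAR; of an SM clip, the read start itself.  Quality ratios are
    computed over the mapped and clipped query intervals; hard clips have
    no sequence and get a clipped ratio of 0.
    """
    if read.unmapped or not read.cigar:
        return []
    out: list[ClippedRead] = []
    first_op, first_n = read.cigar[0]
    last_op, last_n = read.cigar[-1]
    quals = read.quals
    seq = read.seq or ""

    lead_clip = first_n if first_op in ("S", "H") else 0
    lead_soft = first_n if first_op == "S" else 0
    tail_clip = last_n if last_op in ("S", "H") else 0
    tail_soft = last_n if last_op == "S" else 0
    qlen = len(seq)

    def hq(a: int, b: int) -> float:
        if quals is None or a >= b:
            return 0.0
        return high_quality_base_ratio(quals, a, b)

    if lead_clip > config.min_clip:
        out.append(
            ClippedRead(
                read=read,
                side="SM",
                bp=read.pos,
                clip_len=lead_clip,
                clipped_seq=seq[:lead_soft],
                mapped_hq_ratio=hq(lead_soft, qlen - tail_soft),
                clipped_hq_ratio=hq(0, lead_soft),
            )
        )
    if tail_clip > config.min_clip:
        out.append(
            ClippedRead(
                read=read,
                side="MS",
                bp=read.pos + read.reference_span,
                clip_len=tail_clip,
                clipped_seq=seq[qlen - tail_soft :] if tail_soft else "",
                mapped_hq_ratio=hq(lead_soft, qlen - tail_soft),
                clipped_hq_ratio=hq(qlen - tail_soft, qlen),
            )
        )
    return out


def support_threshold(coverage: float, support_frac: float = 0.10) -> int:
    """Minimum read support X = max(2, ceil(support_frac * coverage)).

    The floor of 2 keeps a single read from nominating a candidate at low
    coverage.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    return max(2, math.ceil(support_frac * coverage))


def quality_filter_clips(
    clips: Iterable[ClippedRead], config: CallerConfig = DEFAULT_CONFIG
) -> list[ClippedRead]:
    """Drop clips from low-quality alignments (mapq < 20 or supplementary)."""
    return [
        c
        for c in clips
        if c.read.mapq >= config.min_mapq and not c.read.supplementary
    ]


def candidates_to_bed(
    candidates: Sequence[BreakpointCandidate], path
) -> None:
    """Debug export: one BED line per candidate (chrom, pos, pos+1, support)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.support}\n")


def collect_candidate_breakpoints(
    clips: Sequence[ClippedRead],
    x_support: int,
    window: int = 5,
) -> list[BreakpointCandidate]:
    """Cluster clip breakpoints into candidates (greedy left-to-right sweep).

    A cluster's diameter is at most ``window`` bp; its representative is
    the modal position (ties to the leftmost).  Clusters with fewer than
    ``x_support`` members are dropped.  Input clips should already be
    quality-filtered.
    """
    if not clips:
        return []
    chrom = clips[0].read.chrom
    items = sorted(clips, key=lambda c: c.bp)
    out: list[BreakpointCandidate] = []
    i = 0
    n = len(items)
    while i < n:
        j = i
        while j < n and items[j].bp - items[i].bp <= window:
            j += 1
        cluster = items[i:j]
        if len(cluster) >= x_support:
            counts = Counter(c.bp for c in cluster)
            best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
            out.append(
                BreakpointCandidate(
                    chrom=chrom or "",
                    pos=best[0],
                    support=len(cluster),
                    ms_support=sum(1 for c in cluster if c.side == "MS"),
                    sm_support=sum(1 for c in cluster if c.side == "SM"),
                )
            )
        i = j
    return out
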