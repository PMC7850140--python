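"""Inversion and translocation calling from split reads and discordant pairs.

A split read whose primary and supplementary alignments lie on the same
chromosome with opposite orientations spans an inversion; a same-chromosome
pair aligned in the same orientation supports a large inversion.  Evidence
joining two chromosomes supports a translocation (split reads give exact
breakpoints, pairs approximate ones).  Pair-derived positions are snapped
to nearby clipped-read breakpoints when any exist.
"""

from __future__ import annotations

import logging
import statistics
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from clipcall.alignment_io import AlignedRead, InsertSizeStats, QUERY_OPS, REF_OPS
from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.signal_scan import ClippedRead
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrientedBreak:
    """One breakpoint with its partner, from split-read or pair evidence."""

    chrom: str
    pos: int
    source: str  # SPLIT | PAIR
    partner_chrom: str
    partner_pos: int
    read_name: str
    refined: bool = False


@dataclass(frozen=True)
class _Segment:
    chrom: str
    rstart: int
    rend: int
    strand: str
    qstart: int  # in as-sequenced read orientation
    qend: int
    mapq: int


def split_segments(read: AlignedRead) -> list[_Segment]:
    """Primary + SA-tag alignment segments in as-sequenced query order."""

    def seg(chrom, pos, strand, cigar, mapq) -> _Segment:
        lead = cigar[0][1] if cigar and cigar[0][0] in ("S", "H") else 0
        alen = sum(n for op, n in cigar if op in ("M", "I", "=", "X"))
        total = sum(n for op, n in cigar if op in QUERY_OPS or op == "H")
        rspan = sum(n for op, n in cigar if op in REF_OPS)
        if strand == "+":
            qs = lead
        else:
            qs = total - (lead + alen)
        return _Segment(chrom, pos, pos + rspan, strand, qs, qs + alen, mapq)

    if not read.cigar or read.chrom is None:
        return []
    primary_strand = "-" if read.reverse else "+"
    segs = [
        seg(read.chrom, read.pos, primary_strand, list(read.cigar), read.mapq)
    ]
    for sa in read.sa_tag:
        segs.append(seg(sa.chrom, sa.pos, sa.strand, list(sa.cigar), sa.mapq))
    segs.sort(key=lambda s: s.qstart)
    return segs


def _junction_breaks(a: _Segment, b: _Segment) -> tuple[int, int]:
    """Breakpoints at the junction between two query-adjacent segments."""
    ba = a.rend if a.strand == "+" else a.rstart
    bb = b.rstart if b.strand == "+" else b.rend
    return ba, bb


class _ClipIndex:
    """Sorted clip breakpoints per chromosome for snapping."""

    def __init__(self, clips: Iterable[ClippedRead]):
        self._by_chrom: dict[str, list[int]] = defaultdict(list)
        for c in clips:
            if c.read.chrom is not None:
                self._by_chrom[c.read.chrom].append(c.bp)
        for v in self._by_chrom.values():
            v.sort()

    def snap(self, chrom: str, pos: int, radius: int = 200) -> tuple[int, bool]:
        bps = self._by_chrom.get(chrom)
        if not bps:
            return pos, False
        i = bisect_left(bps, pos)
        best: Optional[int] = None
        for j in (i - 1, i):
            if 0 <= j < len(bps) and abs(bps[j] - pos) <= radius:
                if best is None or abs(bps[j] - pos) < abs(best - pos):
                    best = bps[j]
        return (best, True) if best is not None else (pos, False)


def _cluster_spans(
    spans: list[tuple[int, int, str]],  # (start, end, read_name)
    pos_tol: int,
    size_frac: float,
) -> list[tuple[int, int, int]]:
    """Greedy clustering of (start,end) spans -> (start, end, n_reads)."""
    spans.sort()
    clusters: list[list[tuple[int, int, str]]] = []
    for s in spans:
        placed = False
        for cl in reversed(clusters):
            m_start = statistics.median(x[0] for x in cl)
            if s[0] - m_start > pos_tol:
                break
            m_end = statistics.median(x[1] for x in cl)
            size_a, size_b = s[1] - s[0], m_end - m_start
            if abs(s[0] - m_start) <= pos_tol and (
                abs(size_a - size_b) <= size_frac * max(size_a, size_b, 1)
            ):
                cl.append(s)
                placed = True
                break
        if not placed:
            clusters.append([s])
    out = []
    for cl in clusters:
        start = round(statistics.median(x[0] for x in cl))
        end = round(statistics.median(x[1] for x in cl))
        out.append((start, end, len({x[2] for x in cl})))
    return out


def call_inversions(
    splits: Sequence[AlignedRead],
    pairs: Sequence[AlignedRead],
    clips: Sequence[ClippedRead],
    stats: InsertSizeStats,
    x_support: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[SVCall]:
    """Call inversions from orientation-flipped splits and FF/RR pairs.

    Split evidence gives both breakpoints exactly; pair evidence infers
    them from the observed versus expected insert size and is then snapped
    to clipped-read breakpoints within 200 bp.  Split and pair support mix
    toward the X threshold.
    """
    clip_index = _ClipIndex(clips)
    split_spans: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    pair_spans: dict[str, list[tuple[int, int, str]]] = defaultdict(list)

    for read in splits:
        if read.mapq < config.min_mapq:
            continue
        segs = split_segments(read)
        for a, b in zip(segs, segs[1:]):
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            if min(a.mapq, b.mapq) < config.min_mapq:
                continue
            ba, bb = _junction_breaks(a, b)
            lo, hi = min(ba, bb), max(ba, bb)
            if hi - lo < 1:
                continue
            split_spans[a.chrom].append((lo, hi, read.name))

    seen_pairs: set[str] = set()
    for read in pairs:
        if read.mapq < config.min_mapq or read.name in seen_pairs:
            continue
        if (
            not read.paired
            or read.mate_unmapped
            or read.mate_chrom != read.chrom
            or read.reverse != read.mate_reverse
            or read.mate_pos is None
        ):
            continue
        seen_pairs.add(read.name)
        left = min(read.pos, read.mate_pos)
        right_end = max(read.reference_end, read.mate_pos + stats.read_length)
        span = right_end - left
        inset = max((stats.mean - span) / 2.0, 0.0)
        b1 = round(left + inset)
        b2 = round(right_end - inset)
        b1, _ = clip_index.snap(read.chrom or "", b1)
        b2, _ = clip_index.snap(read.chrom or "", b2)
        if b2 - b1 >= config.min_sv:
            pair_spans[read.chrom or ""].append((b1, b2, read.name))

    # split reads give exact junctions: cluster them tightly, then let the
    # fuzzier pair evidence (breakpoints inferred from insert sizes) add
    # support to an overlapping split cluster rather than nominate rivals
    calls: list[SVCall] = []
    pair_slack = round(stats.mean + 3 * stats.sd)
    for chrom in sorted(set(split_spans) | set(pair_spans)):
        exact = _cluster_spans(
            split_spans.get(chrom, []), pos_tol=20, size_frac=config.merge_size_frac
        )
        leftovers: list[tuple[int, int, str]] = []
        extra: list[set[str]] = [set() for _ in exact]
        for b1, b2, name in pair_spans.get(chrom, []):
            matched = False
            for i, (start, end, _n) in enumerate(exact):
                if abs(b1 - start) <= pair_slack and abs(b2 - end) <= pair_slack:
                    extra[i].add(name)
                    matched = True
                    break
            if not matched:
                leftovers.append((b1, b2, name))
        for (start, end, n_split), names in zip(exact, extra):
            support = n_split + len(names)
            if support < x_support or end - start < config.min_sv:
                continue
            calls.append(
                SVCall(
                    "INV", chrom, start, size=end - start,
                    support=support, evidence="SPLIT",
                )
            )
        for start, end, support in _cluster_spans(
            leftovers, pos_tol=pair_slack, size_frac=0.5
        ):
            if support < x_support or end - start < config.min_sv:
                continue
            start_s, _ = clip_index.snap(chrom, start)
            end_s, _ = clip_index.snap(chrom, end)
            if end_s - start_s >= config.min_sv:
                start, end = start_s, end_s
            calls.append(
                SVCall(
                    "INV", chrom, start, size=end - start,
                    support=support, evidence="PAIR",
                )
            )
    calls.sort(key=lambda c: c.sort_key())
    return calls


def call_translocations(
    splits: Sequence[AlignedRead],
    tra_pairs: Sequence[AlignedRead],
    clips: Sequence[ClippedRead],
    x_support: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[SVCall]:
    """Call translocations: cross-chromosome splits (mapq > 20 on both
    sides) plus cross-chromosome pairs; combined support must reach 2X."""
    clip_index = _ClipIndex(clips)
    # evidence keyed by ordered chromosome pair plus junction orientation:
    # a reciprocal exchange creates TWO junctions at the same coordinate
    # pair, distinguished only by which side of each breakpoint is joined
    # ('L': sequence continues left of the break, 'R': right)
    Key = tuple[str, str, str, str]
    split_ev: dict[Key, list[tuple[int, int, str]]] = defaultdict(list)
    pair_ev: dict[Key, list[tuple[int, int, str]]] = defaultdict(list)

    for read in splits:
        segs = split_segments(read)
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom:
                continue
            if a.mapq <= config.tra_mapq or b.mapq <= config.tra_mapq:
                continue
            ba, bb = _junction_breaks(a, b)
            side_a = "L" if a.strand == "+" else "R"
            side_b = "R" if b.strand == "+" else "L"
            (c1, p1, o1), (c2, p2, o2) = sorted(
                [(a.chrom, ba, side_a), (b.chrom, bb, side_b)],
                key=lambda t: (t[0], t[1]),
            )
            split_ev[(c1, c2, o1, o2)].append((p1, p2, read.name))

    seen: set[str] = set()
    for read in tra_pairs:
        if read.mapq < config.min_mapq or read.name in seen:
            continue
        if (
            read.mate_chrom is None
            or read.mate_chrom == read.chrom
            or read.mate_pos is None
            or read.mate_unmapped
        ):
            continue
        seen.add(read.name)
        own = read.reference_end if not read.reverse else read.pos
        side_own = "R" if read.reverse else "L"
        side_mate = "R" if read.mate_reverse else "L"
        mate = read.mate_pos
        p_own, _ = clip_index.snap(read.chrom or "", own)
        p_mate, _ = clip_index.snap(read.mate_chrom, mate)
        (c1, p1, o1), (c2, p2, o2) = sorted(
            [(read.chrom or "", p_own, side_own), (read.mate_chrom, p_mate, side_mate)],
            key=lambda t: (t[0], t[1]),
        )
        pair_ev[(c1, c2, o1, o2)].append((p1, p2, read.name))

    # as for inversions: exact split junctions first, pair evidence (mate
    # positions scatter by up to the insert size) adds support or, alone,
    # nominates coarse sites
    calls: list[SVCall] = []
    slack = 800
    for key in sorted(set(split_ev) | set(pair_ev)):
        c1, c2, _o1, _o2 = key
        exact = _cluster_pairs(split_ev.get(key, []), tol=20)
        extra: list[set[str]] = [set() for _ in exact]
        leftovers: list[tuple[int, int, str]] = []
        for p1, p2, name in pair_ev.get(key, []):
            matched = False
            for i, (q1, q2, _n) in enumerate(exact):
                if abs(p1 - q1) <= slack and abs(p2 - q2) <= slack:
                    extra[i].add(name)
                    matched = True
                    break
            if not matched:
                leftovers.append((p1, p2, name))
        for (p1, p2, n_split), names in zip(exact, extra):
            if n_split + len(names) < 2 * x_support:
                continue
            calls.append(
                SVCall(
                    "TRA", c1, p1, support=n_split + len(names),
                    evidence="SPLIT", chrom2=c2, pos2=p2,
                )
            )
        for p1, p2, support in _cluster_pairs(leftovers, tol=slack):
            if support < 2 * x_support:
                continue
            calls.append(
                SVCall(
                    "TRA", c1, p1, support=support,
                    evidence="PAIR", chrom2=c2, pos2=p2,
                )
            )
    calls.sort(key=lambda c: c.sort_key())
    return calls


def _cluster_pairs(
    items: list[tuple[int, int, str]], tol: int
) -> list[tuple[int, int, int]]:
    """Greedy clustering of breakend pairs -> (pos1, pos2, n_reads)."""
    items = sorted(items)
    clusters: list[list[tuple[int, int, str]]] = []
    for it in items:
        placed = False
        for cl in reversed(clusters):
            m1 = statistics.median(x[0] for x in cl)
            if it[0] - m1 > tol:
                break
            m2 = statistics.median(x[1] for x in cl)
            if abs(it[0] - m1) <= tol and abs(it[1] - m2) <= tol:
                cl.append(it)
                placed = True
                break
        if not placed:
            clusters.append([it])
    return [
        (
            round(statistics.median(x[0] for x in cl)),
            round(statistics.median(x[1] for x in cl)),
            len({x[2] for x in cl}),
        )
        for cl in clusters
    ]
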