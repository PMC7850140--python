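"""Benchmarking: window-based truth matching, sensitivity/precision/F1,
truth extraction from long-read alignments, and signal-capture analysis.

A call matches a truth event when its breakpoint lies within a 200 bp
window of the truth breakpoint and (when both sizes are known) the sizes
differ by less than 50% of the truth size.  Matching is one-to-one and
greedy, nearest pair first.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts with derived sensitivity, precision and F1."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float


def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean 2sp/(s+p); 0 when both rates are 0."""
    if sensitivity + precision == 0:
        return 0.0
    return 2 * sensitivity * precision / (sensitivity + precision)


def metrics(tp: int, fp: int, fn: int) -> EvalResult:
    """Sensitivity tp/(tp+fn), precision tp/(tp+fp), F1 = 2sp/(s+p).

    Precision with no calls is reported as 0; F1 is 0 when s+p = 0.
    An empty truth set (tp+fn = 0) leaves sensitivity undefined -> error.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no truth events (tp+fn=0)")
    sens = tp / (tp + fn)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    return EvalResult(tp, fp, fn, sens, prec, f1_score(sens, prec))


def _match_distance(
    call: SVCall, truth: SVCall, svtype: str, window: int
) -> Optional[int]:
    """Distance if the pair satisfies the matching rule, else None."""
    if svtype == "TRA":
        best: Optional[int] = None
        for cc, cp in ((call.chrom, call.pos), (call.chrom2, call.pos2)):
            for tc, tp_ in ((truth.chrom, truth.pos), (truth.chrom2, truth.pos2)):
                if cc is None or tc is None or cp is None or tp_ is None:
                    continue
                if cc == tc and abs(cp - tp_) <= window:
                    d = abs(cp - tp_)
                    best = d if best is None else min(best, d)
        return best
    if call.chrom != truth.chrom:
        return None
    dist = abs(call.pos - truth.pos)
    if dist > window:
        return None
    if truth.size is not None and call.size is not None:
        if abs(call.size - truth.size) >= 0.5 * truth.size:
            return None
    return dist


def match_calls(
    calls: Sequence[SVCall],
    truth: Sequence[SVCall],
    svtype: str,
    window: int = 200,
) -> tuple[EvalResult, list[bool], list[bool]]:
    """One-to-one matching of calls to truth events of one svtype.

    The assignment is optimal: maximum cardinality first, smallest total
    breakpoint distance among maximum assignments (solved as a linear
    assignment problem), so no compatible pairing is ever lost to an
    unlucky pairing order.  Returns the metrics plus per-call and
    per-truth TP labels.  Size-less insertion calls match on the
    breakpoint window alone; translocations match on either breakend.
    """
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    types = {c.svtype for c in calls} | {t.svtype for t in truth}
    if len(types) > 1:
        raise ValueError(f"mixed svtypes in one matching invocation: {types}")
    if types and types != {svtype}:
        raise ValueError(f"calls/truth are {types}, expected {svtype}")
    call_hit = [False] * len(calls)
    truth_hit = [False] * len(truth)
    if calls and truth:
        big = 10_000_000.0  # >> any feasible total distance: cardinality wins
        cost = np.full((len(calls), len(truth)), big)
        for ci, c in enumerate(calls):
            for ti, t in enumerate(truth):
                d = _match_distance(c, t, svtype, window)
                if d is not None:
                    cost[ci, ti] = d
        rows, cols = linear_sum_assignment(cost)
        for ci, ti in zip(rows, cols):
            if cost[ci, ti] < big:
                call_hit[ci] = True
                truth_hit[ti] = True
    tp = sum(truth_hit)
    fp = len(calls) - sum(call_hit)
    fn = len(truth) - tp
    if tp + fn == 0:
        res = EvalResult(0, fp, 0, 0.0, 0.0, 0.0)
    else:
        res = metrics(tp, fp, fn)
    return res, call_hit, truth_hit


# ---------------------------------------------------------------------------
# truth from long-read alignments


def longread_truth(
    bam_path: str | Path,
    min_support: int = 3,
    min_sv: int = 50,
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[SVCall]:
    """Extract a DEL/INS truth set from long accurate-read alignments.

    Per primary record, every I/D CIGAR op >= ``min_sv`` is evidence; split
    alignments (SA tag) with colinear same-chromosome same-strand segments
    yield large deletions (reference gap) or insertions (query gap).
    Evidence clusters supported by >= ``min_support`` distinct reads become
    truth events.
    """
    import pysam

    from clipcall.alignment_io import AlignedRead
    from clipcall.inv_tra_caller import split_segments
    from clipcall.spliced_caller import SVEvidence, cluster_evidence

    evidence: list[SVEvidence] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name or ""
            name = rec.query_name or ""
            ref = rec.reference_start
            for op, n in rec.cigartuples or ():
                opc = "MIDNSHP=X"[op]
                if opc in ("M", "=", "X"):
                    ref += n
                elif opc in ("D", "N"):
                    if n >= min_sv:
                        evidence.append(
                            SVEvidence("DEL", chrom, ref, n, "CIGAR_BAM", name)
                        )
                    ref += n
                elif opc == "I":
                    if n >= min_sv:
                        evidence.append(
                            SVEvidence("INS", chrom, ref, n, "CIGAR_BAM", name)
                        )
            read = AlignedRead.from_pysam(rec)
            if read.sa_tag:
                segs = split_segments(read)
                for a, b in zip(segs, segs[1:]):
                    if a.chrom != b.chrom or a.strand != b.strand:
                        continue
                    if a.strand == "+":
                        dr = b.rstart - a.rend
                    else:
                        dr = a.rstart - b.rend
                    dq = b.qstart - a.qend
                    if dr - dq >= min_sv:
                        pos = a.rend if a.strand == "+" else b.rend
                        evidence.append(
                            SVEvidence("DEL", chrom, pos, dr - dq, "CIGAR_BAM", name)
                        )
                    elif dq - dr >= min_sv:
                        pos = a.rend if a.strand == "+" else a.rstart
                        evidence.append(
                            SVEvidence("INS", chrom, pos, dq - dr, "CIGAR_BAM", name)
                        )
    return cluster_evidence(
        evidence, min_support, config, min_size=min_sv, evidence_tag="CIGAR"
    )


# ---------------------------------------------------------------------------
# signal capture (which read-alignment classes see which truth events)


def signal_capture(
    reads: Sequence,
    truth: Sequence[SVCall],
    category: str,
    stats=None,
    config: CallerConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of truth events whose neighbourhood holds a confirmed
    breakpoint of one signal category.

    Clip/split breakpoints are exact: confirmed when two reads agree
    within 5 bp, captured within a 200 bp window.  Discordant-, unmapped-
    mate- and translocation-pair signals only bound the breakpoint: sites
    are approximated 200 bp outside the mapped read, confirmed when two
    reads agree within 200 bp, captured within a 600 bp window.
    """
    from clipcall.alignment_io import InsertSizeStats
    from clipcall.signal_scan import (
        SignalCategory,
        classify_read,
        extract_clips,
    )
    from clipcall.inv_tra_caller import split_segments

    cat = SignalCategory[category] if isinstance(category, str) else category
    exact = cat in (SignalCategory.CLIPPED, SignalCategory.SPLIT)
    confirm_tol = 5 if exact else 200
    capture_window = 200 if exact else 600
    if stats is None:
        stats = InsertSizeStats(500.0, 50.0, 150, 30.0)

    sites: dict[str, list[int]] = defaultdict(list)
    for read in reads:
        if not read.primary or read.duplicate:
            continue
        cats = classify_read(read, stats, config)
        if not (cats & cat):
            continue
        if cat == SignalCategory.CLIPPED:
            for c in extract_clips(read, config):
                sites[read.chrom or ""].append(c.bp)
        elif cat == SignalCategory.SPLIT:
            segs = split_segments(read)
            for a, b in zip(segs, segs[1:]):
                ba = a.rend if a.strand == "+" else a.rstart
                bb = b.rstart if b.strand == "+" else b.rend
                sites[a.chrom].append(ba)
                sites[b.chrom].append(bb)
        else:
            sites[read.chrom or ""].append(read.pos - 200)
            sites[read.chrom or ""].append(read.reference_end + 200)

    confirmed: dict[str, list[int]] = defaultdict(list)
    for chrom, positions in sites.items():
        positions.sort()
        i = 0
        while i < len(positions):
            j = i
            while (
                j + 1 < len(positions)
                and positions[j + 1] - positions[i] <= confirm_tol
            ):
                j += 1
            if j > i:
                confirmed[chrom].append(positions[(i + j) // 2])
            i = j + 1

    captured = 0
    for ev in truth:
        anchors = [(ev.chrom, ev.pos), (ev.chrom, ev.end)]
        if ev.chrom2 is not None and ev.pos2 is not None:
            anchors.append((ev.chrom2, ev.pos2))
        hit = False
        for chrom, pos in anchors:
            for bp in confirmed.get(chrom, ()):
                if abs(bp - pos) <= capture_window:
                    hit = True
                    break
            if hit:
                break
        if hit:
            captured += 1
    return captured / len(truth) if truth else 0.0
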