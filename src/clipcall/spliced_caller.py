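"""Splice-aware alignment of clipped/extended sequences and CIGAR-based
deletion/insertion extraction.

Spliced alignment permits large reference gaps (D/N ops) within a single
query, so a pseudo-long read crossing a deletion junction aligns as
``<left>M <del>D <right>M`` and one crossing an insertion as
``<left>M <ins>I <right>M``.  The builtin backend is a seed-and-chain
aligner restricted to the candidate's local reference window; the external
backend shells out to minimap2's spliced mode.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from clipcall.alignment_io import write_fasta
from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)


@dataclass
class SplicedAlignment:
    """One spliced alignment record of a query against the reference."""

    query_name: str
    chrom: str
    pos: int  # 0-based
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    n_segments: int = 1
    reverse: bool = False

    @property
    def boundary_clipped(self) -> bool:
        return bool(self.cigar) and (
            self.cigar[0][0] in ("S", "H") or self.cigar[-1][0] in ("S", "H")
        )

    @property
    def boundary_aligned_len(self) -> int:
        """Length of the shortest terminal aligned (match) block."""
        blocks = [n for op, n in self.cigar if op in ("M", "=", "X")]
        if not blocks:
            return 0
        first = next(n for op, n in self.cigar if op in ("M", "=", "X"))
        last = next(
            n for op, n in reversed(self.cigar) if op in ("M", "=", "X")
        )
        return min(first, last)


@dataclass(frozen=True)
class SVEvidence:
    """One deletion/insertion observation extracted from a single alignment."""

    svtype: str  # DEL | INS
    chrom: str
    pos: int
    size: int
    source: str  # RAW_CLIP | EXTENDED | CONTIG | CIGAR_BAM
    query_name: str

    def source_reads(self) -> frozenset[str]:
        """Distinct sequencing reads behind this evidence.

        Extended-sequence names encode both constituents as
        ``<ms>/<mate>|<sm>/<mate>|n=<n>``.
        """
        if "|n=" in self.query_name:
            parts = self.query_name.split("|")[:-1]
            return frozenset(parts)
        return frozenset([self.query_name])


# ---------------------------------------------------------------------------
# builtin seed-and-chain spliced aligner


def build_kmer_index(ref: str, k: int = 15) -> dict[str, list[int]]:
    """Positions of every k-mer of a reference window."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(ref) - k + 1):
        index[ref[i : i + k]].append(i)
    return index


def _anchors(
    query: str, index: dict[str, list[int]], k: int, max_hits: int
) -> list[list[int]]:
    """Maximal exact-match anchors [qstart, rstart, length] between query and
    an indexed reference window, built by merging co-diagonal k-mer seeds."""
    raw: dict[int, list[int]] = defaultdict(list)  # diagonal -> qpos list
    for q in range(len(query) - k + 1):
        hits = index.get(query[q : q + k])
        if not hits or len(hits) > max_hits:
            continue
        for r in hits:
            raw[r - q].append(q)
    anchors: list[list[int]] = []
    for diag, qs in raw.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
                continue
            anchors.append([start, start + diag, prev - start + k])
            start = prev = q
        anchors.append([start, start + diag, prev - start + k])
    return anchors


def _chain(anchors: list[list[int]], max_ref_gap: int) -> tuple[float, list[list[int]]]:
    """Colinear chaining by DP over anchors sorted by query start.

    Score is total anchored query length with a mild gap penalty; returns
    the best chain (anchors in query order) and its score.
    """
    if not anchors:
        return 0.0, []
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    n = len(anchors)
    score = [float(a[2]) for a in anchors]
    back = [-1] * n
    for i in range(n):
        qi, ri, li = anchors[i]
        for j in range(i):
            qj, rj, lj = anchors[j]
            dq = qi - (qj + lj)
            dr = ri - (rj + lj)
            # allow small overlaps from repeated seeds; forbid reorderings
            if dq < -li + 1 or dr < -li + 1 or dr > max_ref_gap or dq > 20000:
                continue
            if ri <= rj:
                continue
            gap = abs(dq) + abs(dr)
            s = score[j] + li - min(0.01 * gap, 10.0) - (3.0 if gap else 0.0)
            if s > score[i]:
                score[i] = s
                back[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    chain.reverse()
    return score[best], chain


def _chain_to_cigar(
    chain: list[list[int]], qlen: int
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Build (ref_start, CIGAR) from a colinear anchor chain.

    Between adjacent anchors, equal query/reference gaps become M
    (substitution runs), surplus query becomes I, surplus reference D.
    Unanchored query termini become soft clips.
    """
    ops: list[tuple[str, int]] = []
    q0, r0, l0 = chain[0]
    ref_start = r0
    if q0 > 0:
        ops.append(("S", q0))
    ops.append(("M", l0))
    prev_qe, prev_re = q0 + l0, r0 + l0
    for q, r, l in chain[1:]:
        # trim any overlap with the previous anchor
        trim = max(prev_qe - q, prev_re - r, 0)
        q, r, l = q + trim, r + trim, l - trim
        if l <= 0:
            continue
        dq, dr = q - prev_qe, r - prev_re
        m = min(dq, dr)
        if m > 0:
            ops.append(("M", m))
        if dq > dr:
            ops.append(("I", dq - dr))
        elif dr > dq:
            ops.append(("D", dr - dq))
        ops.append(("M", l))
        prev_qe, prev_re = q + l, r + l
    if prev_qe < qlen:
        ops.append(("S", qlen - prev_qe))
    # merge adjacent same-op runs
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ref_start, tuple(merged)


def builtin_spliced_align(
    name: str,
    query: str,
    ref_seq: str,
    window_start: int,
    chrom: str,
    config: CallerConfig = DEFAULT_CONFIG,
    k: int = 15,
    index: Optional[dict[str, list[int]]] = None,
) -> Optional[SplicedAlignment]:
    """Align one query within a reference window; None when unalignable.

    ``index`` may carry a pre-built k-mer index of ``ref_seq`` so that many
    queries anchored at the same site share one indexing pass.
    """
    if len(query) < k:
        return None
    if index is None:
        index = build_kmer_index(ref_seq, k)
    anchors = _anchors(query, index, k, max_hits=8)
    if not anchors:
        return None
    best_score, chain = _chain(anchors, config.spliced_window)
    if not chain:
        return None
    covered = sum(a[2] for a in chain)
    if covered < min(30, 0.3 * len(query)):
        return None
    ref_start, cigar = _chain_to_cigar(chain, len(query))
    # crude uniqueness proxy: compare against the best single anchor
    # elsewhere (different diagonal region than the chain)
    chain_r = {a[1] for a in chain}
    rival = 0.0
    for a in anchors:
        if a[1] not in chain_r and abs(a[1] - chain[0][1]) > len(query):
            rival = max(rival, float(a[2]))
    mapq = 60 if rival < 0.5 * covered else 20
    gap_blocks = sum(
        1 for op, n in cigar if op in ("I", "D", "N") and n >= 30
    )
    return SplicedAlignment(
        query_name=name,
        chrom=chrom,
        pos=window_start + ref_start,
        mapq=mapq,
        cigar=cigar,
        n_segments=1 + gap_blocks,
    )


# ---------------------------------------------------------------------------
# backends


def spliced_align(
    queries: Sequence[tuple[str, str]],
    reference: str | Path,
    anchors: Optional[Sequence[tuple[str, int]]] = None,
    backend: str = "builtin",
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[SplicedAlignment]:
    """Spliced-align ``(name, sequence)`` queries against the reference.

    The builtin backend needs one ``(chrom, pos)`` anchor per query and
    searches only ``spliced_window`` bp to each side of it.  The external
    backend runs minimap2 in spliced mode genome-wide.
    """
    if backend == "builtin":
        if anchors is None or len(anchors) != len(queries):
            raise ValueError("builtin backend requires one anchor per query")
        return _align_builtin(queries, reference, anchors, config)
    if backend in ("external", "minimap2"):
        return _align_minimap2(queries, reference)
    raise ValueError(f"unknown backend {backend!r}")


def _align_builtin(
    queries: Sequence[tuple[str, str]],
    reference: str | Path,
    anchors: Sequence[tuple[str, int]],
    config: CallerConfig,
) -> list[SplicedAlignment]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(reference))
    out: list[SplicedAlignment] = []
    # queries cluster at candidate sites: group by a coarse anchor bucket so
    # each site's reference window is extracted and k-mer-indexed only once
    groups: dict[tuple[str, int], list[tuple[str, str, int]]] = defaultdict(list)
    for (name, seq), (chrom, pos) in zip(queries, anchors):
        if chrom not in fa:
            continue
        groups[(chrom, pos // 10_000)].append((name, seq, pos))
    for (chrom, _bucket), items in sorted(groups.items()):
        clen = len(fa[chrom])
        lo = min(p for _, _, p in items)
        hi = max(p for _, _, p in items)
        start = max(0, lo - config.spliced_window)
        end = min(clen, hi + config.spliced_window)
        window = str(fa[chrom][start:end]).upper()
        index = build_kmer_index(window)
        for name, seq, _pos in items:
            aln = builtin_spliced_align(
                name, seq.upper(), window, start, chrom, config, index=index
            )
            if aln is not None:
                out.append(aln)
            else:
                log.debug("query %s unaligned", name)
    return out


def _align_minimap2(
    queries: Sequence[tuple[str, str]], reference: str | Path
) -> list[SplicedAlignment]:
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "minimap2 not found on PATH; use the builtin backend"
        )
    import pysam

    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "queries.fa"
        spath = Path(tmp) / "out.sam"
        write_fasta(queries, qpath)
        with open(spath, "w") as sam_out:
            subprocess.run(
                ["minimap2", "-a", "-x", "splice", "--eqx", str(reference), str(qpath)],
                stdout=sam_out,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        records = defaultdict(list)
        with pysam.AlignmentFile(str(spath), "r") as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                records[rec.query_name].append(rec)
        out: list[SplicedAlignment] = []
        for name, recs in records.items():
            nseg = len(recs)
            for rec in recs:
                cigar = tuple(
                    ("M" if "MIDNSHP=X"[op] in "=X" else "MIDNSHP=X"[op], n)
                    for op, n in (rec.cigartuples or ())
                )
                # normalize =/X to M and merge
                merged: list[tuple[str, int]] = []
                for op, n in cigar:
                    if merged and merged[-1][0] == op:
                        merged[-1] = (op, merged[-1][1] + n)
                    else:
                        merged.append((op, n))
                out.append(
                    SplicedAlignment(
                        query_name=name,
                        chrom=rec.reference_name or "",
                        pos=rec.reference_start,
                        mapq=rec.mapping_quality,
                        cigar=tuple(merged),
                        n_segments=nseg,
                        reverse=rec.is_reverse,
                    )
                )
        return out


# ---------------------------------------------------------------------------
# filtering and evidence extraction


def filter_alignment(
    aln: SplicedAlignment, config: CallerConfig = DEFAULT_CONFIG
) -> tuple[bool, str]:
    """Keep/drop decision with reason: drop on low mapq (<10), clipped
    boundary, short terminal aligned block (<20), or fragmentation (>5
    separately aligned regions)."""
    if aln.mapq < 10:
        return False, "low_mapq"
    if aln.boundary_clipped:
        return False, "boundary_clipped"
    if aln.boundary_aligned_len < 20:
        return False, "short_boundary"
    if aln.n_segments > 5:
        return False, "fragmented"
    return True, "ok"


def call_from_cigar(
    aln: SplicedAlignment, source: str = "RAW_CLIP"
) -> list[SVEvidence]:
    """Walk the CIGAR in reference coordinates: every D/N op is deletion
    evidence, every I op insertion evidence (all sizes; the >=50 bp SV cut
    is applied at clustering)."""
    out: list[SVEvidence] = []
    ref = aln.pos
    for op, n in aln.cigar:
        if op in ("D", "N"):
            out.append(
                SVEvidence("DEL", aln.chrom, ref, n, source, aln.query_name)
            )
            ref += n
        elif op in ("M", "=", "X"):
            ref += n
        elif op == "I":
            out.append(
                SVEvidence("INS", aln.chrom, ref, n, source, aln.query_name)
            )
        elif op in ("S", "H", "P"):
            pass
        else:
            raise ValueError(f"malformed CIGAR op {op!r}")
    return out


def _sizes_compatible(a: int, b: int, frac: float) -> bool:
    return abs(a - b) <= frac * max(a, b)


def cluster_evidence(
    evidence: Sequence[SVEvidence],
    x_support: int,
    config: CallerConfig = DEFAULT_CONFIG,
    min_size: Optional[int] = None,
    evidence_tag: str = "SPLICED",
) -> list[SVCall]:
    """Merge compatible evidence into calls and apply the support threshold.

    Evidence of one svtype merges when positions are within
    ``merge_pos_tol`` bp and sizes within ``merge_size_frac`` of each
    other; a call's position/size are cluster medians and its support the
    number of distinct source reads.  Calls with support below
    ``x_support`` or size below ``min_size`` (default: the 50 bp SV
    boundary) are dropped.
    """
    import statistics

    if min_size is None:
        min_size = config.min_sv
    calls: list[SVCall] = []
    by_type: dict[tuple[str, str], list[SVEvidence]] = defaultdict(list)
    for ev in evidence:
        by_type[(ev.svtype, ev.chrom)].append(ev)
    for (svtype, chrom), evs in sorted(by_type.items()):
        evs.sort(key=lambda e: (e.pos, e.size))
        clusters: list[list[SVEvidence]] = []
        for ev in evs:
            placed = False
            for cl in reversed(clusters):
                med_pos = statistics.median(e.pos for e in cl)
                if ev.pos - med_pos > config.merge_pos_tol:
                    break
                med_size = statistics.median(e.size for e in cl)
                if abs(ev.pos - med_pos) <= config.merge_pos_tol and _sizes_compatible(
                    ev.size, round(med_size), config.merge_size_frac
                ):
                    cl.append(ev)
                    placed = True
                    break
            if not placed:
                clusters.append([ev])
        for cl in clusters:
            reads: set[str] = set()
            for ev in cl:
                reads |= ev.source_reads()
            size = round(statistics.median(e.size for e in cl))
            if len(reads) < x_support or size < min_size:
                continue
            calls.append(
                SVCall(
                    svtype=svtype,
                    chrom=chrom,
                    pos=round(statistics.median(e.pos for e in cl)),
                    size=size,
                    support=len(reads),
                    evidence=evidence_tag,
                )
            )
    calls.sort(key=lambda c: c.sort_key())
    return calls
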