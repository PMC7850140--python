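"""End-to-end chunked SV calling: signal scan -> extension + spliced
alignment -> inversion/translocation calling -> insertion decision tree.

Chunks are processed independently (pass 1); translocation evidence is
pooled genome-wide before the insertion tree runs (pass 2), because the
tree's rescue node needs the complete DEL/INV/TRA exclusion sets.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from clipcall import __version__
from clipcall.alignment_io import (
    FALLBACK_STATS,
    AlignedRead,
    GenomeChunk,
    InsertSizeStats,
    iter_chunks,
    read_chunk,
    write_vcf,
)
from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.insertion_tree import (
    ExplainedAsIndel,
    TreeContext,
    bam_indel_evidence,
    resolve_insertion,
)
from clipcall.inv_tra_caller import call_inversions, call_translocations
from clipcall.read_extension import bin_clipped_reads, extend_bin
from clipcall.signal_scan import (
    SignalCategory,
    classify_read,
    collect_candidate_breakpoints,
    extract_clips,
    quality_filter_clips,
    support_threshold,
)
from clipcall.spliced_caller import (
    SVEvidence,
    call_from_cigar,
    cluster_evidence,
    filter_alignment,
    spliced_align,
)
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)


@dataclass
class ChunkResult:
    """Pass-1 output of one chunk."""

    chunk: GenomeChunk
    stats: InsertSizeStats
    x_support: int
    clips: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    del_calls: list[SVCall] = field(default_factory=list)
    spliced_ins_calls: list[SVCall] = field(default_factory=list)
    inv_calls: list[SVCall] = field(default_factory=list)
    split_reads: list[AlignedRead] = field(default_factory=list)
    tra_pair_reads: list[AlignedRead] = field(default_factory=list)
    bam_indels: list[tuple[int, str, int, str]] = field(default_factory=list)
    n_reads: int = 0


@dataclass
class RunManifest:
    """Reproducibility record for one calling run."""

    config: CallerConfig
    bam: str
    reference: str
    seed: int
    version: str = __version__
    chunks: list[dict] = field(default_factory=list)
    call_counts: dict = field(default_factory=dict)


def _scan_stats(
    bam_path: str, chunk: GenomeChunk, fallback: Optional[InsertSizeStats]
) -> InsertSizeStats:
    """Light single-pass library statistics for one chunk (same math as
    estimate_library_stats, but straight off pysam records so the pre-pass
    stays cheap)."""
    import math

    tlens: list[int] = []
    read_length = 0
    aligned_bases = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if chunk.chrom not in bam.references:
            return fallback or FALLBACK_STATS
        for rec in bam.fetch(chunk.chrom, chunk.start, chunk.end):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            if not (chunk.start <= rec.reference_start < chunk.end):
                continue
            alen = rec.query_alignment_length
            aligned_bases += alen
            read_length = max(read_length, alen)
            if (
                rec.mapping_quality == 60
                and rec.is_paired
                and rec.template_length > 0
            ):
                tlens.append(rec.template_length)
    if not tlens or read_length == 0:
        fb = fallback or FALLBACK_STATS
        if aligned_bases and read_length:
            fb = InsertSizeStats(
                fb.mean, fb.sd, read_length, max(aligned_bases / chunk.width, 1e-6)
            )
        return fb
    mean = sum(tlens) / len(tlens)
    var = sum((t - mean) ** 2 for t in tlens) / len(tlens)
    return InsertSizeStats(
        mean=mean,
        sd=math.sqrt(var),
        read_length=read_length,
        coverage=aligned_bases / chunk.width,
    )


def _process_chunk(
    bam_path: str,
    reference: str,
    chunk: GenomeChunk,
    config: CallerConfig,
    backend: str,
    stats: InsertSizeStats,
) -> ChunkResult:
    reads = [
        r
        for r in read_chunk(bam_path, chunk)
        if chunk.start <= r.pos < chunk.end
    ]
    primaries = [r for r in reads if r.primary and not r.duplicate]
    x = support_threshold(stats.coverage, config.support_frac)

    clips_all = []
    splits: list[AlignedRead] = []
    inv_pairs: list[AlignedRead] = []
    tra_pairs: list[AlignedRead] = []
    for r in primaries:
        cats = classify_read(r, stats, config)
        if cats & SignalCategory.CLIPPED:
            clips_all.extend(extract_clips(r, config))
        if cats & SignalCategory.SPLIT:
            splits.append(r)
        if cats & SignalCategory.INVERSION_PAIR:
            inv_pairs.append(r)
        if cats & SignalCategory.TRANSLOCATION_PAIR:
            tra_pairs.append(r)
    clips_q = quality_filter_clips(clips_all, config)
    candidates = collect_candidate_breakpoints(clips_q, x)

    # extension + spliced alignment of raw clips and extended sequences
    joins = extend_bin(
        bin_clipped_reads(clips_q, config.bin_width), stats.read_length, config
    )
    queries: list[tuple[str, str]] = []
    anchors: list[tuple[str, int]] = []
    sources: dict[str, str] = {}
    seen_reads: set[str] = set()
    for c in clips_q:
        if not c.read.seq:
            continue
        qname = f"{c.read.name}/{'1' if c.read.read1 else '2'}"
        if qname in seen_reads:
            continue
        seen_reads.add(qname)
        queries.append((qname, c.read.seq))
        anchors.append((c.read.chrom or chunk.chrom, c.bp))
        sources[qname] = "RAW_CLIP"
    for j in joins:
        queries.append((j.name, j.sequence))
        anchors.append((j.ms.read.chrom or chunk.chrom, j.anchor))
        sources[j.name] = "EXTENDED"

    evidence: list[SVEvidence] = []
    alns = spliced_align(queries, reference, anchors, backend=backend, config=config)
    for aln in alns:
        keep, _reason = filter_alignment(aln, config)
        if not keep:
            continue
        evidence.extend(
            call_from_cigar(aln, source=sources.get(aln.query_name, "RAW_CLIP"))
        )

    bam_indels = bam_indel_evidence(primaries)
    for pos, svtype, size, name in bam_indels:
        if size >= config.min_sv:
            evidence.append(
                SVEvidence(svtype, chunk.chrom, pos, size, "CIGAR_BAM", name)
            )

    calls = cluster_evidence(evidence, x, config)
    del_calls = [c for c in calls if c.svtype == "DEL"]
    ins_calls = [c for c in calls if c.svtype == "INS"]
    inv_calls = call_inversions(splits, inv_pairs, clips_q, stats, x, config)

    return ChunkResult(
        chunk=chunk,
        stats=stats,
        x_support=x,
        clips=clips_q,
        candidates=candidates,
        del_calls=del_calls,
        spliced_ins_calls=ins_calls,
        inv_calls=inv_calls,
        split_reads=splits,
        tra_pair_reads=tra_pairs,
        bam_indels=bam_indels,
        n_reads=len(reads),
    )


def _dedupe_calls(calls: list[SVCall], config: CallerConfig) -> list[SVCall]:
    """Collapse boundary duplicates: same type within 10 bp, sizes within 20%."""
    calls = sorted(calls, key=lambda c: c.sort_key())
    out: list[SVCall] = []
    for c in calls:
        dup = False
        for prev in reversed(out):
            if prev.chrom != c.chrom or c.pos - prev.pos > config.merge_pos_tol:
                break
            if prev.svtype != c.svtype:
                continue
            if c.size is None or prev.size is None:
                dup = True
                break
            if abs(c.size - prev.size) <= config.merge_size_frac * max(
                c.size, prev.size
            ):
                dup = True
                break
        if not dup:
            out.append(c)
    return out


def run_caller(
    bam: str | Path,
    reference: str | Path,
    out_vcf: Optional[str | Path] = None,
    config: CallerConfig = DEFAULT_CONFIG,
    backend: str = "builtin",
    threads: int = 1,
    seed: int = 0,
    emit_indels: bool = False,
) -> tuple[list[SVCall], RunManifest]:
    """Run the full caller over a coordinate-sorted, indexed BAM.

    Returns the merged, sorted call list and a run manifest; writes a VCF
    when ``out_vcf`` is given.  Output is deterministic for fixed inputs
    and independent of ``threads`` (chunks are independent; the merge is
    order-canonical).
    """
    bam, reference = str(bam), str(reference)
    with pysam.AlignmentFile(bam, "rb") as bf:
        ref_lengths = dict(zip(bf.references, bf.lengths))
    chunks = list(iter_chunks(ref_lengths, config.chunk_width))

    manifest = RunManifest(
        config=config, bam=bam, reference=reference, seed=seed
    )

    # library statistics are resolved serially in chunk order (fallback
    # chains to the previous chunk), so chunk processing itself can run in
    # parallel with identical inputs at any thread count
    chunk_stats: list[InsertSizeStats] = []
    prev_stats: Optional[InsertSizeStats] = None
    for ch in chunks:
        s = _scan_stats(bam, ch, prev_stats)
        chunk_stats.append(s)
        prev_stats = s

    results: list[ChunkResult] = []
    if threads > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            futures = [
                pool.submit(
                    _process_chunk, bam, reference, ch, config, backend, s
                )
                for ch, s in zip(chunks, chunk_stats)
            ]
            results = [f.result() for f in futures]
    else:
        results = [
            _process_chunk(bam, reference, ch, config, backend, s)
            for ch, s in zip(chunks, chunk_stats)
        ]

    # genome-wide translocations (evidence joins chromosomes across chunks)
    all_splits = [r for res in results for r in res.split_reads]
    all_tra_pairs = [r for res in results for r in res.tra_pair_reads]
    all_clips = [c for res in results for c in res.clips]
    x_values = [res.x_support for res in results if res.n_reads > 0]
    x_global = max(2, round(sum(x_values) / len(x_values))) if x_values else 2
    tra_calls = call_translocations(
        all_splits, all_tra_pairs, all_clips, x_global, config
    )

    del_calls = _dedupe_calls(
        [c for res in results for c in res.del_calls], config
    )
    inv_calls = _dedupe_calls(
        [c for res in results for c in res.inv_calls], config
    )

    # pass 2: insertion decision tree per candidate
    ins_calls: list[SVCall] = []
    indel_records: list[ExplainedAsIndel] = []
    node_counts: dict[str, int] = {}
    for res in results:
        ctx = TreeContext(
            bam_path=bam,
            reference=reference,
            stats=res.stats,
            x_support=res.x_support,
            clips=res.clips,
            spliced_ins_calls=res.spliced_ins_calls,
            del_calls=del_calls,
            inv_calls=inv_calls,
            tra_calls=tra_calls,
            bam_indel_evidence=res.bam_indels,
            config=config,
            backend=backend,
        )
        for cand in res.candidates:
            outcome = resolve_insertion(cand, ctx)
            if isinstance(outcome, ExplainedAsIndel):
                indel_records.append(outcome)
            elif isinstance(outcome, SVCall):
                ins_calls.append(outcome)
        for node, n in ctx.node_counters.items():
            node_counts[node] = node_counts.get(node, 0) + n
        manifest.chunks.append(
            {
                "chrom": res.chunk.chrom,
                "start": res.chunk.start,
                "end": res.chunk.end,
                "reads": res.n_reads,
                "coverage": round(res.stats.coverage, 2),
                "x_support": res.x_support,
                "candidates": len(res.candidates),
            }
        )
    ins_calls = _dedupe_calls(ins_calls, config)

    calls = del_calls + ins_calls + inv_calls + tra_calls
    if emit_indels:
        calls.extend(
            SVCall(
                rec.svtype,
                rec.chrom,
                rec.pos,
                size=rec.size,
                support=rec.support,
                evidence="CIGAR",
            )
            for rec in indel_records
        )
    calls.sort(key=lambda c: c.sort_key())
    manifest.call_counts = {
        "DEL": len(del_calls),
        "INS": len(ins_calls),
        "INV": len(inv_calls),
        "TRA": len(tra_calls),
        "nodes": node_counts,
    }
    if out_vcf is not None:
        write_vcf(calls, reference, out_vcf)
    return calls, manifest
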