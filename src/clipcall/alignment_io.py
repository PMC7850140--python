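"""Alignment, sequence and variant I/O plus per-chunk library statistics.

All coordinates are 0-based half-open inside the package; conversion to and
from the 1-based SAM/VCF conventions happens only in this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from clipcall.svcall import SVCall

log = logging.getLogger(__name__)

#: CIGAR ops that consume query sequence / reference sequence
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
#: pysam integer opcode -> character
_CIGAR_CHARS = "MIDNSHP=X"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SAEntry:
    """One supplementary alignment from the SA tag (pos converted to 0-based)."""

    chrom: str
    pos: int
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int


@dataclass
class AlignedRead:
    """One SAM record in internal representation."""

    name: str
    chrom: Optional[str]
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: Optional[str]
    quals: Optional[tuple[int, ...]]
    paired: bool = False
    read1: bool = True
    proper_pair: bool = False
    reverse: bool = False
    mate_reverse: bool = False
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    unmapped: bool = False
    mate_unmapped: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    tlen: int = 0
    sa_tag: tuple[SAEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 0 and not self.unmapped:
            raise ValueError("pos must be >= 0 for mapped reads")
        if self.seq is not None and self.cigar:
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR query length {qlen} != seq length {len(self.seq)}"
                )
        if self.seq is not None and self.quals is not None:
            if len(self.quals) != len(self.seq):
                raise ValueError("quals length != seq length")

    @property
    def primary(self) -> bool:
        return not (self.secondary or self.supplementary or self.unmapped)

    @property
    def reference_span(self) -> int:
        """Reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    @property
    def aligned_length(self) -> int:
        """Query bases that are aligned (clips excluded)."""
        return sum(n for op, n in self.cigar if op in ("M", "I", "=", "X"))

    @classmethod
    def from_pysam(cls, rec: "pysam.AlignedSegment") -> "AlignedRead":
        cigar = tuple(
            (_CIGAR_CHARS[op], n) for op, n in (rec.cigartuples or ())
        )
        sa: list[SAEntry] = []
        if rec.has_tag("SA"):
            for part in str(rec.get_tag("SA")).rstrip(";").split(";"):
                c, p, s, cg, mq, _nm = part.split(",")
                sa.append(
                    SAEntry(c, int(p) - 1, s, parse_cigar(cg), int(mq))
                )
        quals = rec.query_qualities
        return cls(
            name=rec.query_name or "",
            chrom=rec.reference_name,
            pos=rec.reference_start if not rec.is_unmapped else (rec.reference_start if rec.reference_start >= 0 else 0),
            mapq=rec.mapping_quality,
            cigar=cigar,
            seq=rec.query_sequence,
            quals=tuple(quals) if quals is not None else None,
            paired=rec.is_paired,
            read1=rec.is_read1 or not rec.is_paired,
            proper_pair=rec.is_proper_pair,
            reverse=rec.is_reverse,
            mate_reverse=rec.mate_is_reverse if rec.is_paired else False,
            secondary=rec.is_secondary,
            supplementary=rec.is_supplementary,
            duplicate=rec.is_duplicate,
            unmapped=rec.is_unmapped,
            mate_unmapped=rec.mate_is_unmapped if rec.is_paired else False,
            mate_chrom=rec.next_reference_name,
            mate_pos=rec.next_reference_start
            if rec.next_reference_start >= 0
            else None,
            tlen=rec.template_length,
            sa_tag=tuple(sa),
        )


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string like ``'100M50S'`` into ``(op, length)`` pairs."""
    if not text:
        raise ValueError("empty CIGAR (unaligned records carry '*' in SAM)")
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_CHARS:
            if not num:
                raise ValueError(f"malformed CIGAR {text!r}")
            out.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR {text!r}")
    if num:
        raise ValueError(f"malformed CIGAR {text!r}")
    return tuple(out)


def cigar_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


@dataclass(frozen=True)
class GenomeChunk:
    """A 0-based half-open genome interval used as a processing unit."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid chunk [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertSizeStats:
    """Per-chunk library statistics: insert-size mean/sd, read length, coverage."""

    mean: float
    sd: float
    read_length: int
    coverage: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("invalid library statistics")


#: used when a chunk has no qualifying pairs and no prior chunk exists
FALLBACK_STATS = InsertSizeStats(mean=500.0, sd=50.0, read_length=150, coverage=30.0)


# ---------------------------------------------------------------------------
# operations


def iter_chunks(
    reference_lengths: dict[str, int], width: int = 1_000_000
) -> Iterator[GenomeChunk]:
    """Tile every chromosome with fixed-width chunks (terminal chunk shorter)."""
    for chrom, length in reference_lengths.items():
        for start in range(0, length, width):
            yield GenomeChunk(chrom, start, min(start + width, length))


def read_chunk(bam_path: str | Path, chunk: GenomeChunk) -> Iterator[AlignedRead]:
    """Yield every record overlapping ``chunk`` (duplicates tagged, not dropped).

    Downstream consumers filter duplicate-flagged reads out; yielding them
    here keeps the reader a faithful view of the file.
    """
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if chunk.chrom not in bam.references:
            log.warning("chromosome %s absent from %s", chunk.chrom, bam_path)
            return
        for rec in bam.fetch(chunk.chrom, chunk.start, chunk.end):
            yield AlignedRead.from_pysam(rec)


def estimate_library_stats(
    reads: Iterable[AlignedRead],
    chunk_width: int,
    fallback: InsertSizeStats | None = None,
) -> InsertSizeStats:
    """Estimate insert-size mean/sd, read length and coverage for one chunk.

    Insert sizes come from primary, non-duplicate, mapq-60 reads; each pair
    is counted once through its leftmost mate (TLEN > 0).  Read length is
    the longest aligned length observed, coverage the total aligned bases
    divided by the chunk width.  The sd is the population sd.
    """
    tlens: list[int] = []
    read_length = 0
    aligned_bases = 0
    for r in reads:
        if not r.primary or r.duplicate:
            continue
        alen = r.aligned_length
        aligned_bases += alen
        read_length = max(read_length, alen)
        if r.mapq == 60 and r.paired and r.tlen > 0:
            tlens.append(abs(r.tlen))
    if not tlens or read_length == 0:
        fb = fallback or FALLBACK_STATS
        log.warning("no mapq-60 pairs in chunk; falling back to %s", fb)
        if aligned_bases and read_length:
            fb = InsertSizeStats(
                fb.mean, fb.sd, read_length, max(aligned_bases / chunk_width, 1e-6)
            )
        return fb
    mean = sum(tlens) / len(tlens)
    var = sum((t - mean) ** 2 for t in tlens) / len(tlens)
    return InsertSizeStats(
        mean=mean,
        sd=math.sqrt(var),
        read_length=read_length,
        coverage=aligned_bases / chunk_width,
    )


def high_quality_base_ratio(quals: Sequence[int], start: int, end: int) -> float:
    """Fraction of bases in ``quals[start:end]`` with Phred value strictly > 20."""
    if not (0 <= start < end <= len(quals)):
        raise ValueError(f"empty or out-of-range interval [{start}, {end})")
    window = quals[start:end]
    return sum(1 for q in window if q > 20) / len(window)


# ---------------------------------------------------------------------------
# FASTA / FASTQ / VCF plumbing


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(
    records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">',
    '##INFO=<ID=NODE,Number=1,Type=String,Description="Evidence class that resolved the call">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Breakpoint precise, size unresolved">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of the mate breakend">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def write_vcf(
    calls: Sequence[SVCall], reference: str | Path, out: str | Path
) -> None:
    """Write calls as VCF 4.2 (1-based positions; DEL/INV carry END, sizes SVLEN).

    ``calls`` must be sorted by (chrom, pos).  A deletion at 0-based ``p`` of
    size ``s`` is written with POS ``p+1`` and END ``p+1+s``.
    """
    import pyfaidx

    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")
    fa = pyfaidx.Fasta(str(reference))
    lines = ["##fileformat=VCFv4.2", "##source=clipcall"]
    for name in fa.keys():
        lines.append(f"##contig=<ID={name},length={len(fa[name])}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    bnd_count = 0
    for i, c in enumerate(calls):
        if c.chrom not in fa or c.pos >= len(fa[c.chrom]):
            raise ValueError(f"call position {c.chrom}:{c.pos} outside reference")
        ref_base = str(fa[c.chrom][c.pos]).upper() or "N"
        pos1 = c.pos + 1
        info = [f"SVTYPE={'BND' if c.svtype == 'TRA' else c.svtype}"]
        if c.svtype == "TRA":
            bnd_count += 1
            this_id = f"BND_{bnd_count}a"
            mate_id = f"BND_{bnd_count}b"
            if c.chrom2 is None or c.pos2 is None:
                raise ValueError("translocation call lacks partner breakend")
            alt_a = f"{ref_base}[{c.chrom2}:{c.pos2 + 1}["
            info.append(f"MATEID={mate_id}")
            info.append(f"SUPPORT={c.support}")
            info.append(f"NODE={c.evidence}")
            lines.append(
                f"{c.chrom}\t{pos1}\t{this_id}\t{ref_base}\t{alt_a}\t.\tPASS\t"
                + ";".join(info)
            )
            mate_ref = str(fa[c.chrom2][c.pos2]).upper() or "N"
            alt_b = f"{mate_ref}[{c.chrom}:{pos1}["
            lines.append(
                f"{c.chrom2}\t{c.pos2 + 1}\t{mate_id}\t{mate_ref}\t{alt_b}\t.\tPASS\t"
                f"SVTYPE=BND;MATEID={this_id};SUPPORT={c.support};NODE={c.evidence}"
            )
            continue
        if c.svtype in ("DEL", "INV"):
            if c.size is None:
                raise ValueError(f"{c.svtype} call without size")
            info.append(f"END={pos1 + c.size}")
            info.append(f"SVLEN={-c.size if c.svtype == 'DEL' else c.size}")
        elif c.svtype == "INS":
            if c.size is not None:
                info.append(f"SVLEN={c.size}")
            else:
                info.append("IMPRECISE")
        info.append(f"SUPPORT={c.support}")
        info.append(f"NODE={c.evidence}")
        lines.append(
            f"{c.chrom}\t{pos1}\tclipcall_{i + 1}\t{ref_base}\t<{c.svtype}>\t.\tPASS\t"
            + ";".join(info)
        )
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[SVCall]:
    """Parse a (clipcall or generic SV) VCF back into internal calls."""
    calls: list[SVCall] = []
    seen_bnd: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            if svtype is None:
                # sequence-resolved records: infer from allele lengths
                if rec.alts and len(rec.alts[0]) > len(rec.ref):
                    svtype = "INS"
                elif rec.alts and len(rec.alts[0]) < len(rec.ref):
                    svtype = "DEL"
                else:
                    continue
            if svtype == "BND":
                if rec.id in seen_bnd:
                    continue
                mate = info.get("MATEID")
                if isinstance(mate, tuple):
                    mate = mate[0]
                if mate:
                    seen_bnd.add(str(mate))
                alt = rec.alts[0] if rec.alts else ""
                chrom2, pos2 = None, None
                for sep in "[]":
                    if sep in alt:
                        inner = alt.split(sep)[1]
                        chrom2, p = inner.split(":")
                        pos2 = int(p) - 1
                        break
                calls.append(
                    SVCall(
                        "TRA",
                        rec.chrom,
                        rec.pos - 1,
                        support=int(info.get("SUPPORT", 0) or 0),
                        chrom2=chrom2,
                        pos2=pos2,
                    )
                )
                continue
            if svtype == "DUP":
                svtype = "INS"  # tandem duplications are evaluated as insertions
            if svtype not in ("DEL", "INS", "INV"):
                continue
            size: Optional[int] = None
            svlen = info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is not None:
                size = abs(int(svlen))
            elif "END" in info and svtype != "INS":
                size = int(info["END"]) - rec.pos
            elif rec.alts and not str(rec.alts[0]).startswith("<"):
                size = abs(len(rec.alts[0]) - len(rec.ref))
            if size == 0:
                size = None
            calls.append(
                SVCall(
                    svtype,
                    rec.chrom,
                    rec.pos - 1,
                    size=size,
                    support=int(info.get("SUPPORT", 0) or 0),
                    evidence=str(info.get("NODE", "SPLICED")),
                )
            )
    return calls
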