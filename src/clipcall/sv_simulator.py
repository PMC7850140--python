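"""Spike-in SV simulation: diploid genomes with truth sets and paired-end reads.

SVs are spiked into two haploid copies of a reference according to random
genotypes (1|1, 0|1, 1|0 with equal probability, so homozygous:heterozygous
is 1:2 in expectation).  Inversions are placed at random positions with
lengths uniform in 50 bp-10 kb; translocations are reciprocal segment
exchanges between random chromosome pairs, three per pair, each creating
two breakpoints.  Reads are drawn per haplotype with normally distributed
insert sizes and Bernoulli per-base substitution errors, then pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from clipcall.alignment_io import write_fasta
from clipcall.svcall import SVCall

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")
GENOTYPES = ("1|1", "0|1", "1|0")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TruthEvent:
    """One ground-truth SV in reference coordinates."""

    svtype: str  # DEL | INS | INV | TRA
    chrom: str
    pos: int
    size: int
    genotype: str
    seq: Optional[str] = None  # inserted sequence (INS)
    chrom2: Optional[str] = None  # partner breakpoint (TRA)
    pos2: Optional[int] = None

    def on_hap(self, hap: int) -> bool:
        """Whether the event is present on haplotype 1 or 2."""
        return self.genotype.split("|")[hap - 1] == "1"


@dataclass
class DiploidGenome:
    """Reference, truth events, and the two derived haplotypes."""

    reference: dict[str, str]
    truth: list[TruthEvent]
    hap1: dict[str, str] = field(default_factory=dict)
    hap2: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def rebuild(self) -> None:
        self.hap1 = apply_truth(self.reference, self.truth, hap=1)
        self.hap2 = apply_truth(self.reference, self.truth, hap=2)


# ---------------------------------------------------------------------------
# reference and event generation


def random_reference(
    n_chroms: int,
    length: int,
    rng: np.random.Generator,
    gc: float = 0.5,
) -> dict[str, str]:
    """A toy reference of ``n_chroms`` random chromosomes of ``length`` bp."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for i in range(n_chroms):
        idx = rng.choice(4, size=length, p=p)
        out[f"chr{i + 1}"] = alphabet[idx].tobytes().decode()
    return out


def random_seq(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, size=length)].tobytes().decode()


def assign_genotypes(n_events: int, rng: np.random.Generator) -> list[str]:
    """i.i.d. uniform genotypes over 1|1, 0|1, 1|0 (hom:het = 1:2)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    return [GENOTYPES[i] for i in rng.integers(0, 3, size=n_events)]


def _free_positions(
    reference: dict[str, str],
    truth: Sequence[TruthEvent],
    rng: np.random.Generator,
    n: int,
    sizes: Sequence[int],
    min_gap: int = 1000,
    max_tries: int = 200,
) -> list[tuple[str, int]]:
    """Random (chrom, pos) draws rejected on 1 kb conflicts with existing
    events and each other."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in reference}
    for ev in truth:
        occupied.setdefault(ev.chrom, []).append((ev.pos, ev.pos + ev.size))
        if ev.chrom2 is not None and ev.pos2 is not None:
            occupied.setdefault(ev.chrom2, []).append((ev.pos2, ev.pos2 + 1))
    chroms = sorted(reference)
    out: list[tuple[str, int]] = []
    for size in sizes:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(0, len(chroms))]
            clen = len(reference[chrom])
            if clen < size + 2 * min_gap:
                continue
            pos = int(rng.integers(min_gap, clen - size - min_gap))
            if all(
                pos + size + min_gap <= s or e + min_gap <= pos
                for s, e in occupied[chrom]
            ):
                occupied[chrom].append((pos, pos + size))
                out.append((chrom, pos))
                break
        else:
            raise RuntimeError(
                "could not place event; genome too small or too crowded"
            )
    return out


def generate_events(
    reference: dict[str, str],
    rng: np.random.Generator,
    n_del: int = 0,
    n_ins: int = 0,
    del_size_range: tuple[int, int] = (100, 5000),
    ins_size_range: tuple[int, int] = (60, 800),
    repeat_frac: float = 0.3,
    existing: Sequence[TruthEvent] = (),
) -> list[TruthEvent]:
    """Invent DEL/INS events with genotypes; ~``repeat_frac`` of insertions
    are tandem arrays of a 20-mer (SVs in real genomes are repeat-enriched,
    and tandem-duplication-like inserts are the hard case for assembly)."""
    sizes = [
        int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for lo, hi in [del_size_range] * n_del + [ins_size_range] * n_ins
    ]
    spots = _free_positions(reference, existing, rng, n_del + n_ins, sizes)
    genotypes = assign_genotypes(n_del + n_ins, rng) if n_del + n_ins else []
    events: list[TruthEvent] = []
    for i, ((chrom, pos), size) in enumerate(zip(spots, sizes)):
        if i < n_del:
            events.append(TruthEvent("DEL", chrom, pos, size, genotypes[i]))
        else:
            if rng.random() < repeat_frac:
                unit = random_seq(rng, 20)
                seq = (unit * (size // 20 + 1))[:size]
            else:
                seq = random_seq(rng, size)
            events.append(
                TruthEvent("INS", chrom, pos, size, genotypes[i], seq=seq)
            )
    return events


# ---------------------------------------------------------------------------
# spiking


def _apply_to_sequence(seq: str, events: Sequence[TruthEvent]) -> str:
    """Apply one chromosome's events right-to-left so coordinates stay valid."""
    for ev in sorted(events, key=lambda e: -e.pos):
        if ev.pos + (ev.size if ev.svtype in ("DEL", "INV") else 0) > len(seq):
            raise ValueError(f"event at {ev.chrom}:{ev.pos} beyond chromosome end")
        if ev.svtype == "DEL":
            seq = seq[: ev.pos] + seq[ev.pos + ev.size :]
        elif ev.svtype == "INS":
            if ev.seq is None or len(ev.seq) != ev.size:
                raise ValueError("INS event lacks a sequence of its size")
            seq = seq[: ev.pos] + ev.seq + seq[ev.pos :]
        elif ev.svtype == "INV":
            seq = (
                seq[: ev.pos]
                + revcomp(seq[ev.pos : ev.pos + ev.size])
                + seq[ev.pos + ev.size :]
            )
        else:
            raise ValueError(f"cannot apply svtype {ev.svtype}")
    return seq


def apply_truth(
    reference: dict[str, str], truth: Sequence[TruthEvent], hap: int
) -> dict[str, str]:
    """Reconstruct one haplotype from the reference and the truth set."""
    linear = [ev for ev in truth if ev.svtype != "TRA" and ev.on_hap(hap)]
    _check_spacing(linear)
    out: dict[str, str] = {}
    for chrom, seq in reference.items():
        evs = [e for e in linear if e.chrom == chrom]
        out[chrom] = _apply_to_sequence(seq, evs)
    # reciprocal translocations: alternating segment exchange at the
    # recorded breakpoint pairs, applied on top of the linear events (the
    # 1 kb spacing rule keeps coordinates safely translatable)
    tra = [ev for ev in truth if ev.svtype == "TRA" and ev.on_hap(hap)]
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    seen = set()
    for ev in tra:
        if ev.chrom2 is None or ev.pos2 is None:
            continue
        # each exchange is recorded once per side; canonicalize to dedupe
        if (ev.chrom, ev.pos) <= (ev.chrom2, ev.pos2):
            key, cut = (ev.chrom, ev.chrom2), (ev.pos, ev.pos2)
        else:
            key, cut = (ev.chrom2, ev.chrom), (ev.pos2, ev.pos)
        if (key, cut) in seen:
            continue
        seen.add((key, cut))
        pairs.setdefault(key, []).append(cut)
    for (ca, cb), cuts in pairs.items():
        a, b = out[ca], out[cb]
        cuts = sorted(set(cuts))
        new_a, new_b = [], []
        prev_a = prev_b = 0
        for i, (cut_a, cut_b) in enumerate(cuts):
            if i % 2 == 0:
                new_a.append(a[prev_a:cut_a])
                new_b.append(b[prev_b:cut_b])
            else:
                new_a.append(b[prev_b:cut_b])
                new_b.append(a[prev_a:cut_a])
            prev_a, prev_b = cut_a, cut_b
        if len(cuts) % 2 == 1:
            new_a.append(b[prev_b:])
            new_b.append(a[prev_a:])
        else:
            new_a.append(a[prev_a:])
            new_b.append(b[prev_b:])
        out[ca], out[cb] = "".join(new_a), "".join(new_b)
    return out


def _check_spacing(events: Sequence[TruthEvent], min_gap: int = 0) -> None:
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for evs in by_chrom.values():
        evs.sort(key=lambda e: e.pos)
        for a, b in zip(evs, evs[1:]):
            ref_span = a.size if a.svtype in ("DEL", "INV") else 0
            if a.pos + ref_span + min_gap > b.pos:
                raise ValueError(
                    f"overlapping events at {a.chrom}:{a.pos} and {b.chrom}:{b.pos}"
                )


def spike_svs(
    reference: dict[str, str],
    events: Sequence[TruthEvent],
    seed: int = 0,
) -> DiploidGenome:
    """Apply genotyped events to both haplotypes; truth stays in reference
    coordinates.  Overlapping events or events beyond a chromosome end
    raise."""
    genome = DiploidGenome(
        reference=dict(reference), truth=list(events), seed=seed
    )
    genome.rebuild()
    return genome


# ---------------------------------------------------------------------------
# random inversions and translocations


def simulate_inversions(
    genome: DiploidGenome,
    rng: np.random.Generator,
    n: int = 200,
    len_range: tuple[int, int] = (50, 10_000),
) -> DiploidGenome:
    """Add ``n`` random inversions (lengths uniform in ``len_range``),
    avoiding 1 kb conflicts with existing events, and rebuild haplotypes."""
    if n == 0:
        return genome
    sizes = [int(rng.integers(len_range[0], len_range[1] + 1)) for _ in range(n)]
    spots = _free_positions(genome.reference, genome.truth, rng, n, sizes)
    genotypes = assign_genotypes(n, rng)
    for (chrom, pos), size, gt in zip(spots, sizes, genotypes):
        genome.truth.append(TruthEvent("INV", chrom, pos, size, gt))
    genome.rebuild()
    return genome


def simulate_translocations(
    genome: DiploidGenome,
    rng: np.random.Generator,
    pairs_per_hap: int = 10,
    events_per_pair: int = 3,
) -> DiploidGenome:
    """Reciprocal translocations: per haplotype, ``pairs_per_hap`` disjoint
    chromosome pairs, ``events_per_pair`` exchanges per pair, two
    breakpoints per exchange (so 60 per haplotype at the defaults).

    Translocations are always heterozygous, assigned to one haplotype.
    """
    chroms = sorted(genome.reference)
    if len(chroms) < 2 * pairs_per_hap:
        raise ValueError(
            f"need at least {2 * pairs_per_hap} chromosomes, have {len(chroms)}"
        )
    for hap, gt in ((1, "1|0"), (2, "0|1")):
        order = list(rng.permutation(len(chroms)))
        for p in range(pairs_per_hap):
            ca, cb = chroms[order[2 * p]], chroms[order[2 * p + 1]]
            la, lb = len(genome.reference[ca]), len(genome.reference[cb])
            cuts_a = sorted(
                int(rng.integers(1000, la - 1000)) for _ in range(events_per_pair)
            )
            cuts_b = sorted(
                int(rng.integers(1000, lb - 1000)) for _ in range(events_per_pair)
            )
            for cut_a, cut_b in zip(cuts_a, cuts_b):
                genome.truth.append(
                    TruthEvent(
                        "TRA", ca, cut_a, 1, gt, chrom2=cb, pos2=cut_b
                    )
                )
                genome.truth.append(
                    TruthEvent(
                        "TRA", cb, cut_b, 1, gt, chrom2=ca, pos2=cut_a
                    )
                )
    genome.rebuild()
    return genome


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: DiploidGenome,
    fq1: str | Path,
    fq2: str | Path,
    rng: np.random.Generator,
    coverage_per_hap: float = 15.0,
    read_len: int = 150,
    error_rate: float = 0.002,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
) -> int:
    """Simulate paired-end reads from both haplotypes into two FASTQ files.

    Fragments are uniform over each chromosome with insert sizes
    Normal(mean, sd) truncated at the read length; mate 1 is the forward
    fragment start, mate 2 the reverse complement of the fragment end.
    Substitution errors are Bernoulli(``error_rate``) per base; erroneous
    bases get low Phred values (2-20), correct bases 30-40.  Returns the
    number of pairs written.
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    alphabet = "ACGT"
    n_pairs = 0
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for hap_i, hap in ((1, genome.hap1), (2, genome.hap2)):
            for chrom in sorted(hap):
                seq = hap[chrom]
                L = len(seq)
                if L < insert_mean + 1:
                    continue
                n = int(round(coverage_per_hap * L / (2 * read_len)))
                inserts = np.maximum(
                    rng.normal(insert_mean, insert_sd, size=n).round().astype(int),
                    read_len,
                )
                inserts = np.minimum(inserts, L)
                starts = (rng.random(n) * (L - inserts + 1)).astype(int)
                nerr1 = rng.binomial(read_len, error_rate, size=n)
                nerr2 = rng.binomial(read_len, error_rate, size=n)
                for i in range(n):
                    s, ins = int(starts[i]), int(inserts[i])
                    r1 = seq[s : s + read_len]
                    r2 = revcomp(seq[s + ins - read_len : s + ins])
                    q1 = rng.integers(30, 41, size=read_len)
                    q2 = rng.integers(30, 41, size=read_len)
                    for arr_q, nerr, which in ((q1, nerr1[i], 1), (q2, nerr2[i], 2)):
                        if nerr == 0:
                            continue
                        pos = rng.choice(read_len, size=int(nerr), replace=False)
                        tgt = r1 if which == 1 else r2
                        tgt = list(tgt)
                        for p in pos:
                            old = tgt[p]
                            choices = [b for b in alphabet if b != old]
                            tgt[p] = choices[int(rng.integers(0, 3))]
                            arr_q[p] = int(rng.integers(2, 21))
                        if which == 1:
                            r1 = "".join(tgt)
                        else:
                            r2 = "".join(tgt)
                    name = f"sim_{hap_i}_{chrom}_{s}_{n_pairs}"
                    f1.write(
                        f"@{name}\n{r1}\n+\n"
                        + "".join(chr(int(q) + 33) for q in q1)
                        + "\n"
                    )
                    f2.write(
                        f"@{name}\n{r2}\n+\n"
                        + "".join(chr(int(q) + 33) for q in q2)
                        + "\n"
                    )
                    n_pairs += 1
    return n_pairs


# ---------------------------------------------------------------------------
# output plumbing


def write_genome(genome: DiploidGenome, outdir: str | Path) -> dict[str, Path]:
    """Write reference, haplotype FASTAs and the truth VCF; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "hap1": outdir / "hap1.fa",
        "hap2": outdir / "hap2.fa",
        "truth": outdir / "truth.vcf",
    }
    write_fasta(sorted(genome.reference.items()), paths["reference"])
    write_fasta(sorted(genome.hap1.items()), paths["hap1"])
    write_fasta(sorted(genome.hap2.items()), paths["hap2"])
    write_truth_vcf(genome, paths["truth"])
    return paths


def truth_to_calls(truth: Sequence[TruthEvent]) -> list[SVCall]:
    """Truth events as calls (for the evaluator's matching machinery)."""
    calls = []
    for ev in truth:
        calls.append(
            SVCall(
                ev.svtype,
                ev.chrom,
                ev.pos,
                size=ev.size if ev.svtype != "TRA" else None,
                support=0,
                evidence="SPLICED",
                chrom2=ev.chrom2,
                pos2=ev.pos2,
                genotype=ev.genotype,
            )
        )
    return calls


def write_truth_vcf(genome: DiploidGenome, path: str | Path) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=clipcall-sim"]
    for name in sorted(genome.reference):
        lines.append(
            f"##contig=<ID={name},length={len(genome.reference[name])}>"
        )
    lines.append(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">'
    )
    lines.append(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'
    )
    lines.append(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim")
    for i, ev in enumerate(
        sorted(genome.truth, key=lambda e: (e.chrom, e.pos))
    ):
        svtype = "BND" if ev.svtype == "TRA" else ev.svtype
        info = [f"SVTYPE={svtype}"]
        if ev.svtype in ("DEL", "INV"):
            info.append(f"END={ev.pos + 1 + ev.size}")
            info.append(f"SVLEN={-ev.size if ev.svtype == 'DEL' else ev.size}")
        elif ev.svtype == "INS":
            info.append(f"SVLEN={ev.size}")
        lines.append(
            f"{ev.chrom}\t{ev.pos + 1}\ttruth_{i}\tN\t<{svtype}>\t.\tPASS\t"
            + ";".join(info)
            + f"\tGT\t{ev.genotype}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
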