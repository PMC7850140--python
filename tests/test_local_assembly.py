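"""local_assembly: de Bruijn assembly, read collection and contig-based
insertion calling."""

from __future__ import annotations

import numpy as np
import pytest

from clipcall.alignment_io import parse_cigar
from clipcall.local_assembly import (
    Contig,
    assemble_pooled,
    call_from_contigs,
    collect_assembly_reads,
    debruijn_assemble,
    revcomp,
)
from clipcall.signal_scan import BreakpointCandidate
from clipcall.spliced_caller import SplicedAlignment, builtin_spliced_align
from tests.conftest import build_bam


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def tile_reads(seq: str, read_len: int = 100, step: int = 5) -> list[str]:
    return [
        seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)
    ]


class TestDebruijnAssemble:
    @pytest.mark.parametrize("k", [41, 61, 81])
    def test_exact_reconstruction(self, k):
        # two reads per start position: terminal k-mers must clear the
        # coverage-2 cutoff for the ends to survive
        rng = np.random.default_rng(200 + k)
        target = rand_seq(rng, 500)
        contigs = debruijn_assemble(tile_reads(target) * 2, k)
        seqs = {c.seq for c in contigs}
        assert target in seqs or revcomp(target) in seqs

    def test_snp_bubble_popped(self):
        rng = np.random.default_rng(201)
        hap_a = rand_seq(rng, 400)
        pos = 200
        hap_b = hap_a[:pos] + ("T" if hap_a[pos] != "T" else "A") + hap_a[pos + 1 :]
        reads = tile_reads(hap_a, step=4) * 2 + tile_reads(hap_b, step=8) * 2
        contigs = debruijn_assemble(reads, 41)
        long = [c for c in contigs if len(c.seq) >= 380]
        assert len(long) == 2  # one orientation each
        assert {c.seq for c in long} == {hap_a, revcomp(hap_a)}

    def test_single_read_pruned(self):
        rng = np.random.default_rng(202)
        assert debruijn_assemble([rand_seq(rng, 200)], 41) == []

    def test_kmer_larger_than_reads_skipped_in_pool(self):
        rng = np.random.default_rng(203)
        reads = tile_reads(rand_seq(rng, 300), read_len=60, step=3)
        contigs = assemble_pooled(reads, kmers=(41, 61, 81))
        assert contigs and all(c.kmer == 41 for c in contigs)

    def test_contig_invariant(self):
        with pytest.raises(ValueError):
            Contig("ACGT", kmer=41, mean_kmer_coverage=2.0)


class TestPlantedInsertionRecovery:
    def test_full_recovery_rate(self):
        """Planted 100-400 bp insertions (unique flanks) are recovered as
        fully assembled calls with the exact size in >= 90% of 50 seeded
        fixtures."""
        rng = np.random.default_rng(777)
        successes = 0
        n_fixtures = 50
        for _ in range(n_fixtures):
            window = rand_seq(rng, 2400)
            size = int(rng.integers(100, 401))
            ins = rand_seq(rng, size)
            donor = window[:1200] + ins + window[1200:]
            reads = tile_reads(donor, read_len=150, step=8)
            contigs = assemble_pooled(reads)
            cand = BreakpointCandidate("chr1", 1200, support=5)
            alns = []
            for i, c in enumerate(contigs):
                aln = builtin_spliced_align(
                    f"contig_{i}", c.seq, window, 0, "chr1"
                )
                if aln is not None:
                    alns.append(aln)
            call = call_from_contigs(alns, cand)
            if (
                call is not None
                and call.evidence == "ASSEMBLY_FULL"
                and call.size == size
            ):
                successes += 1
        assert successes >= 0.9 * n_fixtures


def _contig_aln(cigar: str, pos: int = 900):
    return SplicedAlignment(
        query_name="contig",
        chrom="chr1",
        pos=pos,
        mapq=60,
        cigar=parse_cigar(cigar),
    )


class TestCallFromContigs:
    CAND = BreakpointCandidate("chr1", 1200, support=4)

    def test_full_insertion_near_breakpoint(self):
        call = call_from_contigs([_contig_aln("300M120I280M")], self.CAND)
        assert call is not None and call.evidence == "ASSEMBLY_FULL"
        assert call.size == 120 and call.pos == 1200

    def test_partial_insertion_from_clip(self):
        call = call_from_contigs([_contig_aln("400M80S", pos=800)], self.CAND)
        assert call is not None and call.evidence == "ASSEMBLY_PARTIAL"
        assert call.size is None and call.pos == 1200

    def test_full_preferred_over_partial(self):
        alns = [_contig_aln("400M80S", pos=800), _contig_aln("300M120I280M")]
        call = call_from_contigs(alns, self.CAND)
        assert call.evidence == "ASSEMBLY_FULL"

    def test_matching_contig_gives_nothing(self):
        assert call_from_contigs([_contig_aln("600M")], self.CAND) is None

    def test_distance_bound_respected(self):
        # I op at 900 + 500 = 1400? no: 300M then I at 1200... use far contig
        far = _contig_aln("300M120I280M", pos=2000)  # I at 2300, 1100 bp away
        assert call_from_contigs([far], self.CAND) is None

    def test_never_reports_beyond_200bp(self):
        for pos in (0, 500, 880, 1500, 3000):
            call = call_from_contigs(
                [_contig_aln("300M120I280M", pos=pos)], self.CAND
            )
            if call is not None:
                assert abs(call.pos - self.CAND.pos) <= 200


class TestCollectAssemblyReads:
    @pytest.fixture()
    def bam(self, tmp_path):
        seq = "ACGT" * 37 + "AC"  # 150 bp
        flags_paired = 0x1 | 0x2 | 0x20  # paired, proper, mate reverse
        records = [
            # clipped read inside window, proper pair -> selected
            {
                "name": "clipped",
                "pos": 5000,
                "cigar": "100M50S",
                "seq": seq,
                "flag": 0x1 | 0x2 | 0x20 | 0x40,
                "mtid": 0,
                "mpos": 5300,
            },
            # its mate, outside window -> fetched via mate lookup
            {
                "name": "clipped",
                "pos": 5300,
                "cigar": "150M",
                "seq": seq,
                "flag": 0x1 | 0x2 | 0x10 | 0x80,
                "mtid": 0,
                "mpos": 5000,
            },
            # clean proper pair -> not selected
            {
                "name": "clean",
                "pos": 5050,
                "cigar": "150M",
                "seq": seq,
                "flag": flags_paired | 0x40,
                "mtid": 0,
                "mpos": 5400,
            },
            # improper pair, low mapq -> not selected
            {
                "name": "lowq",
                "pos": 5080,
                "cigar": "150M",
                "seq": seq,
                "flag": 0x1 | 0x40,
                "mapq": 10,
                "mtid": 0,
                "mpos": 5200,
            },
            # improper pair, decent mapq -> selected
            {
                "name": "improper",
                "pos": 5100,
                "cigar": "150M",
                "seq": seq,
                "flag": 0x1 | 0x40,
                "mapq": 40,
                "mtid": 0,
                "mpos": 5200,
            },
            {
                "name": "improper",
                "pos": 5200,
                "cigar": "150M",
                "seq": seq,
                "flag": 0x1 | 0x80,
                "mapq": 40,
                "mtid": 0,
                "mpos": 5100,
            },
        ]
        return build_bam(tmp_path / "asm.bam", records, {"chr1": 20_000})

    def test_selection_rules(self, bam):
        cand = BreakpointCandidate("chr1", 5100, support=4)
        job = collect_assembly_reads(bam, cand, window=1200)
        names = sorted({name for name, _s, _q in job.reads})
        assert "clipped" in names and "improper" in names
        assert "clean" not in names and "lowq" not in names

    def test_mates_included(self, bam):
        cand = BreakpointCandidate("chr1", 5100, support=4)
        job = collect_assembly_reads(bam, cand, window=1200)
        clipped = [r for r in job.reads if r[0] == "clipped"]
        improper = [r for r in job.reads if r[0] == "improper"]
        assert len(clipped) == 2 and len(improper) == 2

    def test_empty_window(self, bam):
        cand = BreakpointCandidate("chr1", 15_000, support=4)
        assert collect_assembly_reads(bam, cand).reads == []
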