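"""sv_simulator: genotype assignment, SV spiking, random inversions and
translocations, and the paired-end read simulator."""

from __future__ import annotations

import math

import numpy as np
import pytest

from clipcall.sv_simulator import (
    TruthEvent,
    apply_truth,
    assign_genotypes,
    generate_events,
    random_reference,
    revcomp,
    simulate_inversions,
    simulate_reads,
    simulate_translocations,
    spike_svs,
)


class TestAssignGenotypes:
    def test_all_three_genotypes_reachable(self):
        rng = np.random.default_rng(0)
        gts = set(assign_genotypes(300, rng))
        assert gts == {"1|1", "0|1", "1|0"}

    def test_hom_het_ratio_half(self):
        # hom:het is 1:2 in expectation; check a 3-sigma Monte-Carlo band
        rng = np.random.default_rng(1)
        n = 12_000
        gts = assign_genotypes(n, rng)
        hom = sum(1 for g in gts if g == "1|1")
        het = n - hom
        ratio = hom / het
        p = 1 / 3
        sd_hom = math.sqrt(n * p * (1 - p))
        lo = (n * p - 3 * sd_hom) / (n - (n * p - 3 * sd_hom))
        hi = (n * p + 3 * sd_hom) / (n - (n * p + 3 * sd_hom))
        assert lo <= ratio <= hi
        assert abs(ratio - 0.5) < 0.05

    def test_deterministic_for_seed(self):
        a = assign_genotypes(100, np.random.default_rng(42))
        b = assign_genotypes(100, np.random.default_rng(42))
        assert a == b

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            assign_genotypes(0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def toy_reference():
    return random_reference(1, 100_000, np.random.default_rng(9))


class TestSpikeSvs:
    def test_homozygous_deletion_shortens_both(self, toy_reference):
        ev = TruthEvent("DEL", "chr1", 50_000, 500, "1|1")
        genome = spike_svs(toy_reference, [ev])
        assert len(genome.hap1["chr1"]) == 99_500
        assert len(genome.hap2["chr1"]) == 99_500
        assert len(genome.truth) == 1

    def test_het_insertion_affects_one_haplotype(self, toy_reference):
        ins = "ACGT" * 50
        ev = TruthEvent("INS", "chr1", 30_000, 200, "0|1", seq=ins)
        genome = spike_svs(toy_reference, [ev])
        assert genome.hap1["chr1"] == toy_reference["chr1"]
        assert len(genome.hap2["chr1"]) == 100_200
        assert genome.hap2["chr1"][30_000:30_200] == ins

    def test_inversion_is_reverse_complement(self, toy_reference):
        ev = TruthEvent("INV", "chr1", 40_000, 1000, "1|1")
        genome = spike_svs(toy_reference, [ev])
        ref_seg = toy_reference["chr1"][40_000:41_000]
        assert genome.hap1["chr1"][40_000:41_000] == revcomp(ref_seg)

    def test_overlapping_events_rejected(self, toy_reference):
        evs = [
            TruthEvent("DEL", "chr1", 50_000, 500, "1|1"),
            TruthEvent("DEL", "chr1", 50_200, 500, "1|1"),
        ]
        with pytest.raises(ValueError):
            spike_svs(toy_reference, evs)

    def test_event_beyond_end_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            spike_svs(
                toy_reference, [TruthEvent("DEL", "chr1", 99_900, 500, "1|1")]
            )

    def test_truth_application_oracle(self, toy_reference):
        """Independently re-applying truth to the reference reproduces the
        stored haplotypes byte for byte."""
        rng = np.random.default_rng(10)
        events = generate_events(toy_reference, rng, n_del=5, n_ins=5)
        genome = spike_svs(toy_reference, events)
        assert apply_truth(toy_reference, genome.truth, 1) == genome.hap1
        assert apply_truth(toy_reference, genome.truth, 2) == genome.hap2


class TestSimulateInversions:
    def test_exact_count_and_length_range(self):
        rng = np.random.default_rng(11)
        ref = random_reference(20, 200_000, rng)
        genome = spike_svs(ref, [])
        simulate_inversions(genome, rng, n=200)
        invs = [e for e in genome.truth if e.svtype == "INV"]
        assert len(invs) == 200
        assert all(50 <= e.size <= 10_000 for e in invs)

    def test_zero_leaves_truth_unchanged(self, toy_reference):
        genome = spike_svs(toy_reference, [])
        simulate_inversions(genome, np.random.default_rng(0), n=0)
        assert genome.truth == []

    def test_min_gap_respected(self):
        rng = np.random.default_rng(12)
        ref = random_reference(2, 300_000, rng)
        genome = spike_svs(ref, [])
        simulate_inversions(genome, rng, n=30, len_range=(50, 2000))
        by_chrom: dict[str, list] = {}
        for e in genome.truth:
            by_chrom.setdefault(e.chrom, []).append(e)
        for evs in by_chrom.values():
            evs.sort(key=lambda e: e.pos)
            for a, b in zip(evs, evs[1:]):
                assert a.pos + a.size + 1000 <= b.pos


class TestSimulateTranslocations:
    def test_default_breakpoint_counts(self):
        rng = np.random.default_rng(13)
        ref = random_reference(20, 10_000, rng)
        genome = spike_svs(ref, [])
        simulate_translocations(genome, rng)
        tra = [e for e in genome.truth if e.svtype == "TRA"]
        hap1 = [e for e in tra if e.on_hap(1)]
        hap2 = [e for e in tra if e.on_hap(2)]
        assert len(hap1) == 60 and len(hap2) == 60
        assert len(tra) == 120
        assert all(e.genotype in ("1|0", "0|1") for e in tra)

    def test_total_length_conserved(self):
        rng = np.random.default_rng(14)
        ref = random_reference(20, 10_000, rng)
        genome = spike_svs(ref, [])
        simulate_translocations(genome, rng, pairs_per_hap=10, events_per_pair=1)
        for hap in (genome.hap1, genome.hap2):
            assert sum(map(len, hap.values())) == sum(map(len, ref.values()))

    def test_seed_determinism(self):
        ref = random_reference(20, 10_000, np.random.default_rng(15))
        g1 = spike_svs(ref, [])
        simulate_translocations(g1, np.random.default_rng(16))
        g2 = spike_svs(ref, [])
        simulate_translocations(g2, np.random.default_rng(16))
        assert g1.hap1 == g2.hap1 and g1.hap2 == g2.hap2

    def test_too_few_chromosomes_rejected(self):
        ref = random_reference(4, 10_000, np.random.default_rng(17))
        genome = spike_svs(ref, [])
        with pytest.raises(ValueError):
            simulate_translocations(genome, np.random.default_rng(18))


class TestSimulateReads:
    def test_coverage_bookkeeping(self, toy_reference, tmp_path):
        genome = spike_svs(toy_reference, [])
        rng = np.random.default_rng(19)
        n = simulate_reads(
            genome, tmp_path / "r1.fq", tmp_path / "r2.fq", rng,
            coverage_per_hap=15.0,
        )
        total_bases = n * 2 * 150
        expected = 30 * 100_000
        assert abs(total_bases - expected) / expected < 0.05

    def test_error_free_reads_are_haplotype_substrings(self, toy_reference, tmp_path):
        genome = spike_svs(toy_reference, [])
        rng = np.random.default_rng(20)
        simulate_reads(
            genome, tmp_path / "r1.fq", tmp_path / "r2.fq", rng,
            coverage_per_hap=0.5, error_rate=0.0,
        )
        hap = genome.hap1["chr1"]
        lines1 = (tmp_path / "r1.fq").read_text().splitlines()
        lines2 = (tmp_path / "r2.fq").read_text().splitlines()
        for i in range(1, min(len(lines1), 80), 4):
            assert lines1[i] in hap
            assert revcomp(lines2[i]) in hap

    def test_byte_identical_for_seed(self, toy_reference, tmp_path):
        genome = spike_svs(toy_reference, [])
        for tag in ("a", "b"):
            simulate_reads(
                genome,
                tmp_path / f"r1_{tag}.fq",
                tmp_path / f"r2_{tag}.fq",
                np.random.default_rng(21),
                coverage_per_hap=1.0,
            )
        assert (tmp_path / "r1_a.fq").read_bytes() == (tmp_path / "r1_b.fq").read_bytes()
        assert (tmp_path / "r2_a.fq").read_bytes() == (tmp_path / "r2_b.fq").read_bytes()

    def test_read_length_must_fit_insert(self, toy_reference, tmp_path):
        genome = spike_svs(toy_reference, [])
        with pytest.raises(ValueError):
            simulate_reads(
                genome, tmp_path / "a.fq", tmp_path / "b.fq",
                np.random.default_rng(0), read_len=600, insert_mean=500.0,
            )
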