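"""evaluation: metrics arithmetic, window matching, the bipartite oracle,
long-read truth extraction and signal capture."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, strategies as st

from clipcall.alignment_io import InsertSizeStats
from clipcall.evaluation import (
    longread_truth,
    match_calls,
    metrics,
    signal_capture,
)
from clipcall.svcall import SVCall
from tests.conftest import build_bam, make_read


class TestMetrics:
    def test_formulas(self):
        res = metrics(tp=10, fp=5, fn=10)
        assert res.sensitivity == 0.5
        assert res.precision == pytest.approx(10 / 15)
        s, p = res.sensitivity, res.precision
        assert res.f1 == pytest.approx(2 * s * p / (s + p))

    def test_published_rates_worked_example(self):
        # sensitivity 81.9%, precision 98.9% -> F1 rounds to 0.90
        tp = 819
        res = metrics(tp=tp, fp=round(tp / 0.989) - tp, fn=1000 - tp)
        assert res.sensitivity == pytest.approx(0.819, abs=1e-3)
        assert res.precision == pytest.approx(0.989, abs=1e-3)
        assert round(res.f1, 2) == 0.90

    def test_zero_tp(self):
        res = metrics(tp=0, fp=0, fn=10)
        assert (res.sensitivity, res.precision, res.f1) == (0.0, 0.0, 0.0)

    def test_half_sensitivity_perfect_precision(self):
        res = metrics(tp=7, fp=0, fn=7)
        assert res.sensitivity == 0.5 and res.precision == 1.0
        assert res.f1 == pytest.approx(2 / 3)

    def test_no_truth_is_error(self):
        with pytest.raises(ValueError):
            metrics(tp=0, fp=3, fn=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(tp=-1, fp=0, fn=1)


def _del(pos, size, chrom="chr1"):
    return SVCall("DEL", chrom, pos, size=size)


class TestMatchRules:
    def test_window_and_size_rule(self):
        truth = [_del(1000, 500)]
        res, _, _ = match_calls([_del(1100, 480)], truth, "DEL")
        assert res.tp == 1  # shift 100 <= 200, size diff 4% < 50%

    def test_size_difference_rejects(self):
        truth = [_del(1000, 500)]
        res, _, _ = match_calls([_del(1000, 240)], truth, "DEL")
        assert res.tp == 0 and res.fp == 1  # 52% >= 50%

    def test_window_rejects(self):
        truth = [_del(1000, 500)]
        res, _, _ = match_calls([_del(1250, 500)], truth, "DEL")
        assert res.tp == 0

    def test_sizeless_insertion_matches_on_window_alone(self):
        truth = [SVCall("INS", "chr1", 5000, size=300)]
        call = SVCall("INS", "chr1", 5120, size=None)
        res, _, _ = match_calls([call], truth, "INS")
        assert res.tp == 1

    def test_translocation_matches_either_breakend(self):
        truth = [SVCall("TRA", "chr2", 900, chrom2="chr5", pos2=7000)]
        call = SVCall("TRA", "chr5", 7100, chrom2="chr9", pos2=1)
        res, _, _ = match_calls([call], truth, "TRA")
        assert res.tp == 1

    def test_mixed_svtypes_rejected(self):
        with pytest.raises(ValueError):
            match_calls([_del(1, 100)], [SVCall("INS", "chr1", 1, size=60)], "DEL")

    def test_identity_is_perfect(self):
        calls = [_del(1000, 500), _del(9000, 120), _del(40_000, 3000)]
        res, _, _ = match_calls(calls, calls, "DEL")
        assert res.sensitivity == 1.0 and res.precision == 1.0

    def test_greedy_trap_instance_still_optimal(self):
        """A size-less call sitting nearest a truth event must not steal it
        from the only call that can match it."""
        truth = [
            SVCall("INS", "chr1", 0, size=100),
            SVCall("INS", "chr1", 150, size=500),
        ]
        calls = [
            SVCall("INS", "chr1", 149, size=None),  # nearest to truth[1]
            SVCall("INS", "chr1", 140, size=450),  # only compatible with truth[1]
        ]
        res, _, _ = match_calls(calls, truth, "INS")
        assert res.tp == 2


def _brute_force_max_matching(compat: list[list[bool]]) -> int:
    """Exhaustive maximum bipartite matching cardinality (<= 8x8)."""
    n_calls = len(compat)
    n_truth = len(compat[0]) if compat else 0
    best = 0
    for k in range(min(n_calls, n_truth), 0, -1):
        for call_subset in itertools.combinations(range(n_calls), k):
            for truth_perm in itertools.permutations(range(n_truth), k):
                if all(
                    compat[c][t] for c, t in zip(call_subset, truth_perm)
                ):
                    return k
    return best


@st.composite
def _small_instance(draw):
    n_calls = draw(st.integers(0, 6))
    n_truth = draw(st.integers(1, 6))
    pos = st.integers(0, 2000)
    size = st.integers(50, 1000)
    calls = [
        _del(draw(pos), draw(size)) for _ in range(n_calls)
    ]
    truth = [_del(draw(pos), draw(size)) for _ in range(n_truth)]
    return calls, truth


class TestBipartiteOracle:
    @given(_small_instance())
    def test_tp_equals_maximum_matching(self, instance):
        calls, truth = instance
        res, call_hit, truth_hit = match_calls(calls, truth, "DEL")
        compat = [
            [
                abs(c.pos - t.pos) <= 200
                and abs(c.size - t.size) < 0.5 * t.size
                for t in truth
            ]
            for c in calls
        ]
        assert res.tp == _brute_force_max_matching(compat)
        # one-to-one: labels agree with counts
        assert sum(call_hit) == res.tp == sum(truth_hit)


class TestLongreadTruth:
    def _long_read(self, name, pos, cigar, qlen):
        seq = "ACGT" * (qlen // 4 + 1)
        return {
            "name": name,
            "pos": pos,
            "cigar": cigar,
            "seq": seq[:qlen],
            "mapq": 60,
        }

    def test_three_reads_make_truth(self, tmp_path):
        records = [
            self._long_read(f"ccs{i}", 1000, "500M60I500M", 1060)
            for i in range(3)
        ]
        bam = build_bam(tmp_path / "lr.bam", records, {"chr1": 50_000})
        (ev,) = longread_truth(bam, min_support=3)
        assert (ev.svtype, ev.pos, ev.size) == ("INS", 1500, 60)

    def test_two_reads_insufficient(self, tmp_path):
        records = [
            self._long_read(f"ccs{i}", 1000, "500M60I500M", 1060)
            for i in range(2)
        ]
        bam = build_bam(tmp_path / "lr2.bam", records, {"chr1": 50_000})
        assert longread_truth(bam, min_support=3) == []

    def test_deletion_from_cigar(self, tmp_path):
        records = [
            self._long_read(f"ccs{i}", 2000, "800M400D800M", 1600)
            for i in range(3)
        ]
        bam = build_bam(tmp_path / "lr3.bam", records, {"chr1": 50_000})
        (ev,) = longread_truth(bam, min_support=3)
        assert (ev.svtype, ev.pos, ev.size) == ("DEL", 2800, 400)

    def test_split_alignment_large_deletion(self, tmp_path):
        # colinear split: [1000,2000) + [30000,31000) -> 28 kb deletion
        records = []
        for i in range(3):
            rec = self._long_read(f"ccs{i}", 1000, "1000M1000S", 2000)
            rec["tags"] = {"SA": f"chr1,30001,+,1000S1000M,60,0;"}
            records.append(rec)
        bam = build_bam(tmp_path / "lr4.bam", records, {"chr1": 100_000})
        (ev,) = longread_truth(bam, min_support=3)
        assert ev.svtype == "DEL" and ev.pos == 2000
        assert ev.size == 28_000


class TestSignalCapture:
    STATS = InsertSizeStats(400.0, 50.0, 150, 30.0)

    def test_clipped_capture(self):
        truth = [SVCall("DEL", "chr1", 10_000, size=400)]
        reads = [
            make_read(name=f"c{i}", pos=9_900, cigar="100M50S")
            for i in range(3)
        ]
        assert signal_capture(reads, truth, "CLIPPED", self.STATS) == 1.0

    def test_single_read_not_confirmed(self):
        truth = [SVCall("DEL", "chr1", 10_000, size=400)]
        reads = [make_read(name="c", pos=9_900, cigar="100M50S")]
        assert signal_capture(reads, truth, "CLIPPED", self.STATS) == 0.0

    def test_discordant_six_hundred_window(self):
        truth = [SVCall("DEL", "chr1", 10_400, size=500)]
        # pair straddling the deletion: approximate sites 200 bp out from
        # the mapped reads still land within the 600 bp capture window
        reads = [
            make_read(
                name=f"d{i}", pos=9_850, cigar="150M", tlen=1100,
                mate_pos=10_800,
            )
            for i in range(2)
        ]
        assert signal_capture(reads, truth, "DISCORDANT", self.STATS) == 1.0

    def test_fraction_over_multiple_events(self):
        truth = [
            SVCall("DEL", "chr1", 10_000, size=400),
            SVCall("DEL", "chr1", 50_000, size=400),
        ]
        reads = [
            make_read(name=f"c{i}", pos=9_900, cigar="100M50S")
            for i in range(2)
        ]
        assert signal_capture(reads, truth, "CLIPPED", self.STATS) == 0.5
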