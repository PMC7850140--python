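"""Reconstruct long sequences by concatenating clipped reads head-to-tail.

An MS read (3' end clipped) reaching into an SV junction and an SM read
(5' end clipped) leaving it share an overlap: the last n bases of the MS
read equal the first n bases of the SM read.  Joining the two across the
largest such overlap yields a pseudo-long read spanning the junction,
which spliced alignment can then resolve where the raw 100-250 bp reads
cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from clipcall.config import CallerConfig, DEFAULT_CONFIG
from clipcall.signal_scan import ClippedRead


@dataclass(frozen=True)
class ExtensionJoin:
    """A successful head-to-tail join of one MS and one SM clipped read."""

    ms: ClippedRead
    sm: ClippedRead
    n: int
    shift_used: int
    sequence: str

    @property
    def name(self) -> str:
        ms_mate = "1" if self.ms.read.read1 else "2"
        sm_mate = "1" if self.sm.read.read1 else "2"
        return (
            f"{self.ms.read.name}/{ms_mate}|{self.sm.read.name}/{sm_mate}"
            f"|n={self.n}"
        )

    @property
    def anchor(self) -> int:
        """Reference coordinate anchoring the join (MS breakpoint)."""
        return self.ms.bp


def _boundary_match(a: str, b: str, shift: int) -> Optional[int]:
    """Equality of two same-length strings excusing up to ``shift`` bases at
    each terminus.  Returns the largest boundary depth at which a mismatch
    occurred (0 if none), or None when a mismatch lies in the interior."""
    n = len(a)
    if n <= 2 * shift:
        return 0 if a == b else None
    if a[shift : n - shift] != b[shift : n - shift]:
        return None
    used = 0
    for i in range(shift):
        if a[i] != b[i]:
            used = max(used, i + 1)
        if a[n - 1 - i] != b[n - 1 - i]:
            used = max(used, i + 1)
    return used


def _near_periodic(s: str, max_period: int = 25, tol_frac: float = 0.1) -> bool:
    """Whether ``s`` is (nearly) tandem-periodic with period <= ``max_period``.

    Shifted self-comparison tolerates a mismatch fraction so sequencing
    errors cannot mask the periodicity; a non-periodic sequence mismatches
    itself at ~75% of shifted positions, leaving a wide margin.
    """
    for p in range(1, min(max_period + 1, len(s))):
        m = len(s) - p
        budget = max(1, int(tol_frac * m))
        mismatches = 0
        for a, b in zip(s[p:], s[:-p]):
            if a != b:
                mismatches += 1
                if mismatches > budget:
                    break
        else:
            return True
    return False


def join_pair(
    sm: ClippedRead,
    ms: ClippedRead,
    read_length: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> Optional[ExtensionJoin]:
    """Join one SM and one MS clipped read over their longest shared overlap.

    Compares the first n bases of the SM read with the last n bases of the
    MS read, starting at n = read_length - 30 and decreasing; the first
    (largest) n strictly above ``min_overlap_n`` with an interior-exact
    match wins.  Up to ``boundary_shift`` bases at each end of the compared
    substrings are excused (clip-boundary sequencing errors).  Inside the
    overlap the MS read's bases are kept.
    """
    ms_seq = ms.read.seq
    sm_seq = sm.read.seq
    if not ms_seq or not sm_seq:
        return None
    if read_length - 30 <= config.min_overlap_n:
        return None
    top = min(read_length - 30, len(ms_seq), len(sm_seq))
    for n in range(top, config.min_overlap_n, -1):
        used = _boundary_match(ms_seq[-n:], sm_seq[:n], config.boundary_shift)
        if used is not None:
            # periodicity guard: a tandem-periodic overlap pins the join
            # offset only up to a multiple of the period, and a wrong offset
            # silently mis-sizes the SV -- leave such pairs to local assembly
            if _near_periodic(ms_seq[-n:]) or _near_periodic(sm_seq[:n]):
                return None
            return ExtensionJoin(
                ms=ms,
                sm=sm,
                n=n,
                shift_used=used,
                sequence=ms_seq + sm_seq[n:],
            )
    return None


def bin_clipped_reads(
    clips: Iterable[ClippedRead],
    bin_width: int = 1000,
) -> list[tuple[ClippedRead, list[ClippedRead]]]:
    """Pair every SM clipped read with the MS reads within ``bin_width`` bp.

    Hard-clipped reads (no clipped sequence) carry no bases to overlap and
    are excluded.  Returns ``(sm, [candidate ms partners])`` with partners
    sorted by breakpoint.
    """
    usable = [c for c in clips if c.clipped_seq]
    ms_reads = sorted(
        (c for c in usable if c.side == "MS"), key=lambda c: c.bp
    )
    out: list[tuple[ClippedRead, list[ClippedRead]]] = []
    import bisect

    bps = [c.bp for c in ms_reads]
    for sm in (c for c in usable if c.side == "SM"):
        lo = bisect.bisect_left(bps, sm.bp - bin_width)
        hi = bisect.bisect_right(bps, sm.bp + bin_width)
        out.append((sm, ms_reads[lo:hi]))
    return out


def extend_bin(
    groups: Iterable[tuple[ClippedRead, list[ClippedRead]]],
    read_length: int,
    config: CallerConfig = DEFAULT_CONFIG,
) -> list[ExtensionJoin]:
    """Produce at most one join per SM read: the partner giving the largest
    overlap n, ties broken toward the leftmost partner breakpoint."""
    joins: list[ExtensionJoin] = []
    for sm, partners in groups:
        best: Optional[ExtensionJoin] = None
        for ms in sorted(partners, key=lambda c: c.bp):
            j = join_pair(sm, ms, read_length, config)
            if j is not None and (best is None or j.n > best.n):
                best = j
        if best is not None:
            joins.append(best)
    return joins


def extension_fasta(joins: Iterable[ExtensionJoin]) -> list[tuple[str, str]]:
    """FASTA records (id encodes source read names and n) for the joins."""
    return [(j.name, j.sequence) for j in joins]
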