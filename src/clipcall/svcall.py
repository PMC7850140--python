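"""Typed structural-variant calls shared by every calling module."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


#: evidence classes a call can carry (the node or signal that resolved it)
EVIDENCE_CLASSES = (
    "CIGAR",
    "SPLICED",
    "ASSEMBLY_FULL",
    "ASSEMBLY_PARTIAL",
    "COMPLEX",
    "SPLIT",
    "PAIR",
)


@dataclass
class SVCall:
    """One called structural variant.

    ``pos`` is 0-based internally; conversion to 1-based happens only when
    writing VCF.  ``size`` is ``None`` for imprecise calls (partially
    assembled or complex-alignment insertions).  For translocations the
    partner breakend lives in ``chrom2``/``pos2``.
    """

    svtype: str  # DEL | INS | INV | TRA
    chrom: str
    pos: int
    size: Optional[int] = None
    support: int = 0
    evidence: str = "SPLICED"
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    inserted_seq: Optional[str] = None
    genotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS", "INV", "TRA"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.size is not None and self.size < 1:
            raise ValueError("size must be >= 1 when known")

    @property
    def end(self) -> int:
        """0-based exclusive end of the affected reference interval."""
        if self.svtype in ("DEL", "INV") and self.size is not None:
            return self.pos + self.size
        return self.pos + 1

    @property
    def imprecise(self) -> bool:
        return self.size is None

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.svtype, self.size or 0)
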