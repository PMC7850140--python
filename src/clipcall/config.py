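"""Caller configuration: every numeric threshold the pipeline uses."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds and window sizes of the calling pipeline.

    Attributes
    ----------
    min_clip : int
        A clip must be strictly longer than this (bp) to count as signal.
    support_frac : float
        Fraction of the sequencing coverage defining the support threshold
        ``X = max(2, ceil(support_frac * coverage))``.
    discordant_pad : int
        Additive cap (bp) in the discordant-pair insert-size test
        ``|TLEN| > min(mean + sd, mean + discordant_pad)``.
    bin_width : int
        Maximum breakpoint distance (bp) between an SM and an MS clipped
        read considered for head-to-tail extension.
    min_overlap_n : int
        Extension joins require an overlap strictly longer than this (bp).
    boundary_shift : int
        Bases at each end of the compared overlap substrings excused from
        exact matching (sequencing errors concentrate at clip boundaries).
    assembly_window : int
        Width (bp) of the read-collection window for local assembly,
        centered on the candidate breakpoint.
    kmers : tuple[int, ...]
        k-mer sizes for local de Bruijn assembly; contigs are pooled.
    complex_mapq : int
        Minimum mapping quality of a clipped read counted by the
        complex-alignment rescue node.
    complex_hq_ratio : float
        Minimum high-quality-base ratio of the mapped region for the
        complex-alignment rescue node.
    tra_mapq : int
        Both split-read segments of a translocation must exceed this
        mapping quality.
    min_mapq : int
        Clipped reads below this mapping quality are excluded from
        extension and candidate collection.
    min_sv : int
        Size boundary (bp) between indels and structural variants.
    chunk_width : int
        Genome chunk width (bp) for per-region processing.
    spliced_window : int
        Half-width (bp) of the reference window the builtin spliced
        aligner searches around a query's anchor.
    merge_pos_tol : int
        Evidence within this many bp merges into one call.
    merge_size_frac : float
        Evidence sizes within this relative fraction merge into one call.
    exclusion_radius : int
        Insertion candidates within this distance (bp) of a DEL/INV/TRA
        call are suppressed by the rescue node.
    """

    min_clip: int = 5
    support_frac: float = 0.10
    discordant_pad: int = 300
    bin_width: int = 1000
    min_overlap_n: int = 30
    boundary_shift: int = 3
    assembly_window: int = 1200
    kmers: tuple[int, ...] = (41, 61, 81)
    complex_mapq: int = 50
    complex_hq_ratio: float = 0.8
    tra_mapq: int = 20
    min_mapq: int = 20
    min_sv: int = 50
    chunk_width: int = 1_000_000
    spliced_window: int = 50_000
    merge_pos_tol: int = 10
    merge_size_frac: float = 0.20
    exclusion_radius: int = 200

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "kmers":
                if not v or any(k <= 0 for k in v):
                    raise ValueError("kmers must be positive")
            elif isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if not (0.0 < self.support_frac <= 1.0):
            raise ValueError("support_frac must be in (0, 1]")


DEFAULT_CONFIG = CallerConfig()
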