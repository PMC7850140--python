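"""Convenience wrapper around bwa mem + samtools for producing the
coordinate-sorted, indexed BAMs the caller consumes.

Alignment itself is upstream of the caller; this wrapper only exists so
simulated reads can be turned into caller input in one call.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from pathlib import Path

log = logging.getLogger(__name__)


def _require(tool: str) -> None:
    if shutil.which(tool) is None:
        raise RuntimeError(f"{tool} not found on PATH")


def bwa_index(reference: str | Path) -> None:
    reference = Path(reference)
    _require("bwa")
    if not (reference.with_suffix(reference.suffix + ".bwt")).exists():
        subprocess.run(
            ["bwa", "index", str(reference)],
            check=True,
            capture_output=True,
        )


def align_reads(
    reference: str | Path,
    fq1: str | Path,
    fq2: str | Path,
    out_bam: str | Path,
    threads: int = 1,
) -> Path:
    """bwa mem -> sorted, indexed BAM at ``out_bam``."""
    _require("bwa")
    _require("samtools")
    out_bam = Path(out_bam)
    bwa_index(reference)
    mem = subprocess.Popen(
        [
            "bwa",
            "mem",
            "-t",
            str(threads),
            "-R",
            r"@RG\tID:sim\tSM:sim",
            str(reference),
            str(fq1),
            str(fq2),
        ],
        stdout=subprocess.PIPE,
        stderr=subprocess.DEVNULL,
    )
    sort = subprocess.run(
        ["samtools", "sort", "-@", str(threads), "-o", str(out_bam), "-"],
        stdin=mem.stdout,
        check=True,
        capture_output=True,
    )
    if mem.stdout is not None:
        mem.stdout.close()
    if mem.wait() != 0:
        raise RuntimeError("bwa mem failed")
    subprocess.run(
        ["samtools", "index", str(out_bam)], check=True, capture_output=True
    )
    return out_bam
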