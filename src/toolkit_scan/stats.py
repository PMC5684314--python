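"""Assembly summary statistics: total size, contig count, N50."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .orf import Contig


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    n_contigs: int
    n50: int | None  # None for an empty assembly


def n50(lengths: Sequence[int]) -> int:
    """Shortest length among the longest contigs that cover half the bases.

    Sort descending and return the first length at which the cumulative sum
    reaches at least half of the total (">= half" at the boundary).
    """
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def transcriptome_stats(assembly: Iterable[Contig]) -> AssemblyStats:
    lengths = [len(c) for c in assembly]
    if not lengths:
        return AssemblyStats(0, 0, None)
    return AssemblyStats(sum(lengths), len(lengths), n50(lengths))
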