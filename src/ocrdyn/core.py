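"""Core genomic value types shared across the package.

All coordinates are 0-based, half-open ``[start, end)``. No operation in
this package accepts 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval: start={self.start} >= end={self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp overlap on the same chromosome (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    The TSS is ``interval.start`` on the + strand and ``interval.end - 1``
    on the − strand.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs a +/- strand")

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    def promoter_window(self, upstream: int, downstream: int) -> GenomicInterval:
        """Strand-aware window around the TSS: ``[TSS - upstream,
        TSS + downstream)`` on +, ``[TSS - downstream, TSS + upstream)``
        on −. Clipped at 0."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.interval.chrom, max(0, lo), max(1, hi))


class CoverageTrack:
    """Per-chromosome base-resolution insertion counts for one stage."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays: Dict[str, np.ndarray] = {}
        for chrom, arr in arrays.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"coverage for {chrom} must be 1-D")
            if (a < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.arrays[chrom] = a

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.arrays.items()}

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Coverage values over ``[start, end)``; out-of-bounds raises."""
        arr = self.arrays[chrom]
        if start < 0 or end > len(arr):
            raise IndexError(
                f"[{start},{end}) outside {chrom} (length {len(arr)})"
            )
        return arr[start:end]

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.slice(chrom, start, end).mean())

    def total(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))


@dataclass
class Peak:
    """An open-chromatin region with per-sample read counts and per-stage
    call status."""

    peak_id: str
    interval: GenomicInterval
    raw_counts: Dict[str, int] = field(default_factory=dict)
    called_in: frozenset = frozenset()

    def __post_init__(self) -> None:
        for sample, c in self.raw_counts.items():
            if c < 0:
                raise ValueError(f"negative count for {self.peak_id}/{sample}")
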