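"""Genomic interval types and arithmetic (1-based, inclusive endpoints).

Internally every coordinate in the package is 1-based inclusive (the VCF
convention); BED output converts to 0-based half-open at the file boundary
(see :mod:`famburden.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    meta: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def intersect_many(groups: Sequence[Sequence[GenomicRegion]]) -> List[GenomicRegion]:
    """Intersection of several region sets (each set internally a union)."""
    if not groups:
        return []
    current = _normalize(groups[0])
    for regs in groups[1:]:
        nxt: List[GenomicRegion] = []
        for a in current:
            for b in _normalize(regs):
                if a.overlaps(b):
                    nxt.append(
                        GenomicRegion(a.chrom, max(a.start, b.start), min(a.end, b.end))
                    )
        current = _normalize(nxt)
    return current


def subtract(
    regions: Sequence[GenomicRegion], cuts: Sequence[GenomicRegion]
) -> List[GenomicRegion]:
    """Remove every sub-interval of ``regions`` overlapped by ``cuts``."""
    out: List[GenomicRegion] = []
    for reg in _normalize(regions):
        pieces = [reg]
        for cut in cuts:
            nxt: List[GenomicRegion] = []
            for p in pieces:
                if not p.overlaps(cut):
                    nxt.append(p)
                    continue
                if p.start < cut.start:
                    nxt.append(GenomicRegion(p.chrom, p.start, cut.start - 1))
                if cut.end < p.end:
                    nxt.append(GenomicRegion(p.chrom, cut.end + 1, p.end))
            pieces = nxt
        out.extend(pieces)
    return _normalize(out)


def _normalize(regions: Sequence[GenomicRegion]) -> List[GenomicRegion]:
    """Sort and merge overlapping/adjacent same-chromosome regions."""
    by_chrom: Dict[str, List[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: List[GenomicRegion] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        regs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        merged: List[GenomicRegion] = []
        for r in regs:
            if merged and r.start <= merged[-1].end + 1:
                last = merged.pop()
                merged.append(
                    GenomicRegion(chrom, last.start, max(last.end, r.end))
                )
            else:
                merged.append(r)
        out.extend(merged)
    return out


def _chrom_key(c: str):
    s = str(c).removeprefix("chr")
    return (0, int(s)) if s.isdigit() else (1, s)


def reciprocal_overlap(a: GenomicRegion, b: GenomicRegion) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    if not a.overlaps(b):
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    return min(ov / a.length_bp, ov / b.length_bp)
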