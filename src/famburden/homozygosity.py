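"""Runs of homozygosity (ROH) and shared-exclusive candidate regions.

ROH are detected per sample as maximal runs of consecutive markers that
contain at most ``max_het`` heterozygous and ``max_missing`` missing calls
(all other calls homozygous), with homozygous markers at both run
boundaries and at least ``min_snps`` markers.  This per-segment allowance
rule is exactly specifiable (and has a brute-force all-subarrays oracle),
unlike sliding-window heuristics; its defaults approximate the common
window-based tool settings.

Candidate regions in a consanguineous family are the sub-intervals of the
genome homozygous in *every* affected member and in *no* retained
unaffected member (both readings of "shared exclusively by the affected"
enforced, each relaxable), longer than ``min_length_bp`` (strict, default
200 kb).  Unaffected members below the late-onset age threshold are
excluded before the exclusivity test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree, effective_status
from .regions import GenomicRegion, intersect_many, subtract, _normalize

logger = logging.getLogger(__name__)

__all__ = ["ROHParams", "ROHSegment", "detect_roh", "detect_roh_matrix",
           "shared_affected_roh"]


@dataclass
class ROHParams:
    min_snps: int = 25
    max_het: int = 1
    max_missing: int = 5


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het_used: int
    n_missing_used: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start_bp, self.end_bp)


def detect_roh(
    calls: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    sample_id: str = "",
    params: Optional[ROHParams] = None,
) -> List[ROHSegment]:
    """Maximal homozygous runs for one sample on one chromosome.

    ``calls`` are dosages in {0,1,2} with -1 missing, position-sorted.
    Overlapping maximal runs can both be emitted (a run of homozygotes
    broken by two heterozygotes under ``max_het=1`` yields one run ending
    before the second het and one starting after the first).
    """
    p = params or ROHParams()
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    if calls.shape != positions.shape:
        raise ValueError("calls and positions must align")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    n = calls.size
    is_het = calls == 1
    is_miss = calls == MISSING
    is_hom = ~is_het & ~is_miss

    # two-pointer: for each left index, the furthest right index keeping
    # within the het/missing allowances (monotone in left)
    segments: List[ROHSegment] = []
    seen = set()
    het_c = np.concatenate([[0], np.cumsum(is_het)])
    miss_c = np.concatenate([[0], np.cumsum(is_miss)])

    def ok(i: int, j: int) -> bool:
        return (
            het_c[j + 1] - het_c[i] <= p.max_het
            and miss_c[j + 1] - miss_c[i] <= p.max_missing
        )

    j = -1
    prev_j = -1
    for i in range(n):
        if not is_hom[i]:
            continue
        if j < i:
            j = i
        while j + 1 < n and ok(i, j + 1):
            j += 1
        # trim the right end down to a homozygous marker
        j_trim = j
        while j_trim >= i and not is_hom[j_trim]:
            j_trim -= 1
        if j_trim < i:
            continue
        if j_trim <= prev_j:
            continue  # contained in the previous emitted run
        n_snps = j_trim - i + 1
        if n_snps < p.min_snps:
            continue
        key = (i, j_trim)
        if key in seen:
            continue
        seen.add(key)
        prev_j = j_trim
        segments.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=str(chrom),
                start_bp=int(positions[i]),
                end_bp=int(positions[j_trim]),
                n_snps=n_snps,
                n_het_used=int(het_c[j_trim + 1] - het_c[i]),
                n_missing_used=int(miss_c[j_trim + 1] - miss_c[i]),
            )
        )
    return segments


def detect_roh_matrix(
    genotypes: GenotypeMatrix,
    params: Optional[ROHParams] = None,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, List[ROHSegment]]:
    """ROH per sample across all chromosomes of a genotype matrix."""
    out: Dict[str, List[ROHSegment]] = {}
    chroms = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    for sid in samples if samples is not None else genotypes.samples:
        row = genotypes.calls[genotypes.sample_index([sid])[0]]
        segs: List[ROHSegment] = []
        for chrom in pd_unique(chroms):
            m = chroms == chrom
            order = np.argsort(pos[m], kind="stable")
            segs.extend(
                detect_roh(row[m][order], pos[m][order], str(chrom), sid, params)
            )
        out[sid] = segs
    return out


def pd_unique(arr: np.ndarray) -> List:
    seen: List = []
    for x in arr:
        if not seen or x != seen[-1]:
            if x not in seen:
                seen.append(x)
    return seen


def shared_affected_roh(
    segments_by_sample: Dict[str, List[ROHSegment]],
    ped: Pedigree,
    min_length_bp: int = 200_000,
    age_threshold: float = 50.0,
    require_all_affected: bool = True,
    exclude_unaffected: bool = True,
) -> List[GenomicRegion]:
    """Homozygous regions shared exclusively by the affected members.

    Intersects ROH across all affected members (``require_all_affected``),
    removes any sub-interval overlapping an ROH of a retained unaffected
    member (``exclude_unaffected``), and keeps intervals strictly longer
    than ``min_length_bp``.
    """
    affected, unaffected = [], []
    for sid in segments_by_sample:
        if sid not in ped:
            continue
        st = effective_status(ped[sid], age_threshold, "homozygosity")
        if st == "affected":
            affected.append(sid)
        elif st == "unaffected":
            unaffected.append(sid)
    if len(affected) < 2:
        logger.warning(
            "family %s: fewer than 2 genotyped affected members; "
            "no shared ROH computed", ped.family_id,
        )
        return []
    groups = [[s.region() for s in segments_by_sample[a]] for a in affected]
    if require_all_affected:
        shared = intersect_many(groups)
    else:
        shared = _normalize([r for g in groups for r in g])
    if exclude_unaffected:
        cuts = [
            s.region() for u in unaffected for s in segments_by_sample[u]
        ]
        shared = subtract(shared, cuts)
    return [r for r in shared if r.length_bp > min_length_bp]
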