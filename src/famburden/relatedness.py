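"""Method-of-moments IBD estimation (PI-HAT) from biallelic genotypes.

For each pair of individuals the observed identity-by-state (IBS) class
counts over co-called loci are matched to their expectations under IBD
states 0/1/2, giving estimated state probabilities z0, z1, z2 and
``pihat = z1/2 + z2`` — the genome-wide IBD proportion reported by the
PLINK ``--genome`` convention.  Estimates are validated against
pedigree-expected values (``2*phi``) with :func:`expected_vs_observed`.

Per-locus class probabilities for alternate-allele frequency ``p``
(``q = 1 - p``):

====  =========  ==========  ================
IBD    P(IBS0)    P(IBS1)     P(IBS2)
====  =========  ==========  ================
0     2 p^2 q^2  4p^3q+4pq^3  p^4+q^4+4p^2q^2
1     0          2pq          p^2+q^2
2     0          0            1
====  =========  ==========  ================

Negative moment solutions are clamped to [0, 1] and renormalized (the
de-facto convention).  No LD pruning is performed here: the caller is
responsible for supplying (approximately) independent markers; the
synthetic panels of this package are independent by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = ["RelatednessEstimate", "estimate_pihat", "expected_vs_observed"]


@dataclass
class RelatednessEstimate:
    pair: Tuple[str, str]
    ibs_counts: Tuple[int, int, int]
    z: Tuple[float, float, float]
    pihat: float
    n_co_called: int
    reliable: bool = True


def estimate_pihat(
    genotypes: GenotypeMatrix,
    freqs: Optional[np.ndarray] = None,
    founder_ids: Optional[Sequence[str]] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    min_variants: int = 100,
) -> List[RelatednessEstimate]:
    """PI-HAT for every pair (default: all pairs of samples).

    ``freqs`` are per-variant alternate-allele frequencies for the moments
    system; by default they are computed from ``founder_ids`` (falling back
    to all samples).  Monomorphic variants are skipped with a log notice.
    Pairs with fewer than ``min_variants`` co-called loci are flagged
    unreliable.
    """
    if freqs is None:
        freqs = genotypes.alt_freq(founder_ids)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_variants,):
        raise ValueError("freqs length must equal the number of variants")

    poly = (freqs > 0.0) & (freqs < 1.0) & ~np.isnan(freqs)
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("skipping %d monomorphic variants in PI-HAT estimation", n_skipped)

    p = freqs[poly]
    q = 1.0 - p
    # per-locus IBS-class probabilities conditional on IBD state
    p_ibs0_ibd0 = 2.0 * p**2 * q**2
    p_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    p_ibs2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    p_ibs1_ibd1 = 2.0 * p * q
    p_ibs2_ibd1 = p**2 + q**2

    calls = genotypes.calls[:, poly]
    if pairs is None:
        pairs = list(combinations(genotypes.samples, 2))

    out: List[RelatednessEstimate] = []
    for i, j in pairs:
        gi = calls[genotypes.sample_index([i])[0]]
        gj = calls[genotypes.sample_index([j])[0]]
        co = (gi != MISSING) & (gj != MISSING)
        n_co = int(co.sum())
        diff = np.abs(gi[co] - gj[co])
        n0 = int((diff == 2).sum())
        n1 = int((diff == 1).sum())
        n2 = int((diff == 0).sum())

        e00 = float(p_ibs0_ibd0[co].sum())
        e10 = float(p_ibs1_ibd0[co].sum())
        e20 = float(p_ibs2_ibd0[co].sum())
        e11 = float(p_ibs1_ibd1[co].sum())
        e21 = float(p_ibs2_ibd1[co].sum())

        z0 = n0 / e00 if e00 > 0 else 0.0
        z1 = (n1 - z0 * e10) / e11 if e11 > 0 else 0.0
        z2 = (n2 - z0 * e20 - z1 * e21) / n_co if n_co > 0 else 0.0
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        total = z.sum()
        z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
        pihat = float(z[1] / 2.0 + z[2])
        out.append(
            RelatednessEstimate(
                pair=(i, j),
                ibs_counts=(n0, n1, n2),
                z=(float(z[0]), float(z[1]), float(z[2])),
                pihat=pihat,
                n_co_called=n_co,
                reliable=n_co >= min_variants,
            )
        )
    return out


def expected_vs_observed(
    ped: Pedigree,
    estimates: Sequence[RelatednessEstimate],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Concordance of estimated PI-HAT with pedigree expectation (2*phi).

    Pairs deviating by more than ``tolerance`` are flagged — the check used
    to confirm reported family relationships and consanguineous unions.
    """
    rows = []
    for est in estimates:
        i, j = est.pair
        if i not in ped or j not in ped:
            continue
        expected = ped.kinship(i, j).expected_pihat
        dev = abs(est.pihat - expected)
        rows.append(
            {
                "id1": i,
                "id2": j,
                "pihat": est.pihat,
                "expected_pihat": expected,
                "abs_deviation": dev,
                "flag": dev > tolerance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id1", "id2", "pihat", "expected_pihat", "abs_deviation", "flag"],
    )


def estimates_to_frame(
    estimates: Sequence[RelatednessEstimate],
) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "id1": e.pair[0],
                "id2": e.pair[1],
                "ibs0": e.ibs_counts[0],
                "ibs1": e.ibs_counts[1],
                "ibs2": e.ibs_counts[2],
                "z0": e.z[0],
                "z1": e.z[1],
                "z2": e.z[2],
                "pihat": e.pihat,
                "n_co_called": e.n_co_called,
                "reliable": e.reliable,
            }
        )
    return pd.DataFrame(rows)
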