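"""Single-point nonparametric linkage (NPL) per family.

For each marker, the posterior over inheritance vectors (one paternal and
one maternal meiosis bit per non-founder) is computed exactly: the marker
likelihood of a vector sums founder-allele assignments consistent with the
observed genotypes, weighted by founder allele frequencies.  Affected
allele sharing is scored with the Whittemore-Halpern pairs statistic
``S_pairs`` (total alleles shared IBD over unordered affected pairs), and
standardized against its null mean/SD under the uniform prior:

    Z = (E[S_pairs | data] - mu0) / sigma0

Family Z scores combine into a Kong-Cox one-parameter LOD by maximizing
``sum_f log10(1 + delta * w_f * Z_f)`` over the feasible ``delta >= 0``;
the per-family minimum achievable standardized score bounds ``delta`` (the
linear-model constraint), which caps the attainable per-family LOD.
Candidate regions are maximal runs of markers with LOD strictly above the
threshold (default 1.2).

This is a deliberate single-point, exact-enumeration design (no multipoint
HMM): pedigrees stay small enough that the full vector space is enumerable,
and every quantity has a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .pedigree import Pedigree, effective_status
from .regions import GenomicRegion

__all__ = [
    "InheritanceVectors",
    "NPLResult",
    "npl_single_point",
    "kong_cox_lod",
    "candidate_linkage_regions",
]


class BitCapExceeded(RuntimeError):
    pass


@dataclass
class NPLResult:
    z: Optional[float]              # None when the marker is uninformative
    expected_sharing: Optional[float]
    null_mean: float
    null_sd: float
    z_support_min: float            # smallest achievable standardized score
    informative: bool
    reason: str = ""


class InheritanceVectors:
    """Enumerated meiosis-bit space for one family, with S_pairs per vector.

    Meiosis bits are ordered (paternal, maternal) per non-founder in
    topological order.  Founder haplotypes occupy fixed "founder slots"
    (two per founder); for every vector the founder-slot origin of each
    member's two alleles is precomputed, which makes both S_pairs scoring
    and per-marker likelihoods cheap.
    """

    def __init__(
        self,
        ped: Pedigree,
        age_threshold: float = 50.0,
        bit_cap: int = 22,
    ) -> None:
        self.ped = ped
        founders = sorted(ped.founders(), key=lambda m: m.id)
        nonfounders = ped.nonfounders()
        self.n_bits = 2 * len(nonfounders)
        if self.n_bits > bit_cap:
            raise BitCapExceeded(
                f"family {ped.family_id}: {self.n_bits} meiosis bits exceed the "
                f"cap of {bit_cap}; split the pedigree before linkage analysis"
            )
        self.founder_slot: Dict[str, Tuple[int, int]] = {
            f.id: (2 * k, 2 * k + 1) for k, f in enumerate(founders)
        }
        self.n_founder_slots = 2 * len(founders)
        n_vec = 1 << self.n_bits
        v = np.arange(n_vec, dtype=np.int64)

        # founder-slot origin of each member's (paternal, maternal) allele,
        # as arrays over the whole vector space
        origin: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for f in founders:
            a, b = self.founder_slot[f.id]
            origin[f.id] = (
                np.full(n_vec, a, dtype=np.int16),
                np.full(n_vec, b, dtype=np.int16),
            )
        bit_pos = 0
        for nf in nonfounders:
            out = []
            for parent_id in (nf.father_id, nf.mother_id):
                bit = ((v >> bit_pos) & 1).astype(bool)
                pat, mat = origin[parent_id]
                out.append(np.where(bit, mat, pat).astype(np.int16))
                bit_pos += 1
            origin[nf.id] = (out[0], out[1])
        self.origin = origin
        self.n_vectors = n_vec

        self.affected = sorted(
            m.id
            for m in ped.members.values()
            if effective_status(m, age_threshold, "linkage") == "affected"
        )
        self.s_pairs = self._score_s_pairs()

    def _score_s_pairs(self) -> np.ndarray:
        """S_pairs(v) = sum over unordered affected pairs of IBD-shared alleles."""
        s = np.zeros(self.n_vectors, dtype=np.float64)
        for i, j in combinations(self.affected, 2):
            a, b = self.origin[i]
            c, d = self.origin[j]
            m_ac, m_ad = a == c, a == d
            m_bc, m_bd = b == c, b == d
            two = (m_ac & m_bd) | (m_ad & m_bc)
            one = m_ac | m_ad | m_bc | m_bd
            s += np.where(two, 2.0, np.where(one, 1.0, 0.0))
        return s

    # -- per-marker likelihood ------------------------------------------

    def marker_likelihoods(
        self, genotypes: Dict[str, int], p_alt: float
    ) -> np.ndarray:
        """Exact likelihood of each inheritance vector for one biallelic marker.

        ``genotypes`` maps member id -> alternate-allele dosage in {0,1,2};
        omit missing members.  Dispatches to a vectorized sum over founder
        allele assignments when the founder-slot space is small, and to a
        per-vector constraint-graph factorization otherwise; the two paths
        are algebraically identical and cross-checked in the test suite.
        """
        if self.n_founder_slots <= 12:
            return self._likelihoods_assignment(genotypes, p_alt)
        return self._likelihoods_graph(genotypes, p_alt)

    def _assignment_tables(self, p_alt: float):
        n_slots = self.n_founder_slots
        n_assign = 1 << n_slots
        if getattr(self, "_assign_cache", None) is None:
            a = np.arange(n_assign, dtype=np.int64)
            A = ((a[:, None] >> np.arange(n_slots)) & 1).astype(np.int8)
            S = A[:, :, None] + A[:, None, :]  # dosage per (slot_i, slot_j)
            self._assign_cache = (A, S)
        A, S = self._assign_cache
        log_p = np.log([1.0 - p_alt, p_alt])
        prior = np.exp(log_p[A].sum(axis=1))
        return A, S, prior

    def _likelihoods_assignment(
        self, genotypes: Dict[str, int], p_alt: float
    ) -> np.ndarray:
        """Sum over all founder-allele assignments, vectorized over vectors."""
        if not 0.0 < p_alt < 1.0:
            raise ValueError("allele frequency must be in (0, 1)")
        _, S, prior = self._assignment_tables(p_alt)
        mask: Optional[np.ndarray] = None
        for i, g in sorted(genotypes.items()):
            if g not in (0, 1, 2):
                continue
            pat, mat = self.origin[i]
            cons = S[:, pat, mat] == g  # (n_assign, n_vectors)
            mask = cons if mask is None else (mask & cons)
        if mask is None:
            return np.ones(self.n_vectors)
        return prior @ mask

    def _likelihoods_graph(
        self, genotypes: Dict[str, int], p_alt: float
    ) -> np.ndarray:
        """Per-vector constraint-graph factorization over founder slots."""
        if not 0.0 < p_alt < 1.0:
            raise ValueError("allele frequency must be in (0, 1)")
        typed = [
            (self.origin[i][0], self.origin[i][1], int(g))
            for i, g in sorted(genotypes.items())
            if g in (0, 1, 2)
        ]
        n_slots = self.n_founder_slots
        log_p = np.log([1.0 - p_alt, p_alt])
        lik = np.empty(self.n_vectors)
        parent = list(range(n_slots))
        parity = [0] * n_slots

        def find(x: int) -> Tuple[int, int]:
            par = 0
            root = x
            while parent[root] != root:
                par ^= parity[root]
                root = parent[root]
            # path compression
            while parent[x] != root:
                nxt, p_x = parent[x], parity[x]
                parent[x], parity[x] = root, par
                par ^= p_x
                x = nxt
            return root, parity[x] if x != root else 0

        for vi in range(self.n_vectors):
            for s in range(n_slots):
                parent[s] = s
                parity[s] = 0
            value: Dict[int, int] = {}
            touched: List[int] = []
            ok = True
            for pat, mat, g in typed:
                s1, s2 = int(pat[vi]), int(mat[vi])
                touched.append(s1)
                touched.append(s2)
                if g == 1:
                    # heterozygote: the two founder slots carry opposite alleles
                    r1, p1 = find(s1)
                    r2, p2 = find(s2)
                    if r1 == r2:
                        if p1 == p2:
                            ok = False
                            break
                        continue
                    # union with relative parity 1
                    parent[r2] = r1
                    parity[r2] = p1 ^ p2 ^ 1
                    if r2 in value:
                        v2 = value.pop(r2) ^ parity[r2]
                        if value.setdefault(r1, v2) != v2:
                            ok = False
                            break
                else:
                    allele = g // 2  # 0 -> ref/ref, 2 -> alt/alt
                    for s in (s1, s2):
                        r, par = find(s)
                        root_val = allele ^ par
                        if value.setdefault(r, root_val) != root_val:
                            ok = False
                            break
                    if not ok:
                        break
            if not ok:
                lik[vi] = 0.0
                continue
            # product over components of summed founder-allele probabilities
            comp_slots: Dict[int, List[Tuple[int, int]]] = {}
            for s in set(touched):
                r, par = find(s)
                comp_slots.setdefault(r, []).append((s, par))
            log_total = 0.0
            for r, slots in comp_slots.items():
                if r in value:
                    val = value[r]
                    log_total += sum(log_p[val ^ par] for _, par in slots)
                else:
                    l0 = sum(log_p[par] for _, par in slots)
                    l1 = sum(log_p[1 ^ par] for _, par in slots)
                    log_total += np.logaddexp(l0, l1)
            lik[vi] = np.exp(log_total)
        return lik

    def marker_likelihoods_alleles(
        self,
        genotypes: Dict[str, Tuple[int, int]],
        freqs: Sequence[float],
    ) -> np.ndarray:
        """Likelihoods for a multiallelic marker (unordered allele pairs).

        ``genotypes`` maps member id -> (allele_a, allele_b) indices into
        ``freqs``.  Used for microsatellite-style fully informative markers;
        enumerates founder-allele assignments directly.
        """
        freqs = np.asarray(freqs, dtype=float)
        if not np.isclose(freqs.sum(), 1.0) or np.any(freqs <= 0):
            raise ValueError("allele frequencies must be positive and sum to 1")
        k = freqs.size
        n_slots = self.n_founder_slots
        n_assign = k**n_slots
        if n_assign * self.n_vectors > 5e7:
            raise ValueError("allele/founder space too large to enumerate")
        digits = np.arange(n_assign)
        A = np.empty((n_assign, n_slots), dtype=np.int16)
        for s in range(n_slots):
            A[:, s] = digits % k
            digits = digits // k
        prior = np.prod(freqs[A], axis=1)
        mask: Optional[np.ndarray] = None
        for i, (a, b) in sorted(genotypes.items()):
            pat, mat = self.origin[i]
            ap = A[:, pat]
            am = A[:, mat]
            cons = ((ap == a) & (am == b)) | ((ap == b) & (am == a))
            mask = cons if mask is None else (mask & cons)
        if mask is None:
            return np.ones(self.n_vectors)
        return prior @ mask

    def _standardize(self, lik: np.ndarray) -> NPLResult:
        s = self.s_pairs
        mu0 = float(s.mean())
        sigma0 = float(s.std())
        z_support_min = (float(s.min()) - mu0) / sigma0 if sigma0 > 0 else 0.0
        total = lik.sum()
        if total <= 0.0:
            return NPLResult(None, None, mu0, sigma0, z_support_min, False,
                             "inconsistent genotypes")
        if lik.max() - lik.min() <= 1e-12 * lik.max():
            return NPLResult(None, None, mu0, sigma0, z_support_min, False,
                             "uninformative")
        e_s = float((lik * s).sum() / total)
        z = (e_s - mu0) / sigma0
        return NPLResult(z, e_s, mu0, sigma0, z_support_min, True)

    def score_marker_alleles(
        self, genotypes: Dict[str, Tuple[int, int]], freqs: Sequence[float]
    ) -> NPLResult:
        if float(self.s_pairs.std()) == 0.0:
            return NPLResult(None, None, float(self.s_pairs.mean()), 0.0, 0.0,
                             False, "sigma0=0")
        return self._standardize(self.marker_likelihoods_alleles(genotypes, freqs))

    def score_marker(self, genotypes: Dict[str, int], p_alt: float) -> NPLResult:
        s = self.s_pairs
        mu0 = float(s.mean())
        sigma0 = float(s.std())
        z_support_min = (float(s.min()) - mu0) / sigma0 if sigma0 > 0 else 0.0
        if sigma0 == 0.0:
            return NPLResult(None, None, mu0, sigma0, 0.0, False, "sigma0=0")
        typed_affected = sum(
            1 for i in self.affected if genotypes.get(i) in (0, 1, 2)
        )
        if typed_affected < 2:
            return NPLResult(
                None, None, mu0, sigma0, z_support_min, False, "<2 typed affected"
            )
        lik = self.marker_likelihoods(genotypes, p_alt)
        total = lik.sum()
        if total <= 0.0:
            return NPLResult(
                None, None, mu0, sigma0, z_support_min, False, "inconsistent genotypes"
            )
        if lik.max() - lik.min() <= 1e-12 * lik.max():
            return NPLResult(
                None, None, mu0, sigma0, z_support_min, False, "uninformative"
            )
        e_s = float((lik * s).sum() / total)
        z = (e_s - mu0) / sigma0
        return NPLResult(z, e_s, mu0, sigma0, z_support_min, True)


def npl_single_point(
    ped: Pedigree,
    genotypes: Dict[str, int],
    p_alt: float,
    age_threshold: float = 50.0,
    bit_cap: int = 22,
) -> NPLResult:
    """Exact single-point NPL Z score for one marker in one family."""
    return InheritanceVectors(ped, age_threshold, bit_cap).score_marker(
        genotypes, p_alt
    )


def kong_cox_lod(
    zscores: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    z_support_min: Optional[Sequence[float]] = None,
    delta_cap: float = 10.0,
    tol: float = 1e-8,
) -> float:
    """Kong-Cox linear-model LOD from per-family NPL Z scores.

    Maximizes ``sum_f log10(1 + delta * w_f * z_f)`` over ``delta >= 0``
    subject to every argument staying positive over the achievable score
    range: ``z_support_min`` (per-family minimum standardized score, as
    returned by the NPL enumeration) bounds delta when supplied; otherwise
    observed negative Z's bound it, with ``delta_cap`` as a last resort.
    Returns 0 when no positive evidence exists.
    """
    z = np.asarray([zv for zv in zscores if zv is not None and np.isfinite(zv)])
    if z.size == 0:
        return 0.0
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != z.shape:
        raise ValueError("weights length must match zscores")
    bounds = [delta_cap]
    lower = z if z_support_min is None else np.asarray(z_support_min, dtype=float)
    for wf, zb in zip(w, np.minimum(z, lower) if z_support_min is not None else z):
        if wf * zb < 0:
            bounds.append(-1.0 / (wf * zb))
    hi = min(bounds) * (1.0 - 1e-12)
    if hi <= 0:
        return 0.0

    def neg_obj(delta: float) -> float:
        args = 1.0 + delta * w * z
        if np.any(args <= 0):
            return np.inf
        return -float(np.log10(args).sum())

    res = minimize_scalar(neg_obj, bounds=(0.0, hi), method="bounded",
                          options={"xatol": tol})
    best = max(-res.fun, -neg_obj(hi * (1.0 - 1e-9)), 0.0)
    return float(best)


def candidate_linkage_regions(
    track: pd.DataFrame, lod_threshold: float = 1.2
) -> List[GenomicRegion]:
    """Maximal runs of consecutive markers with LOD strictly above threshold.

    ``track`` needs columns ``chrom, pos, lod`` and must be position-sorted
    within chromosome; each run becomes a region spanning its first to last
    marker position.  A single sub-threshold marker separates runs.
    """
    for col in ("chrom", "pos", "lod"):
        if col not in track.columns:
            raise ValueError(f"linkage track lacks column {col!r}")
    regions: List[GenomicRegion] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"linkage track not position-sorted on {chrom}")
        lods = sub["lod"].to_numpy(dtype=float)
        start = None
        for k in range(len(pos) + 1):
            above = k < len(pos) and lods[k] > lod_threshold
            if above and start is None:
                start = k
            elif not above and start is not None:
                peak = float(np.nanmax(lods[start:k]))
                regions.append(
                    GenomicRegion(
                        str(chrom), int(pos[start]), int(pos[k - 1]),
                        meta=(("max_lod", peak),),
                    )
                )
                start = None
    return regions
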