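"""End-to-end evaluation scenarios with known ground truth.

Each function builds a synthetic dataset under the generator's study
conditions, runs the relevant stage(s), and returns the measured quantity
(recovered relatedness, ROH recovery overlap, rare-variant filter
round-trip errors, logistic calibration and power).  Shared by the test
suite and the reproduction script.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .association import bonferroni_adjust, fit_logistic_or
from .genotypes import GenotypeMatrix
from .homozygosity import ROHParams, detect_roh
from .pedigree import Individual, Pedigree
from .regions import GenomicRegion, reciprocal_overlap
from .relatedness import estimate_pihat
from .simulate import (default_marker_panel, family_templates,
                       inject_rare_variant, simulate_family_set)
from .variants import filter_candidate_variants

__all__ = [
    "pihat_recovery",
    "roh_recovery",
    "variant_filter_roundtrip",
    "logistic_type1_error",
    "prs_shift_power",
]


def _relationship_templates(kind: str, n: int) -> List[Pedigree]:
    """Pedigrees producing one pair of the requested relationship each."""
    out = []
    for k in range(n):
        f = f"{kind[:2].upper()}{k}"
        if kind == "full_sibs":
            members = [
                Individual(f + "_f", sex="male"),
                Individual(f + "_m", sex="female"),
                Individual(f + "_x", f + "_f", f + "_m", "male"),
                Individual(f + "_y", f + "_f", f + "_m", "female"),
            ]
        elif kind == "avuncular":
            members = [
                Individual(f + "_f", sex="male"),
                Individual(f + "_m", sex="female"),
                Individual(f + "_x", f + "_f", f + "_m", "male"),
                Individual(f + "_p", f + "_f", f + "_m", "female"),
                Individual(f + "_s", sex="male"),
                Individual(f + "_y", f + "_s", f + "_p", "male"),
            ]
        elif kind == "first_cousins":
            members = [
                Individual(f + "_gf", sex="male"),
                Individual(f + "_gm", sex="female"),
                Individual(f + "_p1", f + "_gf", f + "_gm", "male"),
                Individual(f + "_p2", f + "_gf", f + "_gm", "female"),
                Individual(f + "_s1", sex="female"),
                Individual(f + "_s2", sex="male"),
                Individual(f + "_x", f + "_p1", f + "_s1", "male"),
                Individual(f + "_y", f + "_p2", f + "_s2", "female"),
            ]
        else:
            raise ValueError(f"unknown relationship {kind!r}")
        out.append(Pedigree(f, members))
    return out


def pihat_recovery(
    n_pairs: int = 50, n_snps: int = 5000, seed: int = 0
) -> Dict[str, float]:
    """Mean estimated PI-HAT per relationship class over replicate pairs.

    Pedigree expectations: full sibs 0.5, avuncular 0.25, first cousins
    0.125.
    """
    variants, freqs = default_marker_panel(n_snps, seed=seed)
    out: Dict[str, float] = {}
    for j, kind in enumerate(("full_sibs", "avuncular", "first_cousins")):
        peds = _relationship_templates(kind, n_pairs)
        peds, gm, _ = simulate_family_set(peds, variants, freqs,
                                          seed=seed + 100 + j)
        vals = []
        for ped in peds:
            pair = (ped.family_id + "_x", ped.family_id + "_y")
            est = estimate_pihat(gm.subset(samples=list(pair)), freqs=freqs,
                                 pairs=[pair])[0]
            vals.append(est.pihat)
        out[kind] = float(np.mean(vals))
    return out


def roh_recovery(
    n_reps: int = 10,
    segment_bp: int = 2_000_000,
    marker_spacing_bp: int = 20_000,
    seed: int = 0,
) -> float:
    """Mean reciprocal overlap of detected vs implanted autozygous segments.

    A dense single-chromosome panel carries a heterozygosity-rich
    background (allele frequency 0.5) with one implanted homozygous
    segment of ``segment_bp``; detection uses the default ROH parameters.
    """
    rng = np.random.default_rng(seed)
    n_markers = 800
    pos = np.arange(n_markers) * marker_spacing_bp + 1
    overlaps = []
    seg_markers = segment_bp // marker_spacing_bp
    for _ in range(n_reps):
        calls = rng.binomial(2, 0.5, size=n_markers).astype(np.int8)
        start = int(rng.integers(50, n_markers - seg_markers - 50))
        hom = (rng.random(seg_markers) < 0.5).astype(np.int8) * 2
        calls[start:start + seg_markers] = hom
        truth = GenomicRegion("1", int(pos[start]),
                              int(pos[start + seg_markers - 1]))
        segs = detect_roh(calls, pos, params=ROHParams())
        best = max(
            (reciprocal_overlap(truth, s.region()) for s in segs),
            default=0.0,
        )
        overlaps.append(best)
    return float(np.mean(overlaps))


def variant_filter_roundtrip(seed: int = 0) -> Tuple[int, int]:
    """(false positives, false negatives) of the rare-variant filter chain
    on a clean simulation: injected fully penetrant variants plus decoys
    that each violate exactly one retention rule."""
    variants, freqs = default_marker_panel(800, seed=seed)
    templates = family_templates()[:3]
    peds, gm, truth = simulate_family_set(templates, variants, freqs,
                                          seed=seed + 1)
    n_fp = n_fn = 0
    for j, (ped, zyg) in enumerate(zip(peds, ("hom", "het", "het"))):
        row, gts = inject_rare_variant(
            ped, truth, zygosity=zyg, gnomad_af=0.01, gene=f"TRUE{j}",
            seed=seed + 10 + j, genotypes=gm, carve_bp=20_000_000,
        )
        rng = np.random.default_rng(seed + 20 + j)
        members = list(ped.members)
        affected = [m.id for m in ped.members.values()
                    if m.affection == "affected"]
        old_unaffected = [
            m.id for m in ped.members.values()
            if m.affection == "unaffected" and (m.age_years or 0) >= 50
        ]
        carrier = {m: 1 if m in affected else 0 for m in members}
        decoys = [
            # too common in the population reference
            ({"gene": "D_COMMON", "consequence": "missense",
              "gnomad_af": 0.20}, carrier),
            # wrong consequence class
            ({"gene": "D_SYN", "consequence": "synonymous",
              "gnomad_af": 0.001}, carrier),
            # not fully penetrant: one affected member does not carry
            ({"gene": "D_PARTIAL", "consequence": "missense",
              "gnomad_af": 0.001},
             {**carrier, affected[0]: 0}),
            # carried by an exome-eligible unaffected member
            ({"gene": "D_UNAFF", "consequence": "missense",
              "gnomad_af": 0.001},
             {**carrier, **{u: 1 for u in old_unaffected[:1]}}),
        ]
        var_rows = [
            {"chrom": row["chrom"], "pos": row["pos"], "ref": "C",
             "alt": "T", "gene": row["gene"],
             "consequence": row["consequence"],
             "gnomad_af": row["gnomad_af"]}
        ]
        gt_rows = [dict(gts)]
        for meta, g in decoys:
            var_rows.append(
                {"chrom": "2", "pos": int(rng.integers(1, 10_000_000)),
                 "ref": "G", "alt": "A", **meta}
            )
            gt_rows.append(g)
        vdf = pd.DataFrame(var_rows)
        gdf = pd.DataFrame(gt_rows)[members]
        got = set(filter_candidate_variants(vdf, gdf, ped)["gene"])
        expected = {row["gene"]}
        n_fp += len(got - expected)
        n_fn += len(expected - got)
    return n_fp, n_fn


def logistic_type1_error(
    n_reps: int = 1000, n_case: int = 20, n_control: int = 40,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of the logistic score test under label permutation."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_case + n_control)
    labels = np.array([1] * n_case + [0] * n_control)
    hits = 0
    for _ in range(n_reps):
        y = rng.permutation(labels)
        if fit_logistic_or(x, y).p_raw < alpha:
            hits += 1
    return hits / n_reps


def prs_shift_power(
    shift_sd: float = 1.0, n_case: int = 24, n_control: int = 1272,
    m_comparisons: int = 4, seed: int = 0,
) -> Tuple[float, float]:
    """(odds ratio per SD, Bonferroni-adjusted p) for a case shift in PRS
    at the study group sizes."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([
        rng.normal(shift_sd, 1.0, n_case), rng.normal(0.0, 1.0, n_control)
    ])
    y = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    res = fit_logistic_or(x, y)
    p_adj = bonferroni_adjust([res.p_raw], m_comparisons)[0]
    return res.odds_ratio, p_adj
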