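"""Genotype quality control: pre-imputation thresholds, the exact
Hardy-Weinberg test, post-imputation filters, and the PRS SNP filter.

Rule order in :func:`qc_filter` is fixed: sample call rate first, then
variant MAF, variant call rate, and HWE; every removal is recorded with its
first failing rule so that report counts reconcile exactly with the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_filter",
    "hwe_exact_test",
    "post_imputation_filter",
    "prs_snp_filter",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class QCThresholds:
    sample_call_rate: float = 0.95
    variant_maf: float = 0.05
    variant_call_rate: float = 0.95
    hwe_p: float = 5e-8


@dataclass
class QCReport:
    samples_removed: List[Tuple[str, float]] = field(default_factory=list)
    variants_removed: List[Tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_variants_before: int = 0
    n_variants_after: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": sid, "kind": "sample", "reason": "call_rate", "detail": cr}
            for sid, cr in self.samples_removed
        ] + [
            {"item": vid, "kind": "variant", "reason": reason, "detail": ""}
            for vid, reason in self.variants_removed
        ]
        return pd.DataFrame(rows, columns=["item", "kind", "reason", "detail"])


class EmptyDataError(RuntimeError):
    """Every sample or variant was filtered out."""


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test for Hardy-Weinberg deviation.

    Given the observed genotype counts, conditions on the allele counts and
    sums the probabilities of all heterozygote counts no more probable than
    the observed one (the plain exact test of Wigginton-Cutler-Abecasis,
    without the mid-p modification).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype count")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    if n_hom_ref > n_hom_alt:  # canonicalize: bitwise symmetric in ref/alt
        n_hom_ref, n_hom_alt = n_hom_alt, n_hom_ref
    n_a = 2 * n_hom_ref + n_het      # allele A count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)

    def log_prob(h: int) -> float:
        # P(het = h | allele counts) on the log scale
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_b + 1)
            + h * math.log(2.0)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[n_het]
    # tolerance guards against ties lost to rounding
    p = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12)
    return min(1.0, p)


def qc_filter(
    genotypes: GenotypeMatrix,
    thresholds: Optional[QCThresholds] = None,
    pedigree: Optional[Pedigree] = None,
    pedigrees: Optional[List[Pedigree]] = None,
    hwe_founders_only: bool = True,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Pre-imputation QC.

    Samples with call rate below the threshold are removed first; variant
    MAF and call rate are then computed on the retained samples.  The HWE
    test uses founders only when pedigrees are supplied (family members are
    not independent draws from the population), controlled by
    ``hwe_founders_only``.
    """
    th = thresholds or QCThresholds()
    report = QCReport(
        n_samples_before=genotypes.n_samples,
        n_variants_before=genotypes.n_variants,
    )

    cr = genotypes.sample_call_rate()
    keep_samples = [
        s for s, c in zip(genotypes.samples, cr) if c >= th.sample_call_rate
    ]
    report.samples_removed = [
        (s, float(c))
        for s, c in zip(genotypes.samples, cr)
        if c < th.sample_call_rate
    ]
    if not keep_samples:
        raise EmptyDataError("no samples left after call-rate filter")
    gm = genotypes.subset(samples=keep_samples)

    peds = list(pedigrees or ([] if pedigree is None else [pedigree]))
    hwe_samples = gm.samples
    if peds and hwe_founders_only:
        founder_ids = {f.id for p in peds for f in p.founders()}
        hwe_samples = [s for s in gm.samples if s in founder_ids] or gm.samples

    maf = gm.maf()
    vcr = gm.variant_call_rate()
    hwe_idx = gm.sample_index(hwe_samples)
    keep = np.ones(gm.n_variants, dtype=bool)
    for k, vid in enumerate(gm.variants["variant_id"]):
        if maf[k] < th.variant_maf or np.isnan(maf[k]):
            report.variants_removed.append((vid, "maf"))
            keep[k] = False
        elif vcr[k] < th.variant_call_rate:
            report.variants_removed.append((vid, "call_rate"))
            keep[k] = False
        else:
            col = gm.calls[hwe_idx, k]
            col = col[col != MISSING]
            if col.size:
                p = hwe_exact_test(
                    int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
                )
                if p < th.hwe_p:
                    report.variants_removed.append((vid, "hwe"))
                    keep[k] = False
    gm = gm.subset(variant_mask=keep)
    if gm.n_variants == 0:
        raise EmptyDataError("no variants left after QC")
    report.n_samples_after = gm.n_samples
    report.n_variants_after = gm.n_variants
    return gm, report


def post_imputation_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    r2_min: float = 0.3,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Remove imputed variants with MAF < 1% or imputation r2 < 0.3.

    Every variant must carry an ``r2`` annotation (directly genotyped
    variants conventionally carry r2 = 1).
    """
    if "r2" not in genotypes.variants.columns:
        raise ValueError("variant table lacks an 'r2' annotation column")
    r2 = genotypes.variants["r2"]
    if r2.isna().any():
        bad = genotypes.variants.loc[r2.isna(), "variant_id"].tolist()
        raise ValueError(f"missing r2 annotation for variants: {bad}")
    report = QCReport(
        n_samples_before=genotypes.n_samples,
        n_variants_before=genotypes.n_variants,
        n_samples_after=genotypes.n_samples,
    )
    maf = genotypes.maf()
    keep = np.ones(genotypes.n_variants, dtype=bool)
    for k, vid in enumerate(genotypes.variants["variant_id"]):
        if maf[k] < maf_min or np.isnan(maf[k]):
            report.variants_removed.append((vid, "post_maf"))
            keep[k] = False
        elif r2.iloc[k] < r2_min:
            report.variants_removed.append((vid, "post_r2"))
            keep[k] = False
    out = genotypes.subset(variant_mask=keep)
    report.n_variants_after = out.n_variants
    return out, report


def prs_snp_filter(
    gwas_table: pd.DataFrame,
    maf_min: float = 0.01,
    quality_min: float = 0.9,
) -> Tuple[pd.DataFrame, QCReport]:
    """Filter a GWAS weight table before PRS construction.

    Drops rows with MAF below ``maf_min``, imputation quality below
    ``quality_min``, strand-ambiguous (palindromic) allele pairs, and any
    indel (allele of length != 1).  Expects columns
    ``snp_id, effect_allele, other_allele, maf, quality``.
    """
    for col in ("snp_id", "effect_allele", "other_allele", "maf", "quality"):
        if col not in gwas_table.columns:
            raise ValueError(f"GWAS table lacks column {col!r}")
    report = QCReport(n_variants_before=len(gwas_table))
    keep = []
    for _, row in gwas_table.iterrows():
        a1 = str(row["effect_allele"]).upper()
        a2 = str(row["other_allele"]).upper()
        if not a1 or not a2 or not a1.isalpha() or not a2.isalpha():
            raise ValueError(f"malformed allele for {row['snp_id']}: {a1!r}/{a2!r}")
        if len(a1) != 1 or len(a2) != 1:
            report.variants_removed.append((row["snp_id"], "indel"))
            keep.append(False)
        elif (a1, a2) in AMBIGUOUS_PAIRS:
            report.variants_removed.append((row["snp_id"], "ambiguous"))
            keep.append(False)
        elif row["maf"] < maf_min:
            report.variants_removed.append((row["snp_id"], "maf"))
            keep.append(False)
        elif row["quality"] < quality_min:
            report.variants_removed.append((row["snp_id"], "quality"))
            keep.append(False)
        else:
            keep.append(True)
    out = gwas_table.loc[keep].reset_index(drop=True)
    report.n_variants_after = len(out)
    return out, report
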