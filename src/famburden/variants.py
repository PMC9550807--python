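"""Exome-style candidate-variant filtering within multiplex families.

A candidate variant must (a) have a consequence in the retained set
(missense/nonsynonymous and splice-site by default), (b) be rarer than
``af_max`` (strict, default 5%) in the population reference (missing
frequency treated as "not observed", i.e. rarer), and (c) be fully
penetrant in the family under one zygosity model:

* heterozygous model — every affected member carries at least one copy and
  every retained unaffected member carries none;
* homozygous model — every affected member is homozygous for the variant
  and no retained unaffected member is (heterozygous unaffected carriers
  are allowed by default, as expected for a recessive-acting allele).

Retained unaffected members are those past the late-onset age threshold
(exome stage of :func:`famburden.pedigree.effective_status`); a family with
no such member is evaluated on the affected only and flagged "unopposed".
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .genotypes import MISSING
from .pedigree import Pedigree, effective_status
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

__all__ = ["filter_candidate_variants", "annotate_regions",
           "DEFAULT_CONSEQUENCES"]

DEFAULT_CONSEQUENCES: Set[str] = {
    "missense", "nonsynonymous", "nonsynonymous_snv",
    "splice", "splice_site", "splicing",
}

VARIANT_COLS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
                "gnomad_af"]


def filter_candidate_variants(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    ped: Pedigree,
    af_max: float = 0.05,
    consequences: Optional[Set[str]] = None,
    age_threshold: float = 50.0,
    allow_unaffected_het_under_hom_model: bool = True,
) -> pd.DataFrame:
    """Fully penetrant rare-variant candidates for one family.

    ``variants`` carries one row per annotated variant (columns
    ``chrom, pos, ref, alt, gene, consequence, gnomad_af`` and optionally
    ``pop_af``); ``genotypes`` is row-aligned with one column per family
    member (dosage 0/1/2, -1 missing).  Returns the retained rows with
    ``zygosity_class`` and bookkeeping columns added.
    """
    for col in VARIANT_COLS:
        if col not in variants.columns:
            raise ValueError(f"variant table lacks column {col!r}")
    keep_cons = {c.lower() for c in (consequences or DEFAULT_CONSEQUENCES)}

    affected = [
        m.id for m in ped.members.values()
        if effective_status(m, age_threshold, "exome") == "affected"
        and m.id in genotypes.columns
    ]
    unaffected = [
        m.id for m in ped.members.values()
        if effective_status(m, age_threshold, "exome") == "unaffected"
        and m.id in genotypes.columns
    ]
    if not affected:
        raise ValueError(f"family {ped.family_id}: no genotyped affected members")
    unopposed = not unaffected
    if unopposed:
        logger.warning(
            "family %s: no exome-eligible unaffected member; penetrance "
            "evaluated on affected only", ped.family_id,
        )

    rows = []
    for idx, var in variants.iterrows():
        cons = str(var["consequence"]).lower()
        if cons not in keep_cons:
            continue
        af = var["gnomad_af"]
        af_note = ""
        if af is None or (isinstance(af, float) and np.isnan(af)):
            af = 0.0
            af_note = "not observed in reference"
        if not af < af_max:
            continue
        g_aff = genotypes.loc[idx, affected].to_numpy(dtype=float)
        g_un = genotypes.loc[idx, unaffected].to_numpy(dtype=float)
        if np.any(g_aff == MISSING):
            continue  # cannot establish full penetrance with missing affected calls
        g_un_called = g_un[g_un != MISSING]
        zygosity = None
        if np.all(g_aff == 2) and not np.any(g_un_called == 2):
            if allow_unaffected_het_under_hom_model or not np.any(g_un_called == 1):
                zygosity = "homozygous"
        if zygosity is None and np.all(g_aff >= 1) and not np.any(g_un_called >= 1):
            zygosity = "heterozygous"
        if zygosity is None:
            continue
        row = dict(var)
        row.update(
            family_id=ped.family_id,
            zygosity_class=zygosity,
            gnomad_af=af,
            af_note=af_note,
            unopposed=unopposed,
            n_affected_carriers=len(affected),
            n_unaffected_checked=len(unaffected),
        )
        rows.append(row)
    cols = list(variants.columns) + [
        "family_id", "zygosity_class", "af_note", "unopposed",
        "n_affected_carriers", "n_unaffected_checked",
    ]
    return pd.DataFrame(rows, columns=pd.unique(pd.Index(cols)))


def annotate_regions(
    candidates: pd.DataFrame,
    linkage_regions: Sequence[GenomicRegion] = (),
    roh_regions: Sequence[GenomicRegion] = (),
    known_chroms: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Flag candidates inside candidate linkage regions (attaching the
    region's LOD) and inside shared affected ROH (inclusive endpoints)."""
    out = candidates.copy()
    if known_chroms:
        bad = sorted(
            set(map(str, out.get("chrom", pd.Series(dtype=str)))) - known_chroms
        )
        if bad:
            raise ValueError(f"variant chromosomes not in region set: {bad}")
    in_link: List[bool] = []
    lods: List[Optional[float]] = []
    in_roh: List[bool] = []
    for _, var in out.iterrows():
        chrom, pos = str(var["chrom"]), int(var["pos"])
        hit = next(
            (r for r in linkage_regions if r.contains(chrom, pos)), None
        )
        in_link.append(hit is not None)
        lods.append(dict(hit.meta).get("max_lod") if hit is not None else None)
        in_roh.append(any(r.contains(chrom, pos) for r in roh_regions))
    out["in_linkage_region"] = pd.Series(in_link, index=out.index, dtype=bool)
    out["linkage_lod"] = lods
    out["in_shared_roh"] = pd.Series(in_roh, index=out.index, dtype=bool)
    return out
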