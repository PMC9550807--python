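"""File dialects: PED/MAP, VCF (GT only), BED, and side TSVs.

Coordinates are 1-based inclusive everywhere inside the package; BED files
are written/read as 0-based half-open with a bit-exact converter.  PED has
no age column, so ages and group labels travel in a companion TSV
(``id, age_years, group``).
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Individual, Pedigree
from .regions import GenomicRegion

__all__ = [
    "write_ped_map", "read_ped_map",
    "write_vcf", "read_vcf",
    "write_bed", "read_bed",
    "write_ages_tsv", "read_ages_tsv",
]

_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_TO_SEX = {"1": "male", "2": "female"}
_AFF_TO_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}
_PED_TO_AFF = {"1": "unaffected", "2": "affected"}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PED / MAP


def write_ped_map(
    path_prefix: str,
    pedigrees: Sequence[Pedigree],
    genotypes: GenotypeMatrix,
) -> Tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (allele-pair dialect)."""
    map_path, ped_path = path_prefix + ".map", path_prefix + ".ped"
    v = genotypes.variants
    with open(map_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['variant_id']}\t0\t{row['pos']}\n")
    # allele-orientation sidecar: PED itself cannot say which allele is alt
    with open(path_prefix + ".ref", "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['variant_id']}\t{row['ref']}\t{row['alt']}\n")
    by_id: Dict[str, Tuple[str, Individual]] = {}
    for ped in pedigrees:
        for m in ped.members.values():
            by_id[m.id] = (ped.family_id, m)
    ref = v["ref"].to_numpy()
    alt = v["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for s, row in zip(genotypes.samples, genotypes.calls):
            fam, ind = by_id.get(s, (s, None))
            father = ind.father_id if ind else None
            mother = ind.mother_id if ind else None
            sex = _SEX_TO_PED[ind.sex] if ind else "0"
            aff = _AFF_TO_PED[ind.affection] if ind else "0"
            fields = [fam, s, father or "0", mother or "0", sex, aff]
            for k, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref[k], ref[k]]
                elif g == 1:
                    fields += [ref[k], alt[k]]
                else:
                    fields += [alt[k], alt[k]]
            fh.write(" ".join(map(str, fields)) + "\n")
    return ped_path, map_path


def read_ped_map(path_prefix: str) -> Tuple[List[Pedigree], GenotypeMatrix]:
    map_path, ped_path = path_prefix + ".map", path_prefix + ".ped"
    variants = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "variant_id", "cm", "pos"], dtype={"chrom": str},
    )
    n_var = len(variants)
    fam_members: Dict[str, List[Individual]] = {}
    samples: List[str] = []
    rows: List[np.ndarray] = []
    allele_sets: List[Dict[str, int]] = [dict() for _ in range(n_var)]
    raw: List[List[Tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_var} fields, "
                    f"got {len(parts)}"
                )
            fam, iid, fa, mo, sex, aff = parts[:6]
            ind = Individual(
                id=iid,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=_PED_TO_SEX.get(sex, "unknown"),
                affection=_PED_TO_AFF.get(aff, "unknown"),
            )
            fam_members.setdefault(fam, []).append(ind)
            samples.append(iid)
            pairs = [
                (parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(n_var)
            ]
            raw.append(pairs)
            for k, (a1, a2) in enumerate(pairs):
                for a in (a1, a2):
                    if a != "0":
                        allele_sets[k].setdefault(a, len(allele_sets[k]))
    ref_alleles, alt_alleles = [], []
    sidecar = {}
    ref_path = path_prefix + ".ref"
    if os.path.exists(ref_path):
        with open(ref_path) as fh:
            for line in fh:
                vid, ref, alt = line.split()
                sidecar[vid] = (ref, alt)
    for k in range(n_var):
        vid = variants["variant_id"].iloc[k]
        if vid in sidecar:
            ref, alt = sidecar[vid]
        else:
            alleles = sorted(allele_sets[k], key=allele_sets[k].get)
            ref = alleles[0] if alleles else "A"
            alt = alleles[1] if len(alleles) > 1 else "G"
        ref_alleles.append(ref)
        alt_alleles.append(alt)
    calls = np.full((len(samples), n_var), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw):
        for k, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            calls[i, k] = (a1 == alt_alleles[k]) + (a2 == alt_alleles[k])
    variants = pd.DataFrame(
        {
            "variant_id": variants["variant_id"],
            "chrom": variants["chrom"].astype(str),
            "pos": variants["pos"].astype(int),
            "ref": ref_alleles,
            "alt": alt_alleles,
        }
    )
    peds = [Pedigree(fam, mem) for fam, mem in fam_members.items()]
    return peds, GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# VCF (GT only)


def write_vcf(path: str, genotypes: GenotypeMatrix,
              r2: Optional[Sequence[float]] = None) -> str:
    v = genotypes.variants
    chrom_order = list(dict.fromkeys(v["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        if r2 is not None:
            fh.write(
                '##INFO=<ID=R2,Number=1,Type=Float,'
                'Description="Imputation accuracy">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for k in range(len(v)):
            row = v.iloc[k]
            info = f"R2={r2[k]:.4f}" if r2 is not None else "."
            gts = "\t".join(gt_map[int(g)] for g in genotypes.calls[:, k])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t{info}\tGT\t{gts}\n"
            )
    return path


def read_vcf(path: str) -> Tuple[GenotypeMatrix, Optional[np.ndarray]]:
    """Read a GT-only VCF into a genotype matrix (phase is ignored)."""
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows, calls, r2s = [], [], []
    has_r2 = "R2" in vf.header.info
    for rec in vf:
        alt = rec.alts[0] if rec.alts else "."
        rows.append(
            (rec.id or f"{rec.chrom}_{rec.pos}", str(rec.chrom), int(rec.pos),
             rec.ref, alt)
        )
        gt_row = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                gt_row.append(MISSING)
            else:
                gt_row.append(int(sum(gt)))
        calls.append(gt_row)
        r2s.append(rec.info.get("R2") if has_r2 else np.nan)
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    gm = GenotypeMatrix(samples, variants, np.array(calls, dtype=np.int8).T)
    r2_arr = np.array(r2s, dtype=float) if has_r2 else None
    return gm, r2_arr


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)


def write_bed(path: str, regions: Sequence[GenomicRegion]) -> str:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
    return path


def read_bed(path: str) -> List[GenomicRegion]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track")):
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: fewer than 3 BED fields")
            out.append(
                GenomicRegion(parts[0], int(parts[1]) + 1, int(parts[2]))
            )
    return out


# ---------------------------------------------------------------------------
# companion TSVs


def write_ages_tsv(path: str, pedigrees: Sequence[Pedigree],
                   groups: Optional[Dict[str, str]] = None) -> str:
    rows = []
    for ped in pedigrees:
        for m in ped.members.values():
            rows.append(
                {
                    "id": m.id,
                    "age_years": "" if m.age_years is None else m.age_years,
                    "group": (groups or {}).get(m.id, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_ages_tsv(path: str, pedigrees: Sequence[Pedigree]) -> None:
    df = pd.read_csv(path, sep="\t")
    by_id = {m.id: m for p in pedigrees for m in p.members.values()}
    for _, row in df.iterrows():
        ind = by_id.get(str(row["id"]))
        if ind is not None and not pd.isna(row["age_years"]):
            ind.age_years = float(row["age_years"])
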