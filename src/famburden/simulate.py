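"""Synthetic multiplex-family data with known truth.

Generates everything the pipeline consumes, so every stage is testable
without external data:

* seven default family templates emulating consanguineous multiplex
  pedigrees (first-cousin parental unions in six of seven, 3-4 affected
  members each);
* a genome-wide biallelic SNP panel on 22 autosomes with a uniform
  1 cM/Mb genetic map, plus a curated 174-row risk-allele panel
  (165 non-MHC + 9 MHC rows, the MHC rows on chr6:25-34 Mb) with
  published-style per-allele odds ratios;
* founder haplotypes drawn independently per locus from panel
  frequencies, gene-dropped through the pedigree with Haldane
  (no-interference) recombination; the truth record keeps every
  haplotype's founder origin, from which true IBD sharing and autozygous
  segments are exact;
* a liability-threshold disease model (log-odds weights on risk alleles
  plus standard-normal noise, optional fully penetrant rare-variant
  effect) for affection labels and age draws;
* injection of fully penetrant rare exonic variants (heterozygous or, in
  consanguineous families, homozygous inside a truly autozygous segment)
  and of genotype missingness.

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Individual, Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "DiseaseModel",
    "default_marker_panel",
    "default_risk_panel",
    "family_templates",
    "simulate_family_set",
    "simulate_unrelated",
    "assign_affection",
    "inject_rare_variant",
    "inject_missingness",
    "true_ibd_sharing",
    "autozygous_segments",
]

CHROM_LENGTH_BP = 100_000_000  # per autosome in the default panel
MHC_CHROM, MHC_START, MHC_END = "6", 25_000_000, 34_000_000


@dataclass
class GeneticMap:
    """Marker genetic map; Haldane map function theta = (1 - e^(-2d)) / 2."""

    markers: pd.DataFrame  # columns: chrom, pos_bp, pos_cM

    def __post_init__(self) -> None:
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise ValueError(f"map positions not increasing on {chrom}")

    @classmethod
    def uniform(cls, variants: pd.DataFrame, cm_per_mb: float = 1.0) -> "GeneticMap":
        m = variants[["chrom", "pos"]].rename(columns={"pos": "pos_bp"}).copy()
        m["pos_cM"] = m["pos_bp"] * cm_per_mb / 1e6
        return cls(m)

    def thetas(self) -> Dict[str, np.ndarray]:
        """Recombination fraction between adjacent markers, per chromosome."""
        out = {}
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            d = np.diff(sub["pos_cM"].to_numpy()) / 100.0  # Morgans
            out[str(chrom)] = 0.5 * (1.0 - np.exp(-2.0 * d))
        return out


@dataclass
class DiseaseModel:
    """Liability-threshold model on risk-allele dosages.

    liability = sum_i w_i * dosage_i + rare_effect + N(0, 1); affected iff
    liability > threshold.  ``rare_variant_effect`` in {none, dominant_full,
    recessive_full} makes carriers (any copy / two copies) affected with
    certainty regardless of liability.
    """

    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    threshold: float = 2.326  # ~1% prevalence under null weights
    rare_variant_effect: str = "none"
    affected_age_mean: float = 42.0
    affected_age_sd: float = 10.94
    unaffected_age_mean: float = 55.36
    unaffected_age_sd: float = 15.23

    def __post_init__(self) -> None:
        if self.rare_variant_effect not in {"none", "dominant_full", "recessive_full"}:
            raise ValueError(
                f"unknown rare_variant_effect {self.rare_variant_effect!r}"
            )


# ---------------------------------------------------------------------------
# panels


def default_marker_panel(
    n_snps: int = 5000,
    n_chrom: int = 22,
    seed: int = 0,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Genome-wide SNP panel: positions, alleles, and alt-allele frequencies."""
    rng = np.random.default_rng(seed)
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps - per.sum()] += 1
    n_mhc_reserved = 12  # guarantee enough MHC-window SNPs for the risk panel
    rows = []
    for c in range(n_chrom):
        chrom = str(c + 1)
        if chrom == MHC_CHROM:
            mhc_pos = rng.choice(
                np.arange(MHC_START, MHC_END, 1000),
                size=min(n_mhc_reserved, per[c]), replace=False,
            )
            rest = rng.choice(np.arange(1, CHROM_LENGTH_BP, 1000),
                              size=per[c] - len(mhc_pos), replace=False)
            pos = np.sort(np.unique(np.concatenate([mhc_pos, rest])))
        else:
            pos = np.sort(
                rng.choice(np.arange(1, CHROM_LENGTH_BP, 1000), size=per[c],
                           replace=False)
            )
        for p in pos:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append((f"snp_{chrom}_{p}", chrom, int(p), ref, alt))
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    freqs = rng.uniform(freq_low, freq_high, size=len(variants))
    return variants, freqs


def default_risk_panel(
    variants: pd.DataFrame,
    freqs: np.ndarray,
    n_total: int = 174,
    n_mhc: int = 9,
    seed: int = 0,
    divergence_fst: float = 0.01,
) -> pd.DataFrame:
    """Curated risk-allele panel drawn from the marker panel.

    ``n_mhc`` rows fall in the MHC window (chr6:25-34 Mb) and carry larger
    odds ratios (the strongest susceptibility locus cluster); the rest are
    genome-wide with modest effects.  Two frequency columns emulate the
    study population and an external reference aggregate: the reference
    frequency is a Balding-Nichols draw around the study frequency at a
    field-typical divergence (Fst ~ 0.01 within continental groups).
    """
    rng = np.random.default_rng(seed)
    in_mhc = (
        (variants["chrom"] == MHC_CHROM)
        & (variants["pos"] >= MHC_START)
        & (variants["pos"] <= MHC_END)
    ).to_numpy()
    mhc_idx = np.flatnonzero(in_mhc)
    if len(mhc_idx) < n_mhc:
        raise ValueError("marker panel has too few MHC-window SNPs")
    pick_mhc = rng.choice(mhc_idx, size=n_mhc, replace=False)
    rest = np.flatnonzero(~in_mhc)
    pick_rest = rng.choice(rest, size=n_total - n_mhc, replace=False)
    idx = np.concatenate([pick_mhc, pick_rest])
    is_mhc = np.zeros(n_total, dtype=bool)
    is_mhc[:n_mhc] = True
    odds = np.where(
        is_mhc,
        rng.uniform(1.3, 3.0, size=n_total),
        np.exp(rng.normal(np.log(1.1), 0.05, size=n_total)),
    )
    p = freqs[idx]
    a = p * (1.0 - divergence_fst) / divergence_fst
    b = (1.0 - p) * (1.0 - divergence_fst) / divergence_fst
    ref_freq = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    table = pd.DataFrame(
        {
            "snp_id": variants["variant_id"].to_numpy()[idx],
            "chrom": variants["chrom"].to_numpy()[idx],
            "pos": variants["pos"].to_numpy()[idx],
            "risk_allele": variants["alt"].to_numpy()[idx],
            "odds_ratio": odds,
            "is_mhc": is_mhc,
            "study_freq": p,
            "reference_freq": ref_freq,
        }
    )
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pedigree templates


def _first_cousin_template(
    family_id: str, n_children: int, n_affected: int, ages: Sequence[int]
) -> Pedigree:
    """Three-generation family whose bottom couple are first cousins."""
    f = family_id
    members = [
        Individual(f"{f}_GF", sex="male"),
        Individual(f"{f}_GM", sex="female"),
        Individual(f"{f}_P1", f"{f}_GF", f"{f}_GM", "male"),
        Individual(f"{f}_P2", f"{f}_GF", f"{f}_GM", "female"),
        Individual(f"{f}_S1", sex="female"),
        Individual(f"{f}_S2", sex="male"),
        Individual(f"{f}_A", f"{f}_P1", f"{f}_S1", "male"),
        Individual(f"{f}_B", f"{f}_P2", f"{f}_S2", "female"),
    ]
    for k in range(n_children):
        members.append(
            Individual(
                f"{f}_C{k + 1}", f"{f}_A", f"{f}_B",
                "male" if k % 2 else "female",
            )
        )
    ped = Pedigree(family_id, members)
    # affection: the first n_affected children (spilling over to parent A
    # when n_affected exceeds the sibship); grandparental generation old
    for k in range(n_children):
        ped[f"{f}_C{k + 1}"].affection = (
            "affected" if k < n_affected else "unaffected"
        )
    for mid, age in zip(
        [f"{f}_GF", f"{f}_GM", f"{f}_P1", f"{f}_P2", f"{f}_S1", f"{f}_S2",
         f"{f}_A", f"{f}_B"]
        + [f"{f}_C{k + 1}" for k in range(n_children)],
        ages,
    ):
        ped[mid].age_years = age
    for mid in (f"{f}_GF", f"{f}_GM", f"{f}_P1", f"{f}_P2", f"{f}_S1",
                f"{f}_S2", f"{f}_A", f"{f}_B"):
        ped[mid].affection = "unaffected"
    if n_affected > n_children:
        ped[f"{f}_A"].affection = "affected"
    return ped


def _nuclear_template(
    family_id: str, n_children: int, n_affected: int, ages: Sequence[int]
) -> Pedigree:
    f = family_id
    members = [
        Individual(f"{f}_F", sex="male", affection="unaffected"),
        Individual(f"{f}_M", sex="female", affection="unaffected"),
    ]
    for k in range(n_children):
        members.append(
            Individual(f"{f}_C{k + 1}", f"{f}_F", f"{f}_M",
                       "female" if k % 2 else "male",
                       "affected" if k < n_affected else "unaffected")
        )
    ped = Pedigree(family_id, members)
    for mid, age in zip(
        [f"{f}_F", f"{f}_M"] + [f"{f}_C{k + 1}" for k in range(n_children)], ages
    ):
        ped[mid].age_years = age
    return ped


def family_templates() -> List[Pedigree]:
    """Seven multiplex templates: first-cousin unions in six, 3-4 affected.

    Ages mix unaffected members above and below the 50-year onset-risk
    threshold so that the status-handling rules are actually exercised.
    """
    upper = [88, 85, 66, 63, 62, 60, 45, 42]
    peds = [
        _first_cousin_template("FAM01", 3, 4, upper + [30, 27, 25]),
        _first_cousin_template("FAM02", 3, 3, upper + [34, 31, 55]),
        _first_cousin_template("FAM03", 3, 3, upper + [36, 30, 52]),
        _first_cousin_template("FAM04", 3, 4, upper + [42, 40, 38]),
        _first_cousin_template("FAM05", 3, 3, upper + [38, 35, 58]),
        _first_cousin_template("FAM07", 3, 3, upper + [44, 41, 61]),
        _nuclear_template("FAM08", 5, 3, [75, 72, 44, 40, 36, 33, 52]),
    ]
    return peds


# ---------------------------------------------------------------------------
# gene dropping


class Truth:
    """Per-haplotype founder origins; exact IBD is derived from these."""

    def __init__(self) -> None:
        self.origins: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self.variants: Optional[pd.DataFrame] = None

    def ids(self) -> List[str]:
        return list(self.origins)


def _meiosis(
    rng: np.random.Generator,
    hap_pair: Tuple[np.ndarray, np.ndarray],
    origin_pair: Tuple[np.ndarray, np.ndarray],
    chrom_slices: List[slice],
    thetas: List[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """One gamete: Haldane recombination between adjacent markers."""
    n = hap_pair[0].size
    chooser = np.empty(n, dtype=np.int8)
    for sl, th in zip(chrom_slices, thetas):
        m = sl.stop - sl.start
        start = rng.integers(0, 2)
        cross = rng.random(m - 1) < th if m > 1 else np.empty(0, dtype=bool)
        chooser[sl] = (start + np.concatenate([[0], np.cumsum(cross)])) % 2
    hap = np.where(chooser == 0, hap_pair[0], hap_pair[1])
    origin = np.where(chooser == 0, origin_pair[0], origin_pair[1])
    return hap.astype(np.int8), origin.astype(np.int32)


def simulate_family_set(
    templates: Sequence[Pedigree],
    variants: pd.DataFrame,
    freqs: np.ndarray,
    gmap: Optional[GeneticMap] = None,
    seed: int = 0,
) -> Tuple[List[Pedigree], GenotypeMatrix, Truth]:
    """Gene-drop the marker panel through each template pedigree.

    Founder haplotypes are independent per locus at the panel frequencies;
    each meiosis recombines under the Haldane map.  Fully reproducible from
    ``seed``; the truth record holds every haplotype's founder origin.
    """
    rng = np.random.default_rng(seed)
    gmap = gmap or GeneticMap.uniform(variants)
    freqs = np.asarray(freqs, dtype=float)
    chrom_slices: List[slice] = []
    theta_list: List[np.ndarray] = []
    thetas = gmap.thetas()
    chroms = variants["chrom"].to_numpy()
    start = 0
    for chrom in dict.fromkeys(chroms):
        m = int((chroms == chrom).sum())
        chrom_slices.append(slice(start, start + m))
        theta_list.append(thetas[str(chrom)])
        start += m

    truth = Truth()
    truth.variants = variants
    samples: List[str] = []
    calls: List[np.ndarray] = []
    haps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    origin_counter = 0
    n_markers = len(variants)
    for ped in templates:
        for founder in sorted(ped.founders(), key=lambda m: m.id):
            h = (rng.random((2, n_markers)) < freqs).astype(np.int8)
            o = (
                np.full(n_markers, origin_counter, dtype=np.int32),
                np.full(n_markers, origin_counter + 1, dtype=np.int32),
            )
            origin_counter += 2
            haps[founder.id] = (h[0], h[1])
            truth.origins[founder.id] = o
        for nf in ped.nonfounders():
            out_h, out_o = [], []
            for parent_id in (nf.father_id, nf.mother_id):
                h, o = _meiosis(
                    rng, haps[parent_id], truth.origins[parent_id],
                    chrom_slices, theta_list,
                )
                out_h.append(h)
                out_o.append(o)
            haps[nf.id] = (out_h[0], out_h[1])
            truth.origins[nf.id] = (out_o[0], out_o[1])
        for m in sorted(ped.members, key=lambda i: (ped._depth[i], i)):
            samples.append(m)
            calls.append(haps[m][0] + haps[m][1])
    gm = GenotypeMatrix(samples, variants.copy(), np.array(calls, dtype=np.int8))
    return list(templates), gm, truth


def simulate_unrelated(
    n: int,
    variants: pd.DataFrame,
    freqs: np.ndarray,
    seed: int = 0,
    prefix: str = "IND",
) -> GenotypeMatrix:
    """Unrelated individuals in Hardy-Weinberg proportions at panel freqs."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    calls = (
        (rng.random((n, len(variants))) < freqs).astype(np.int8)
        + (rng.random((n, len(variants))) < freqs).astype(np.int8)
    )
    samples = [f"{prefix}{k:05d}" for k in range(n)]
    return GenotypeMatrix(samples, variants.copy(), calls)


# ---------------------------------------------------------------------------
# phenotype


def assign_affection(
    genotypes: GenotypeMatrix,
    model: DiseaseModel,
    seed: int = 0,
    rare_carrier_dosage: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Liability-threshold affection labels and ages for every sample.

    Returns a frame with columns ``id, liability, affection, age_years``.
    ``rare_carrier_dosage`` (per-sample dosage of an injected rare variant)
    triggers certain affection under the dominant/recessive full-penetrance
    modes of the model.
    """
    rng = np.random.default_rng(seed)
    dos = genotypes.dosage_frame()
    liab = np.zeros(genotypes.n_samples)
    if len(model.weights):
        snps = [s for s in model.weights.index if s in dos.columns]
        if len(snps) != len(model.weights):
            raise ValueError("liability weights refer to SNPs absent from panel")
        X = dos[snps].to_numpy(dtype=float)
        X = np.where(np.isnan(X), 0.0, X)
        liab += X @ model.weights.loc[snps].to_numpy(dtype=float)
    liab += rng.standard_normal(genotypes.n_samples)
    affected = liab > model.threshold
    if rare_carrier_dosage is not None and model.rare_variant_effect != "none":
        carrier = rare_carrier_dosage.reindex(genotypes.samples).fillna(0)
        need = 1 if model.rare_variant_effect == "dominant_full" else 2
        affected = affected | (carrier.to_numpy() >= need)
    ages = np.where(
        affected,
        rng.normal(model.affected_age_mean, model.affected_age_sd,
                   genotypes.n_samples),
        rng.normal(model.unaffected_age_mean, model.unaffected_age_sd,
                   genotypes.n_samples),
    )
    ages = np.clip(np.round(ages), 18, 95).astype(int)
    return pd.DataFrame(
        {
            "id": genotypes.samples,
            "liability": liab,
            "affection": np.where(affected, "affected", "unaffected"),
            "age_years": ages,
        }
    )


# ---------------------------------------------------------------------------
# rare-variant and missingness injection


def autozygous_segments(
    truth: Truth, sample_id: str
) -> List[Tuple[str, int, int]]:
    """Maximal truly autozygous runs (both haplotypes same founder origin)."""
    o0, o1 = truth.origins[sample_id]
    auto = o0 == o1
    chroms = truth.variants["chrom"].to_numpy()
    pos = truth.variants["pos"].to_numpy()
    out = []
    start = None
    for k in range(len(auto) + 1):
        inside = k < len(auto) and auto[k] and (start is None or chroms[k] == chroms[start])
        if inside and start is None:
            start = k
        elif not inside and start is not None:
            out.append((str(chroms[start]), int(pos[start]), int(pos[k - 1])))
            start = k if k < len(auto) and auto[k] else None
    return out


def true_ibd_sharing(truth: Truth, i: str, j: str) -> float:
    """Genome-average IBD proportion between two simulated individuals."""
    oi, oj = truth.origins[i], truth.origins[j]
    m11 = oi[0] == oj[0]
    m12 = oi[0] == oj[1]
    m21 = oi[1] == oj[0]
    m22 = oi[1] == oj[1]
    two = (m11 & m22) | (m12 & m21)
    one = m11 | m12 | m21 | m22
    share = np.where(two, 2.0, np.where(one, 1.0, 0.0))
    return float(share.mean() / 2.0)


def cosegregating_affection(
    ped: Pedigree, truth: Truth, marker_index: int
) -> Tuple[List[str], int]:
    """Make affection follow a dominant fully penetrant founder haplotype.

    Carriers of the founder haplotype with the most carriers at
    ``marker_index`` (emulating ascertainment of a multiplex family
    segregating a dominant variant) become affected; everyone else
    unaffected.  Returns (carrier ids, founder slot).
    """
    counts: Dict[int, set] = {}
    for m in ped.members.values():
        o0, o1 = truth.origins[m.id]
        for slot in (int(o0[marker_index]), int(o1[marker_index])):
            counts.setdefault(slot, set()).add(m.id)
    slot, carriers = max(counts.items(), key=lambda kv: (len(kv[1]), -kv[0]))
    for m in ped.members.values():
        m.affection = "affected" if m.id in carriers else "unaffected"
    return sorted(carriers), slot


def inject_rare_variant(
    ped: Pedigree,
    truth: Optional[Truth] = None,
    zygosity: str = "het",
    gnomad_af: float = 0.001,
    consequence: str = "missense",
    gene: str = "GENE1",
    seed: int = 0,
    age_threshold: float = 50.0,
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
    genotypes: Optional[GenotypeMatrix] = None,
    carve_bp: int = 2_000_000,
) -> Tuple[Dict, pd.Series]:
    """A fully penetrant rare variant cosegregating in one family.

    Every affected member carries the variant at the requested zygosity;
    unaffected members never carry it under the heterozygous model, while
    under the homozygous model obligate-carrier parents of affected members
    are heterozygous and nobody unaffected is homozygous.  For
    ``zygosity='hom'`` the position is placed inside a truly autozygous
    segment shared by all affected members when the truth record provides
    one.  Returns (annotated variant row, per-member dosage series).
    """
    if zygosity not in {"het", "hom"}:
        raise ValueError("zygosity must be 'het' or 'hom'")
    affected = [m.id for m in ped.members.values() if m.affection == "affected"]
    if not affected:
        raise ValueError(f"family {ped.family_id} has no affected member")
    rng = np.random.default_rng(seed)
    if zygosity == "hom" and not ped.consanguineous_unions():
        warnings.warn(
            f"homozygous variant requested in non-consanguineous family "
            f"{ped.family_id}; honoring anyway", stacklevel=2,
        )
    if chrom is None or pos is None:
        chrom, pos = _pick_position(
            ped, truth, affected, zygosity, rng,
            genotypes=genotypes, carve_bp=carve_bp,
        )
    dosage = {}
    target = 2 if zygosity == "hom" else 1
    parents_of_affected = {
        p for a in affected
        for p in (ped[a].father_id, ped[a].mother_id) if p is not None
    }
    for m in ped.members.values():
        if m.affection == "affected":
            dosage[m.id] = target
        elif zygosity == "hom" and m.id in parents_of_affected:
            dosage[m.id] = 1  # obligate carrier
        else:
            dosage[m.id] = 0
    variant = {
        "variant_id": f"rare_{ped.family_id}_{gene}",
        "chrom": str(chrom),
        "pos": int(pos),
        "ref": "C",
        "alt": "T",
        "gene": gene,
        "consequence": consequence,
        "gnomad_af": float(gnomad_af),
        "pop_af": float(np.clip(gnomad_af * rng.uniform(0.5, 2.0), 0, 1)),
        "family_id": ped.family_id,
        "zygosity": "homozygous" if zygosity == "hom" else "heterozygous",
    }
    return variant, pd.Series(dosage, name=variant["variant_id"])


def _pick_position(ped, truth, affected, zygosity, rng,
                   genotypes=None, carve_bp=2_000_000):
    if truth is not None and zygosity == "hom":
        shared = None
        for a in affected:
            segs = {
                (c, s, e) for (c, s, e) in autozygous_segments(truth, a)
            }
            ivals = _seg_union(segs)
            shared = ivals if shared is None else _seg_intersect(shared, ivals)
        shared = [s for s in shared or [] if s[2] - s[1] >= carve_bp // 4]
        if shared:
            c, s, e = max(shared, key=lambda t: t[2] - t[1])
            return c, (s + e) // 2
        if genotypes is not None:
            return _carve_autozygous_segment(
                ped, truth, affected, genotypes, carve_bp, rng
            )
        logger.warning(
            "family %s: no shared autozygous segment found; placing "
            "homozygous variant at a random position", ped.family_id,
        )
    if truth is not None and truth.variants is not None:
        row = truth.variants.iloc[rng.integers(0, len(truth.variants))]
        return str(row["chrom"]), int(row["pos"]) + 1
    return "1", int(rng.integers(1, CHROM_LENGTH_BP))


def _carve_autozygous_segment(ped, truth, affected, genotypes, carve_bp, rng):
    """Implant a shared autozygous segment for all affected members.

    Picks a window of ~``carve_bp`` on a random chromosome and makes every
    affected member homozygous there for one founder haplotype pattern
    (truth origins updated to reflect the autozygosity).
    """
    v = genotypes.variants
    chroms = list(dict.fromkeys(v["chrom"]))
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    m = (v["chrom"] == chrom).to_numpy()
    pos = v["pos"].to_numpy()[m]
    idx_all = np.flatnonzero(m)
    lo = int(rng.integers(0, max(1, len(pos) - 2)))
    hi = lo
    while hi + 1 < len(pos) and pos[hi + 1] - pos[lo] <= carve_bp:
        hi += 1
    window = idx_all[lo:hi + 1]
    pattern = genotypes.calls[
        genotypes.sample_index([affected[0]])[0], window
    ].copy()
    pattern = np.where(pattern == 1, 0, pattern)  # homozygous template
    pattern = np.where(pattern == MISSING, 0, pattern)
    for a in affected:
        i = genotypes.sample_index([a])[0]
        genotypes.calls[i, window] = pattern
        if a in truth.origins:
            o0, o1 = truth.origins[a]
            o1[window] = o0[window]
    logger.info(
        "family %s: carved a %d-marker shared autozygous segment on %s",
        ped.family_id, len(window), chrom,
    )
    return str(chrom), int((pos[lo] + pos[min(hi, len(pos) - 1)]) // 2)


def _seg_union(segs):
    return sorted(segs)


def _seg_intersect(a, b):
    out = []
    for (c1, s1, e1) in a:
        for (c2, s2, e2) in b:
            if c1 == c2 and s1 <= e2 and s2 <= e1:
                out.append((c1, max(s1, s2), min(e1, e2)))
    return out


def inject_missingness(
    genotypes: GenotypeMatrix,
    sample_rates=0.0,
    variant_rates=0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Set calls to missing at given per-sample and per-variant rates.

    Rates may be scalars or arrays (per sample / per variant); a call is
    missing when either draw fires.  Reproducible from ``seed``.
    """
    s = np.broadcast_to(np.asarray(sample_rates, dtype=float),
                        (genotypes.n_samples,))
    v = np.broadcast_to(np.asarray(variant_rates, dtype=float),
                        (genotypes.n_variants,))
    if np.any((s < 0) | (s > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(genotypes.calls.shape)
    drop = (u < s[:, None]) | (rng.random(genotypes.calls.shape) < v[None, :])
    out = genotypes.copy()
    out.calls[drop] = MISSING
    return out
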