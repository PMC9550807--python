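"""End-to-end orchestration: simulate -> QC -> relatedness -> linkage ->
homozygosity -> variant filtering -> scores -> association.

Every stage writes its result as plain text (TSV/BED/VCF) into the output
directory, and a manifest records the seed, the full configuration, file
hashes, and stage timings, so that a run is reproducible and auditable
end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .association import compare_groups, freq_correlation, within_family_trend
from .genotypes import GenotypeMatrix
from .homozygosity import ROHParams, detect_roh_matrix, shared_affected_roh
from .linkage import (BitCapExceeded, InheritanceVectors,
                      candidate_linkage_regions, kong_cox_lod)
from .pedigree import Pedigree, effective_status
from .qc import QCThresholds, post_imputation_filter, prs_snp_filter, qc_filter
from .regions import GenomicRegion
from .relatedness import estimate_pihat, estimates_to_frame, expected_vs_observed
from .scores import (compute_prs, risk_allele_dosage, substitute_proxies,
                     unweighted_sum_score, weighted_sum_score)
from .simulate import (DiseaseModel, GeneticMap, default_marker_panel,
                       default_risk_panel, family_templates, inject_missingness,
                       inject_rare_variant, simulate_family_set,
                       simulate_unrelated)
from .variants import annotate_regions, filter_candidate_variants

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_genotypes"]


@dataclass
class RunConfig:
    """All thresholds and sizes of one pipeline run (flat, serializable)."""

    out_dir: str = "famburden_out"
    seed: int = 1
    # simulation sizes
    n_snps: int = 2000
    n_sporadic: int = 23
    n_population_controls: int = 400
    n_control_families: int = 19
    # thresholds (defaults as used throughout the package)
    call_rate: float = 0.95
    maf: float = 0.05
    hwe_p: float = 5e-8
    post_maf: float = 0.01
    post_r2: float = 0.3
    prs_maf: float = 0.01
    prs_quality: float = 0.9
    proxy_r2: float = 0.8
    lod: float = 1.2
    roh_bp: int = 200_000
    exome_af: float = 0.05
    age: float = 50.0
    # performance / density knobs (the default panel is sparse compared
    # with array data, so ROH marker counts scale accordingly)
    linkage_markers: int = 60
    roh_min_snps: int = 15
    carve_bp: int = 25_000_000
    sample_missing_rate: float = 0.01
    variant_missing_rate: float = 0.005

    def to_text(self) -> str:
        return "\n".join(
            f"{k}={v}" for k, v in dataclasses.asdict(self).items()
        ) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs: Dict[str, object] = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key=value): {line!r}")
            k, v = line.split("=", 1)
            k = k.strip()
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            typ = fields[k]
            if typ in ("int", int):
                kwargs[k] = int(v)
            elif typ in ("float", float):
                kwargs[k] = float(v)
            else:
                kwargs[k] = v.strip()
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("call_rate", "maf", "post_maf", "post_r2", "prs_maf",
                     "prs_quality", "proxy_r2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"config {name}={v} outside (0, 1]")
        if self.hwe_p <= 0 or self.hwe_p >= 1:
            raise ValueError("hwe_p must be in (0, 1)")
        for name in ("lod", "roh_bp", "exome_af", "age", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config {name} must be positive")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_genotypes(path: str, fmt: Optional[str] = None):
    """Read genotypes (+pedigree for PED) from ``ped_map`` or ``vcf``."""
    if fmt is None:
        fmt = "vcf" if path.endswith(".vcf") else "ped_map"
    if fmt == "vcf":
        gm, r2 = fio.read_vcf(path)
        if r2 is not None:
            gm.variants["r2"] = r2
        return [], gm
    if fmt == "ped_map":
        prefix = path[:-4] if path.endswith((".ped", ".map")) else path
        return fio.read_ped_map(prefix)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------


def _simulate_inputs(cfg: RunConfig):
    """Build the full synthetic study: families, comparison groups, panels."""
    rng = np.random.default_rng(cfg.seed)
    variants, freqs = default_marker_panel(cfg.n_snps, seed=cfg.seed)
    risk = default_risk_panel(variants, freqs, seed=cfg.seed + 1)
    weights = pd.Series(
        np.log(risk["odds_ratio"].to_numpy()), index=risk["snp_id"].to_numpy()
    )
    mean_l = float((weights * 2 * risk["study_freq"].to_numpy()).sum())
    var_l = float(
        (weights**2 * 2 * risk["study_freq"] * (1 - risk["study_freq"])).sum()
    ) + 1.0
    model = DiseaseModel(weights=weights,
                         threshold=mean_l + 2.326 * np.sqrt(var_l))

    peds, fam_gm, truth = simulate_family_set(
        family_templates(), variants, freqs, seed=cfg.seed + 2
    )
    # ascertainment emulation: within each multiplex family the designated
    # number of affected members are those with the highest liability among
    # the youngest generation, so affection correlates with risk burden
    dos = fam_gm.dosage_frame()
    snps = list(weights.index)
    liab = pd.Series(
        np.nan_to_num(dos[snps].to_numpy(float)) @ weights.to_numpy()
        + rng.standard_normal(fam_gm.n_samples),
        index=fam_gm.samples,
    )
    coseg_info: Dict[str, Tuple[str, int]] = {}
    for k, ped in enumerate(peds):
        if k in (3, 6):
            # two families segregate a dominant fully penetrant haplotype:
            # affection follows carrier status at a random marker
            midx = int(rng.integers(0, len(variants)))
            from .simulate import cosegregating_affection
            cosegregating_affection(ped, truth, midx)
            coseg_info[ped.family_id] = (
                str(variants.iloc[midx]["chrom"]),
                int(variants.iloc[midx]["pos"]),
            )
            continue
        n_aff = sum(m.affection == "affected" for m in ped.members.values())
        cands = [m.id for m in ped.members.values()
                 if (m.age_years or 99) < 65]
        if len(cands) < n_aff:
            cands = list(ped.members)
        top = set(sorted(cands, key=lambda i: -liab[i])[:n_aff])
        for m in ped.members.values():
            m.affection = "affected" if m.id in top else "unaffected"

    # comparison groups
    sporadic = _conditioned_unrelated(
        cfg.n_sporadic, variants, freqs, model, "affected", cfg.seed + 3, "SPO"
    )
    pop = simulate_unrelated(cfg.n_population_controls, variants, freqs,
                             seed=cfg.seed + 4, prefix="CTRL")
    ctrl_members: List[str] = []
    ctrl_peds: List[Pedigree] = []
    if cfg.n_control_families > 0:
        from .simulate import _nuclear_template
        templates = [
            _nuclear_template(f"CF{k:02d}", 1 + k % 2, 0,
                              [62, 60, 33, 30][: 3 + k % 2])
            for k in range(cfg.n_control_families)
        ]
        ctrl_peds, ctrl_gm, _ = simulate_family_set(
            templates, variants, freqs, seed=cfg.seed + 5
        )
        ctrl_members = ctrl_gm.samples
    else:
        ctrl_gm = None

    # merge all genotypes into one matrix
    mats = [fam_gm, sporadic, pop] + ([ctrl_gm] if ctrl_gm is not None else [])
    samples = sum((m.samples for m in mats), [])
    calls = np.vstack([m.calls for m in mats])
    gm = GenotypeMatrix(samples, variants.copy(), calls)

    groups: Dict[str, str] = {}
    for ped in peds:
        for m in ped.members.values():
            groups[m.id] = ("familial_case" if m.affection == "affected"
                            else "unaffected_relative")
    for s in sporadic.samples:
        groups[s] = "sporadic_case"
    for s in pop.samples:
        groups[s] = "population_control"
    for s in ctrl_members:
        groups[s] = "control_family"

    # injected fully penetrant rare variants (as in consanguineous
    # multiplex families): one homozygous, several heterozygous
    inj_rows, inj_gts = [], []
    coseg_pos = coseg_info.get(peds[3].family_id)
    plans = [
        (peds[1], "hom", 0.0206, "MUCX", None),
        (peds[0], "het", 0.0234, "MYOX", None),
        (peds[2], "het", 0.0002, "TCEX", None),
        (peds[3], "het", 0.0159, "MASX", coseg_pos),
    ]
    for k, (ped, zyg, af, gene, where) in enumerate(plans):
        kwargs = {}
        if where is not None:
            kwargs = {"chrom": where[0], "pos": where[1] + 1}
        row, gts = inject_rare_variant(
            ped, truth, zygosity=zyg, gnomad_af=af, gene=gene,
            seed=cfg.seed + 10 + k, age_threshold=cfg.age, genotypes=gm,
            carve_bp=cfg.carve_bp, **kwargs,
        )
        inj_rows.append(row)
        inj_gts.append(gts)
    injected = pd.DataFrame(inj_rows)

    # genome-wide GWAS weight table for the PRS: the risk SNPs with their
    # true log-odds effects plus a background of small-effect markers
    n_bg = min(600, len(variants) - len(risk))
    bg_idx = rng.choice(
        [k for k in range(len(variants))
         if variants.iloc[k]["variant_id"] not in set(risk["snp_id"])],
        size=n_bg, replace=False,
    )
    gwas_ids = list(risk["snp_id"]) + list(
        variants.iloc[bg_idx]["variant_id"]
    )
    vmeta = variants.set_index("variant_id")
    maf = pd.Series(np.minimum(freqs, 1 - freqs),
                    index=variants["variant_id"])
    true_beta = pd.concat([
        pd.Series(np.log(risk["odds_ratio"].to_numpy()),
                  index=risk["snp_id"].to_numpy()),
        pd.Series(rng.normal(0.0, 0.02, n_bg),
                  index=variants.iloc[bg_idx]["variant_id"].to_numpy()),
    ])
    gwas = pd.DataFrame(
        {
            "snp_id": gwas_ids,
            "effect_allele": vmeta.loc[gwas_ids, "alt"].to_numpy(),
            "other_allele": vmeta.loc[gwas_ids, "ref"].to_numpy(),
            "maf": maf.loc[gwas_ids].to_numpy(),
            "quality": np.round(rng.beta(30, 1, len(gwas_ids)), 4),
            "beta": true_beta.loc[gwas_ids].to_numpy()
            + rng.normal(0.0, 0.01, len(gwas_ids)),
        }
    )

    # LD proxy table: nearest panel neighbor of each risk SNP
    ld_rows = []
    for _, rrow in risk.iterrows():
        same = variants[
            (variants["chrom"] == rrow["chrom"])
            & (variants["variant_id"] != rrow["snp_id"])
        ]
        if same.empty:
            continue
        j = (same["pos"] - rrow["pos"]).abs().idxmin()
        ld_rows.append(
            {
                "index_snp": rrow["snp_id"],
                "proxy_snp": variants.loc[j, "variant_id"],
                "r2": round(float(rng.uniform(0.75, 0.99)), 3),
                "risk_allele": variants.loc[j, "alt"],
            }
        )
    ld_table = pd.DataFrame(ld_rows)

    return dict(
        variants=variants, freqs=freqs, risk=risk, model=model, peds=peds,
        truth=truth, gm=gm, groups=groups, injected=injected,
        injected_gts=inj_gts, ctrl_peds=ctrl_peds, gwas=gwas,
        ld_table=ld_table,
    )


def _conditioned_unrelated(n, variants, freqs, model, condition, seed, prefix):
    """Rejection-sample unrelated individuals with the given affection."""
    rng = np.random.default_rng(seed)
    collected = []
    batch = max(4 * n, 200)
    guard = 0
    while len(collected) < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("rejection sampling failed to converge")
        gm = simulate_unrelated(batch, variants, freqs,
                                seed=int(rng.integers(2**31)), prefix="TMP")
        w = model.weights
        dosage = gm.dosage_frame()[list(w.index)].to_numpy(float)
        liab = dosage @ w.to_numpy() + rng.standard_normal(batch)
        want = liab > model.threshold if condition == "affected" \
            else liab <= model.threshold
        collected.extend(gm.calls[np.flatnonzero(want)])
    calls = np.array(collected[:n], dtype=np.int8)
    return GenotypeMatrix([f"{prefix}{k:04d}" for k in range(n)],
                          variants.copy(), calls)


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage on a synthetic study; returns the manifest dict."""
    cfg = config
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: Dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg),
                      "stages": {}, "files": {}}
    t_all = time.time()

    def _stage(name: str, t0: float) -> None:
        manifest["stages"][name] = round(time.time() - t0, 3)

    def _emit(name: str, path: str) -> None:
        manifest["files"][name] = {"path": os.path.basename(path),
                                   "sha256": _sha256(path)}

    # -- simulate -------------------------------------------------------
    t0 = time.time()
    sim = _simulate_inputs(cfg)
    gm: GenotypeMatrix = sim["gm"]
    peds: List[Pedigree] = sim["peds"]
    gm = inject_missingness(gm, cfg.sample_missing_rate,
                            cfg.variant_missing_rate, seed=cfg.seed + 6)
    ped_path, map_path = fio.write_ped_map(
        os.path.join(cfg.out_dir, "simulated"), peds + sim["ctrl_peds"], gm
    )
    _emit("simulated_ped", ped_path)
    _emit("simulated_map", map_path)
    risk_path = os.path.join(cfg.out_dir, "risk_panel.tsv")
    sim["risk"].to_csv(risk_path, sep="\t", index=False)
    _emit("risk_panel", risk_path)
    _stage("simulate", t0)

    # -- qc -------------------------------------------------------------
    t0 = time.time()
    th = QCThresholds(cfg.call_rate, cfg.maf, cfg.call_rate, cfg.hwe_p)
    gm_qc, report = qc_filter(gm, th, pedigrees=peds + sim["ctrl_peds"])
    rng = np.random.default_rng(cfg.seed + 7)
    r2 = np.where(rng.random(gm_qc.n_variants) < 0.7, 1.0,
                  rng.beta(9, 1, gm_qc.n_variants))
    gm_qc.variants["r2"] = np.round(r2, 4)
    gm_qc, post_report = post_imputation_filter(gm_qc, cfg.post_maf, cfg.post_r2)
    qc_path = os.path.join(cfg.out_dir, "qc_report.tsv")
    pd.concat([report.to_frame(), post_report.to_frame()]).to_csv(
        qc_path, sep="\t", index=False
    )
    _emit("qc_report", qc_path)
    _stage("qc", t0)

    # -- relatedness ----------------------------------------------------
    t0 = time.time()
    rel_rows = []
    for ped in peds:
        ids = [i for i in ped.members if i in gm_qc.samples]
        sub = gm_qc.subset(samples=ids)
        ests = estimate_pihat(sub, freqs=sub.alt_freq())
        conc = expected_vs_observed(ped, ests)
        conc.insert(0, "family_id", ped.family_id)
        rel_rows.append(conc)
    rel = pd.concat(rel_rows, ignore_index=True)
    rel_path = os.path.join(cfg.out_dir, "relatedness.tsv")
    rel.to_csv(rel_path, sep="\t", index=False)
    _emit("relatedness", rel_path)
    _stage("relatedness", t0)

    # -- linkage --------------------------------------------------------
    t0 = time.time()
    step = max(1, gm_qc.n_variants // cfg.linkage_markers)
    link_idx = np.arange(0, gm_qc.n_variants, step)
    freqs_qc = gm_qc.alt_freq()
    track_rows = []
    enums: Dict[str, InheritanceVectors] = {}
    for ped in peds:
        try:
            enums[ped.family_id] = InheritanceVectors(ped, cfg.age)
        except BitCapExceeded as e:
            logger.warning("%s", e)
    for k in link_idx:
        vrow = gm_qc.variants.iloc[k]
        p_alt = float(freqs_qc[k])
        if not 0.0 < p_alt < 1.0:
            continue
        row = {"chrom": vrow["chrom"], "pos": int(vrow["pos"]),
               "variant_id": vrow["variant_id"]}
        zs, zmins = [], []
        for ped in peds:
            iv = enums.get(ped.family_id)
            if iv is None:
                continue
            genos = {
                s: int(g)
                for s, g in zip(gm_qc.samples, gm_qc.calls[:, k])
                if s in ped.members and g >= 0
            }
            res = iv.score_marker(genos, p_alt)
            fam = ped.family_id
            if res.informative:
                zs.append(res.z)
                zmins.append(res.z_support_min)
                row[f"z_{fam}"] = res.z
                row[f"lod_{fam}"] = kong_cox_lod([res.z])
            else:
                row[f"z_{fam}"] = np.nan
                row[f"lod_{fam}"] = 0.0
        # combined LOD under the support-bounded linear model
        row["lod_combined"] = kong_cox_lod(zs, z_support_min=zmins) if zs else 0.0
        row["n_informative_families"] = len(zs)
        track_rows.append(row)
    track = pd.DataFrame(track_rows)
    track_path = os.path.join(cfg.out_dir, "linkage_track.tsv")
    track.to_csv(track_path, sep="\t", index=False)
    _emit("linkage_track", track_path)
    link_regions: Dict[str, List[GenomicRegion]] = {}
    for ped in peds:
        col = f"lod_{ped.family_id}"
        if len(track) and col in track.columns:
            fam_track = track.rename(columns={col: "lod"})[
                ["chrom", "pos", "lod"]
            ]
            link_regions[ped.family_id] = candidate_linkage_regions(
                fam_track, cfg.lod
            )
        else:
            link_regions[ped.family_id] = []
    link_bed = fio.write_bed(
        os.path.join(cfg.out_dir, "linkage_regions.bed"),
        [r for rs in link_regions.values() for r in rs],
    )
    _emit("linkage_regions", link_bed)
    _stage("linkage", t0)

    # -- homozygosity ---------------------------------------------------
    t0 = time.time()
    roh_regions: Dict[str, List[GenomicRegion]] = {}
    seg_rows = []
    roh_params = ROHParams(min_snps=cfg.roh_min_snps)
    for ped in peds:
        ids = [i for i in ped.members if i in gm_qc.samples]
        segs = detect_roh_matrix(gm_qc.subset(samples=ids), roh_params)
        for sid, ss in segs.items():
            for s in ss:
                seg_rows.append(dataclasses.asdict(s))
        roh_regions[ped.family_id] = shared_affected_roh(
            segs, ped, cfg.roh_bp, cfg.age
        )
    seg_path = os.path.join(cfg.out_dir, "roh_segments.tsv")
    pd.DataFrame(seg_rows).to_csv(seg_path, sep="\t", index=False)
    _emit("roh_segments", seg_path)
    shared_bed = fio.write_bed(
        os.path.join(cfg.out_dir, "shared_roh.bed"),
        [r for rs in roh_regions.values() for r in rs],
    )
    _emit("shared_roh", shared_bed)
    _stage("homozygosity", t0)

    # -- variant filtering ----------------------------------------------
    t0 = time.time()
    cand_frames = []
    injected: pd.DataFrame = sim["injected"]
    for ped in peds:
        fam_idx = [
            k for k in range(len(injected))
            if injected.iloc[k]["family_id"] == ped.family_id
        ]
        if not fam_idx:
            continue
        fam_rows = injected.iloc[fam_idx]
        gt_cols = pd.DataFrame(
            {m: [sim["injected_gts"][k].get(m, 0) for k in fam_idx]
             for m in ped.members},
            index=fam_rows.index,
        )
        cands = filter_candidate_variants(
            fam_rows.drop(columns=["zygosity"]), gt_cols, ped,
            af_max=cfg.exome_af, age_threshold=cfg.age,
        )
        cands = annotate_regions(
            cands, link_regions.get(ped.family_id, []),
            roh_regions.get(ped.family_id, []),
        )
        cand_frames.append(cands)
    candidates = (pd.concat(cand_frames, ignore_index=True)
                  if cand_frames else pd.DataFrame())
    cand_path = os.path.join(cfg.out_dir, "candidate_variants.tsv")
    candidates.to_csv(cand_path, sep="\t", index=False)
    _emit("candidate_variants", cand_path)
    _stage("variant_filter", t0)

    # -- scores ---------------------------------------------------------
    t0 = time.time()
    risk = sim["risk"]
    risk_sub, sub_log = substitute_proxies(
        risk, list(gm_qc.variants["variant_id"]), sim["ld_table"],
        cfg.proxy_r2,
    )
    sub_log_path = os.path.join(cfg.out_dir, "proxy_substitutions.tsv")
    sub_log.to_csv(sub_log_path, sep="\t", index=False)
    _emit("proxy_substitutions", sub_log_path)
    dosages = risk_allele_dosage(gm_qc, risk_sub)
    w_all = weighted_sum_score(dosages, risk_sub, "all")
    w_non = weighted_sum_score(dosages, risk_sub, "non_mhc")
    u_all = unweighted_sum_score(dosages, risk_sub)

    gwas_f, _ = prs_snp_filter(sim["gwas"], cfg.prs_maf, cfg.prs_quality)
    gwas_f = gwas_f[gwas_f["snp_id"].isin(gm_qc.variants["variant_id"])]
    beta = pd.Series(gwas_f["beta"].to_numpy(),
                     index=gwas_f["snp_id"].to_numpy())
    prs_dos = gm_qc.dosage_frame()[list(beta.index)]
    prs_dos = prs_dos.fillna(prs_dos.mean())
    prs_raw, prs_z = compute_prs(prs_dos, beta)
    groups = sim["groups"]
    fam_status = {
        m.id: m.affection for p in peds for m in p.members.values()
    }
    fam_of = {m.id: p.family_id for p in peds for m in p.members.values()}
    score_table = pd.DataFrame(
        {
            "id": gm_qc.samples,
            "family_id": [fam_of.get(s, "") for s in gm_qc.samples],
            "group": [groups.get(s, "population_control") for s in gm_qc.samples],
            "status": [fam_status.get(s, "") for s in gm_qc.samples],
            "weighted_sum_score": w_all.to_numpy(),
            "weighted_sum_score_non_mhc": w_non.to_numpy(),
            "unweighted_sum_score": u_all.to_numpy(),
            "prs_raw": prs_raw.to_numpy(),
            "prs_z": prs_z.to_numpy(),
        }
    )
    score_path = os.path.join(cfg.out_dir, "scores.tsv")
    score_table.to_csv(score_path, sep="\t", index=False)
    _emit("scores", score_path)
    _stage("scores", t0)

    # -- association ----------------------------------------------------
    t0 = time.time()
    comparisons = [
        ("familial_case", "population_control"),
        ("familial_case", "control_family"),
        ("familial_case", "unaffected_relative"),
        ("sporadic_case", "familial_case"),
    ]
    assoc = compare_groups(
        score_table, comparisons,
        score_types=("prs_z", "weighted_sum_score",
                     "weighted_sum_score_non_mhc", "unweighted_sum_score"),
    )
    assoc_path = os.path.join(cfg.out_dir, "association.tsv")
    assoc.to_csv(assoc_path, sep="\t", index=False)
    _emit("association", assoc_path)

    fam_scores = score_table[score_table["status"] != ""].rename(
        columns={"prs_z": "prs"}
    )
    trend, n_trend, not_comp = within_family_trend(fam_scores)
    trend_path = os.path.join(cfg.out_dir, "family_trend.tsv")
    trend.to_csv(trend_path, sep="\t", index=False)
    _emit("family_trend", trend_path)
    r, r2c = freq_correlation(risk["study_freq"], risk["reference_freq"])
    summary = {
        "n_candidate_linkage_regions": int(
            sum(len(v) for v in link_regions.values())
        ),
        "n_shared_roh_regions": int(sum(len(v) for v in roh_regions.values())),
        "n_candidate_variants": int(len(candidates)),
        "trend_positive_families": n_trend,
        "trend_not_comparable": not_comp,
        "risk_panel_freq_correlation_r": round(r, 4),
    }
    manifest["summary"] = summary
    _stage("association", t0)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    man_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    cfg_path = os.path.join(cfg.out_dir, "config.txt")
    with open(cfg_path, "w") as fh:
        fh.write(cfg.to_text())
    return manifest
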