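"""Common-risk burden scores: weighted/unweighted sum scores over a curated
risk-allele panel, polygenic risk scores from external effect sizes, proxy
SNP substitution, and Z-normalization.

The weighted sum score of an individual over a panel of risk alleles is

    score = sum_i dosage_i * log10(OR_i)

where ``dosage_i`` counts copies (0/1/2) of the risk allele of SNP ``i``
and ``OR_i`` is its published per-allele odds ratio.  MHC-region rows can
be excluded to isolate the non-MHC burden.  The PRS is the plain dot
product of a dosage matrix with externally estimated per-SNP effect sizes,
Z-normalized against a reference set of individuals so that logistic
regression odds ratios are per standard deviation of score.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "validate_risk_table",
    "risk_allele_dosage",
    "weighted_sum_score",
    "unweighted_sum_score",
    "substitute_proxies",
    "compute_prs",
]

RISK_TABLE_COLS = ["snp_id", "chrom", "pos", "risk_allele", "odds_ratio", "is_mhc"]


def validate_risk_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in RISK_TABLE_COLS:
        if col not in table.columns:
            raise ValueError(f"risk-allele table lacks column {col!r}")
    if table["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in risk-allele table")
    if (table["odds_ratio"] <= 0).any():
        raise ValueError("odds ratios must be positive")
    return table


def risk_allele_dosage(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    missing_policy: str = "impute_mean",
) -> pd.DataFrame:
    """Risk-allele dosage matrix (individuals x panel SNPs).

    Genotype calls count the alternate allele; each panel row's risk allele
    must match the variant's ref or alt allele (orientation flips the
    dosage).  Missing calls are imputed to twice the risk-allele frequency
    (``impute_mean``), dropped per individual (``drop``), or rejected
    (``fail``).
    """
    if missing_policy not in {"impute_mean", "drop", "fail"}:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    vmeta = genotypes.variants.set_index("variant_id")
    dos = genotypes.dosage_frame()
    cols: Dict[str, np.ndarray] = {}
    for _, row in table.iterrows():
        sid = row["snp_id"]
        if sid not in vmeta.index:
            raise KeyError(f"panel SNP {sid!r} absent from genotypes "
                           "(run proxy substitution first)")
        ref, alt = str(vmeta.loc[sid, "ref"]), str(vmeta.loc[sid, "alt"])
        risk = str(row["risk_allele"])
        d = dos[sid].to_numpy(dtype=float)
        if risk == alt:
            pass
        elif risk == ref:
            d = 2.0 - d
        else:
            raise ValueError(
                f"risk allele {risk!r} of {sid} matches neither ref {ref!r} "
                f"nor alt {alt!r}"
            )
        if np.isnan(d).any():
            if missing_policy == "fail":
                raise ValueError(f"missing genotype at panel SNP {sid}")
            if missing_policy == "impute_mean":
                mean = np.nanmean(d)
                if np.isnan(mean):
                    mean = 0.0
                d = np.where(np.isnan(d), mean, d)
            # "drop": leave NaN; scores skip per-individual
        cols[sid] = d
    return pd.DataFrame(cols, index=genotypes.samples)


def weighted_sum_score(
    dosages: pd.DataFrame,
    table: pd.DataFrame,
    include: str = "all",
) -> pd.Series:
    """Per-individual weighted sum score: sum of dosage x log10(OR).

    ``include='non_mhc'`` drops MHC-flagged rows (the non-MHC burden).
    ``dosages`` is the risk-allele dosage frame from
    :func:`risk_allele_dosage`.
    """
    table = validate_risk_table(table)
    if include == "non_mhc":
        table = table.loc[~table["is_mhc"].astype(bool)]
    elif include != "all":
        raise ValueError(f"include must be 'all' or 'non_mhc', got {include!r}")
    snps = [s for s in table["snp_id"] if s in dosages.columns]
    if len(snps) < len(table):
        missing = sorted(set(table["snp_id"]) - set(snps))
        raise KeyError(f"panel SNPs missing from dosage frame: {missing}")
    w = np.log10(table.set_index("snp_id").loc[snps, "odds_ratio"].to_numpy(float))
    d = dosages[snps].to_numpy(dtype=float)
    return pd.Series(np.nansum(d * w, axis=1), index=dosages.index,
                     name="weighted_sum_score")


def unweighted_sum_score(dosages: pd.DataFrame, table: pd.DataFrame,
                         include: str = "all") -> pd.Series:
    """Per-individual count of risk alleles over the panel."""
    table = validate_risk_table(table)
    if include == "non_mhc":
        table = table.loc[~table["is_mhc"].astype(bool)]
    snps = [s for s in table["snp_id"] if s in dosages.columns]
    if len(snps) < len(table):
        missing = sorted(set(table["snp_id"]) - set(snps))
        raise KeyError(f"panel SNPs missing from dosage frame: {missing}")
    d = dosages[snps].to_numpy(dtype=float)
    return pd.Series(np.nansum(d, axis=1), index=dosages.index,
                     name="unweighted_sum_score")


def substitute_proxies(
    table: pd.DataFrame,
    genotyped_snps: Sequence[str],
    ld_table: Optional[pd.DataFrame] = None,
    r2_min: float = 0.8,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Replace panel SNPs absent from the genotyped set with LD proxies.

    ``ld_table`` rows: ``index_snp, proxy_snp, r2, risk_allele`` (the risk
    allele of the index SNP mapped onto the proxy's alleles).  The highest-
    r2 proxy with ``r2 >= r2_min`` (inclusive) wins, ties broken by
    lexicographically smallest ``proxy_snp``; a row with a missing/empty
    allele mapping is never guessed — the index SNP is dropped instead.
    Returns the substituted table and a substitution log.
    """
    present = set(genotyped_snps)
    used = {s for s in table["snp_id"] if s in present}
    log_rows: List[Dict] = []
    out_rows: List[Dict] = []
    for _, row in table.iterrows():
        sid = row["snp_id"]
        if sid in present:
            out_rows.append(dict(row))
            continue
        best = None
        if ld_table is not None and len(ld_table):
            cand = ld_table[
                (ld_table["index_snp"] == sid)
                & (ld_table["r2"] >= r2_min)
                & (ld_table["proxy_snp"].isin(present - used))
            ]
            if len(cand):
                cand = cand.sort_values(
                    ["r2", "proxy_snp"], ascending=[False, True]
                )
                best = cand.iloc[0]
        if best is None:
            log_rows.append({"index_snp": sid, "proxy_snp": "", "r2": np.nan,
                             "action": "dropped_no_proxy"})
            continue
        mapped = best.get("risk_allele")
        if mapped is None or (isinstance(mapped, float) and np.isnan(mapped)) \
                or str(mapped) == "":
            logger.warning("proxy for %s has ambiguous allele mapping; dropped", sid)
            log_rows.append({"index_snp": sid, "proxy_snp": best["proxy_snp"],
                             "r2": float(best["r2"]),
                             "action": "dropped_ambiguous_alleles"})
            continue
        new = dict(row)
        new["snp_id"] = best["proxy_snp"]
        new["risk_allele"] = str(mapped)
        used.add(best["proxy_snp"])
        out_rows.append(new)
        log_rows.append({"index_snp": sid, "proxy_snp": best["proxy_snp"],
                         "r2": float(best["r2"]), "action": "substituted"})
    out = pd.DataFrame(out_rows, columns=table.columns)
    log = pd.DataFrame(log_rows,
                       columns=["index_snp", "proxy_snp", "r2", "action"])
    logger.info("risk panel after proxy substitution: %d of %d SNPs",
                len(out), len(table))
    return out, log


def compute_prs(
    dosages: pd.DataFrame,
    beta: pd.Series,
    reference_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.Series, pd.Series]:
    """Raw and Z-normalized polygenic risk score.

    ``dosages`` holds expected effect-allele dosages (fractional allowed)
    with one column per SNP; ``beta`` the externally estimated per-SNP
    effects aligned by column name.  ``prs_z`` standardizes against the
    mean/SD (population SD) of ``reference_ids`` (default: all scored
    individuals); a degenerate (zero-SD) reference is an error.
    """
    missing = [c for c in beta.index if c not in dosages.columns]
    if missing:
        raise KeyError(f"dosage columns missing for PRS SNPs: {missing[:5]}")
    X = dosages[list(beta.index)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PRS dosages must be complete (impute first)")
    raw = pd.Series(X @ beta.to_numpy(dtype=float), index=dosages.index,
                    name="prs_raw")
    ref = raw if reference_ids is None else raw.loc[list(reference_ids)]
    sd = float(np.std(ref.to_numpy()))
    if sd == 0.0:
        raise ValueError("degenerate normalization reference (zero SD)")
    z = (raw - float(np.mean(ref.to_numpy()))) / sd
    z.name = "prs_z"
    return raw, z
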