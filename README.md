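# famburden

Candidate-region mapping and common-risk burden scoring in multiplex,
consanguineous multiple sclerosis (MS) families.

## The problem

In families with several MS cases — particularly where parental
consanguinity is common — disease risk can come from two very different
directions: a rare, highly penetrant variant segregating in the family, or
an unusually heavy load of the common susceptibility alleles found by
GWAS.  Disentangling the two requires running several classic analyses on
the same pedigrees and comparing their results:

1. **Relatedness checking** — method-of-moments IBD estimation (PI-HAT)
   from genotypes, validated against the pedigree expectation `2·φ`
   (kinship coefficient φ), to confirm reported relationships and
   consanguineous unions.
2. **Nonparametric linkage (NPL)** — exact single-point scoring of
   affected allele sharing with the Whittemore–Halpern pairs statistic
   `S_pairs`, standardized as `Z = (E[S|data] − μ₀)/σ₀` over the
   enumerated inheritance-vector space, combined into a Kong–Cox
   one-parameter LOD: `LOD = max_{δ≥0} Σ_f log₁₀(1 + δ·w_f·Z_f)`.
   Runs of markers with LOD > 1.2 become candidate linkage regions.
3. **Homozygosity mapping** — runs of homozygosity (ROH) per sample;
   regions > 200 kb homozygous in *all* affected and in *no* unaffected
   family member (past the late-onset age threshold of 50 years) are
   candidate autozygous regions.
4. **Rare-variant filtering** — exonic variants that are nonsynonymous or
   splice-site, rarer than 5% in a population reference, and fully
   penetrant in the family (all affected carry one zygosity class, no
   eligible unaffected does), annotated by the candidate regions above.
5. **Common-risk burden** — per-individual weighted sum score
   `Σᵢ SNPᵢ · log₁₀(ORᵢ)` over a curated 174-SNP risk panel (165 non-MHC
   + 9 MHC), an unweighted allele count, and a genome-wide polygenic risk
   score `X·β` (Z-normalized), compared across familial cases, unaffected
   relatives, sporadic cases, and controls by logistic regression with
   Wald CIs and Bonferroni correction.

Every stage runs end to end on a built-in synthetic-data generator that
emulates consanguineous multiplex pedigrees (gene dropping under Haldane
recombination, liability-threshold phenotypes, injectable fully penetrant
rare variants), so the whole pipeline is testable without any external
data.

## Worked example

The package ships the per-individual weighted sum score and PRS listing of
six multiplex MS families.  The within-family trend analysis asks, per
family, whether the affected members' mean exceeds the unaffected members'
mean *strictly on both scores*:

```python
from famburden.datasets import load_family_scores
from famburden.association import within_family_trend

summary, count, not_comparable = within_family_trend(load_family_scores())
print(summary.round(4).to_string(index=False))
print("trend-positive families:", count)
```

```
family_id  n_affected  n_unaffected  weighted_mean_affected  weighted_mean_unaffected  prs_mean_affected  prs_mean_unaffected  trend_positive
    FMS01           4             2                  1.8175                   -0.1800             1.7275              -1.2750            True
    FMS02           3             3                  1.3767                    1.3000             1.2200               1.2200           False
    FMS03           3             3                  0.6100                   -0.8500             0.9833              -1.1500            True
    FMS04           4             2                 -0.6775                    0.0850             0.2375              -0.2300           False
    FMS05           3             4                  0.5867                    1.1350            -0.6333              -0.1550           False
    FMS07           3             3                  0.5933                   -0.6933             0.8000              -0.1367            True
trend-positive families: 3
```

Three of the six comparable families (FMS01, FMS03, FMS07) show the
higher-burden-in-cases pattern; note FMS02 fails on an exact PRS mean tie
(1.22 vs 1.22) under the strict rule.  In the remaining families the
common-variant burden cannot explain who is affected — which is precisely
where the rare-variant filtering arm of the pipeline takes over.

A full synthetic run (simulate → QC → relatedness → linkage → ROH →
variant filter → scores → association) is one command:

```bash
famburden run-all --seed 1 --out famburden_out
```

It writes every intermediate as TSV/BED/VCF plus a `manifest.json` with
file hashes, stage timings, and the full configuration; the same seed
reproduces identical hashes.

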