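# Methods

This note documents the models, defaults, and design choices behind each
stage of the pipeline, and what the synthetic-data generator does and does
not emulate.

## Pedigree model and age-dependent status

A pedigree is a parent–child DAG in which consanguineous unions (mates
sharing an ancestor) are permitted and detectable.  Kinship coefficients
are computed by the standard recursion (φ(i,i) = ½(1+Fᵢ); for i≠j, recurse
on the deeper individual's parents), with founders assumed mutually
unrelated and non-inbred.  A configuration hook can seed founder
inbreeding for stress tests; by default there is no founder genealogy
beyond the pedigree itself.  Expected PI-HAT is `2·φ`.

MS is a late-onset disease, so an unaffected relative younger than the
onset-risk threshold (default 50 years) is not evidence against
segregation.  `effective_status` therefore maps young or age-unknown
unaffecteds to `unknown` in linkage and `excluded` in homozygosity mapping
and exome segregation filtering; affected members are always retained.
Treating a missing age conservatively (as young) is a deliberate choice:
it can only reduce false exclusions of candidate variants.

## Synthetic data

The generator defines the conditions under which the pipeline is
validated:

* **Panel** — ~5,000 biallelic SNPs over 22 autosomes of 100 Mb each on a
  uniform 1 cM/Mb map; alternate-allele frequencies uniform on
  (0.05, 0.95).  A dozen positions are guaranteed inside the MHC window
  (chr6:25–34 Mb) so the risk panel can always place its 9 MHC rows.
* **Risk panel** — 174 rows (165 non-MHC with OR ≈ lognormal around 1.1,
  9 MHC rows with OR in 1.3–3.0, matching the field's observation that
  MHC carries the largest MS effects).  Two frequency columns emulate the
  study population and an external reference aggregate; the reference
  column is a Balding–Nichols draw at Fst = 0.01, a typical
  within-continental divergence.  The observed correlation between the
  two columns is therefore a property of that divergence model, not a
  fitted quantity.
* **Gene dropping** — founder haplotypes drawn independently per locus;
  meioses recombine under Haldane's no-interference map function
  θ = (1 − e^(−2d))/2.  The truth record keeps each haplotype's founder
  origin at every marker, which makes true IBD sharing and autozygous
  segments exact and lets tests verify estimators against truth rather
  than against other estimators.
* **Templates** — seven multiplex families: six are three-generation
  pedigrees whose bottom couple are first cousins (the consanguinity
  loop), one is a non-consanguineous nuclear family; 3–4 affected members
  each.  Unaffected ages straddle the 50-year threshold so the exclusion
  rules are exercised.
* **Phenotype** — liability threshold: `L = Σ wᵢ·dosageᵢ + rare term +
  N(0,1)`, affected iff `L >` threshold; with a fully penetrant rare
  dominant (resp. recessive) effect, any carrier (resp. homozygote) is
  affected with certainty.  Affected ages are drawn around 42 ± 10.9
  years and unaffected around 55.4 ± 15.2, mirroring a familial MS cohort
  age structure.  In the end-to-end pipeline demo, affection within most
  families follows within-family liability ranking (emulating
  ascertainment of multiplex families for common-variant burden), while
  two families segregate a dominant fully penetrant founder haplotype
  (emulating a rare-variant family) — this produces both arms of the
  phenomenon the pipeline is designed to separate.
* **Rare-variant injection** — a fully penetrant variant is added per
  selected family: all affected carry it at the requested zygosity, no
  eligible unaffected does (obligate-carrier parents are heterozygous
  under the recessive model).  A homozygous variant is placed inside a
  truly autozygous shared segment; if the family happens to have none, a
  segment is carved into the genotypes (and the truth record) first.
* **Missingness** — per-sample and per-variant Bernoulli masking from one
  seeded generator.

What the generator does **not** emulate: linkage disequilibrium from a
reference panel (markers are independent given the pedigree), X-linked
inheritance, genotyping error (only missingness), population
stratification, and environmental covariates (the liability noise term is
a generic stand-in).  Consequently, passing tests demonstrate correctness
of the algorithms under their stated assumptions, not robustness to
LD-induced pseudo-IBD or batch artifacts in real array data; users of the
relatedness and ROH stages on real data should LD-prune first.

## Genotype QC

Rule order is fixed: sample call rate (< 0.95 removed) → variant MAF
(< 0.05) → variant call rate (< 0.95) → Hardy–Weinberg exact test
(p < 5·10⁻⁸), each removal recorded with its first failing rule so the
report reconciles exactly.  All inequalities are strict, and MAF/call rate
are computed on the retained samples.  The HWE test is the plain
(non-mid-p) exact test conditioning on allele counts; when pedigrees are
supplied it uses founders only, because family members are not independent
draws — a flag restores the all-samples behavior.  Post-imputation
filtering removes MAF < 1% or imputation r² < 0.3 (every variant must
carry an r² annotation; genotyped variants conventionally carry 1.0).  The
PRS SNP filter drops MAF < 1%, quality < 0.9, strand-ambiguous pairs
(A/T, T/A, C/G, G/C), and indels.

## Relatedness

Method-of-moments IBD: per pair, observed IBS0/1/2 counts over co-called
loci are equated to their expectations given IBD state (computed from
allele frequencies), solved sequentially for ẑ₀, ẑ₁, ẑ₂, then clamped to
[0,1] and renormalized — the de-facto convention of the `--genome`-style
estimator.  `PI-HAT = ẑ₁/2 + ẑ₂`.  Frequencies default to founder-based
estimates.  The clamping induces a small upward bias for distant pairs
(mean first-cousin estimates run ≈0.01 above the 0.125 expectation at
5,000 SNPs); this is inherent to the convention and visible in the
recovery numbers.  Pairs with fewer than 100 co-called loci are flagged
unreliable; monomorphic variants are skipped.

## Linkage

Single-point exact NPL replaces multipoint HMM machinery deliberately: the
inheritance-vector space (two meiosis bits per non-founder, cap 22 bits)
is enumerated exactly, every marker likelihood is exact, and everything
has a brute-force oracle.  Marker likelihoods are computed two ways that
are algebraically identical and cross-checked: a vectorized sum over
founder-allele assignments (used when founder slots ≤ 12) and a per-vector
constraint-graph factorization over founder slots (value/parity
propagation; used for larger founder sets).  Multiallelic markers are
supported through the assignment path for fully informative test
configurations.

`S_pairs` (Whittemore–Halpern pairs) is the scoring statistic; the null
mean and SD come from the same enumeration under the uniform prior.
Founder-couple phase symmetry is not exploited — the bit cap compensates,
and the code stays oracle-checkable.  Uninformative markers (constant
likelihood or σ₀ = 0) are skipped with a notice; genotype-inconsistent
markers are flagged rather than crashing.

Kong–Cox LOD maximizes `Σ_f log₁₀(1 + δ·w_f·Z_f)` over δ ≥ 0 by bounded
scalar optimization (tolerance 1e-8); all arguments must stay positive.
The feasible δ range is bounded by, in order of preference: the supplied
per-family minimum achievable standardized score (the linear-model support
bound, which the enumeration provides for free and which caps per-family
LODs), observed negative Z's, or a configurable cap (default 10).  The
pipeline reports per-family LOD tracks bounded by observed Z's (matching
per-family analysis practice) alongside a support-bounded combined track.
Candidate regions are maximal runs of markers with LOD strictly above 1.2.

## Homozygosity

ROH detection uses maximal runs with per-segment allowances (≤ 1
heterozygous, ≤ 5 missing calls, ≥ 25 markers, homozygous boundary
markers) instead of a sliding-window heuristic; the rule is exactly
specifiable and equals a brute-force all-subarrays oracle.  Two
overlapping maximal runs can both be emitted when a het call splits a long
run.  Defaults approximate common window-based tool settings; on the
sparse synthetic panel the pipeline scales `min_snps` down (15) since 25
consecutive markers would span tens of Mb.

"Shared exclusively by the affected" is enforced in both readings: the
region must be homozygous in *every* affected member and overlap *no*
retained unaffected member's ROH (each constraint relaxable by flag).
Zygosity is genotype homozygosity regardless of allele identity across
individuals.  Lengths are `end − start + 1` (1-based inclusive), and the
200-kb threshold is strict.

## Variant filtering

"Fully penetrant" is operationalized per zygosity model: heterozygous —
every affected carries ≥ 1 copy and every retained unaffected carries 0;
homozygous — every affected is homozygous and no retained unaffected is
(heterozygous unaffected carriers allowed by default, as expected for a
recessive allele; a flag forbids them).  A missing population frequency is
treated as rarer than any threshold, with a "not observed" provenance
note.  Population-specific frequencies are carried as annotation only.  A
family with no exome-eligible unaffected member is evaluated on the
affected only and flagged "unopposed".  Region annotation is a
point-in-interval test with inclusive endpoints, attaching the linkage
region's LOD.

## Scores

The weighted sum score uses log₁₀ odds ratios exactly as defined
(`Σ dosageᵢ·log₁₀ ORᵢ`); scores are reported raw (an optional centering is
left to the caller — published listings sometimes appear centered, and the
trend analysis is invariant to any affine transform applied uniformly).
Missing dosages at panel SNPs default to the dosage expectation
(2 × risk-allele frequency); alternatives are drop-per-individual or fail.
Proxy substitution replaces absent index SNPs by their highest-r² proxy at
r² ≥ 0.8 (inclusive), ties broken by lexicographically smallest proxy id,
ambiguous allele mappings dropped rather than guessed, and each proxy used
at most once.  The PRS is `X·β` with externally estimated β taken as
given; Z-normalization uses the population SD over a configurable
reference set (default: all scored individuals).  The MHC flag window is
chr6:25–34 Mb (GRCh37 convention).

## Association

Single-predictor logistic regression (intercept + score), Newton ML to
1e-8, Wald SEs and symmetric-on-log-scale 95% CIs; no covariates and no
relatedness correction — mixed models are not identifiable at these family
sample sizes, so plain logistic regression with that caveat is the
documented choice.  Complete separation returns a flagged infinite-OR
sentinel.  Bonferroni adjustment defaults to m = number of comparisons
within one score type.  The within-family trend rule is a strict mean
comparison on both scores simultaneously (ties count negative); families
lacking scored members on either side are reported as not comparable.
Frequency correlation is the ordinary Pearson product-moment r with
r² = r².

## Problem sizes and numerical choices

The default test-suite and reproduction-script sizes are chosen as the
smallest at which each quantity is statistically meaningful: 5,000
independent SNPs and 50 replicate pairs per relationship class for
relatedness recovery (Monte-Carlo SE ≈ 0.008 for first cousins), 800
dense markers with 10 replicates for 2-Mb ROH recovery, 1,000 permutation
replicates for type-I error (SE ≈ 0.007), and 24 vs 1,272 individuals for
the PRS shift power check.  The end-to-end pipeline demo uses a 2,000-SNP
panel with ~60 linkage markers per family, completing in well under five
minutes on one CPU.  Optimizer tolerances are 1e-8 (Kong–Cox δ, logistic
gradient); oracle-equivalence tests assert agreement to 1e-10; likelihood
ties below 1e-12 relative are treated as uninformative.

## Known limitations

Single-point NPL is less powerful than multipoint at equal marker density;
the ROH detector's allowance rule only approximates window-based tools;
the relatedness estimator inherits the clamping bias noted above; the PRS
arm consumes externally estimated effect sizes and does not model LD; and
the published six-family score listing bundled for the worked example
contains scores as printed (two decimals), so derived means inherit that
rounding.
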