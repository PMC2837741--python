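# Methods

## The statistic

For one biallelic SNP measured on N individuals, let `n_ij` be the mass of
imputation posterior probability assigned to genotype `j` (AA, AB, BB)
summed over individuals whose true genotype is `i`.  Because imputation
programs report probability triplets rather than hard calls, the cells of
this 3×3 table are nonnegative reals and the grand total equals N.  From
the table:

- observed agreement `P_o = (n_11 + n_22 + n_33) / N`,
- chance agreement `P_c = Σ_i (n_i./N)(n_.i/N)` — the diagonal mass expected
  if genotypes were called at random with the same marginal rates,
- imputation quality score `IQS = (P_o − P_c) / (1 − P_c)`.

On integer hard-call tables IQS is exactly unweighted Cohen's kappa
(verified in the test suite against a brute-force kappa to 1e-12).  IQS = 1
iff every off-diagonal cell is zero; 0 means no better than chance;
negative values mean worse than chance.  When `1 − P_c ≤ 1e-12` (all
marginal mass in one genotype, e.g. a monomorphic SNP) the score is
reported as undefined (NaN, serialised "NA"), never coerced to 0 and never
an error: downstream filters simply fail such SNPs, and robustness analyses
exclude MAF ≤ 0.01 where the denominator is unstable.

The chance correction is the entire point.  Raw concordance ("imputation
accuracy", the fraction of maximum-posterior calls that equal the truth)
tends to 1 as the minor allele frequency tends to 0 no matter how little
information the imputation carries, because calling everyone
major-homozygote is almost always "correct".  IQS removes exactly that
artifact.

For two posterior sets `a` and `b` for the same SNP on the same
individuals (two platforms, neither directly genotyped), the table
generalises to `n_ij = Σ_k a_ik b_jk` — each individual contributes the
outer product of their two probability triplets — and IQS is computed from
it identically.  When the two cohorts share no individuals only the
marginal product `N·ā_i·b̄_j` is available; this is a strictly weaker
comparison (per-individual agreement is unobservable) and is offered only
behind an explicit `disjoint=True` flag.

## Companion statistics

- **Accuracy**: argmax-posterior call vs truth, ties broken toward the
  lowest genotype index (a fixed, deterministic rule; imputation programs
  do not document theirs).  The 0.9 confidence threshold is deliberately
  *not* used here.
- **Efficiency**: fraction of individuals whose maximum posterior exceeds
  0.9 — the conventional "callable genotype" rate.
- **Variance ratio** (MACH `rsq_hat` convention): population variance of
  the expected dosage `e_k = p_AB + 2 p_BB` divided by `2 p̂ (1 − p̂)` with
  `p̂ = mean(e)/2`.  The denominator is on the dosage (2-trial) scale; some
  descriptions write "p(1−p)" as allele-scale shorthand.  Both conventions
  (population variance, dosage-scale denominator) are pinned by unit tests
  (dosages (0,2) → ratio 2).
- **Info score** (IMPUTE-style): `1 − Σ_k(f_k − e_k²) / (2N θ(1−θ))` with
  `f_k = p_AB + 4 p_BB` and `θ = Σe_k/2N`.  `f_k − e_k²` is individual k's
  posterior dosage variance, so certain genotypes give exactly 1.  SNPTEST's
  PROPER_INFO is computed differently internally and not published in
  detail; this standard measure stands in for it and is labelled
  `info_score` everywhere.
- **MAF difference**: |estimated − reference| minor allele frequency; NaN
  (fails every filter) when the reference table lacks the SNP.

## Association machinery

The validation protocol needs a per-SNP case/control test that accepts
genotype uncertainty.  We use the 1-df score/trend chi-square on expected
dosage: `statistic = N r²` with `r` the Pearson correlation between dosage
and the 0/1 phenotype.  On certain genotypes this is algebraically the
Cochran–Armitage trend test (verified against the contingency-table formula
to 1e-9 on randomized tables); with uncertain genotypes it is the
first-order equivalent of probability-weighted logistic regression, and at
the null-phenotype validation task the two agree to first order.  Zero
dosage variance yields statistic 0, p = 1, flagged degenerate.

The genomic inflation factor is `λ = median(statistic) / 0.4549…` (the
χ²₁ median).  λ is reported but is knowingly a blunt instrument here: a few
hundred grossly mis-imputed SNPs out of 20,000 produce dramatic genome-wide
false positives while moving the median only a few percent.  Genome-wide
significance is p < 5×10⁻⁸, strict; no multiplicity correction is applied
anywhere (the protocol counts false positives, it does not discover).

## The synthetic cohort generator

`simulate.SimConfig` fully determines every dataset: all draws flow from
one master seed through named `SeedSequence` children (MAF draw, truth,
per-SNP error levels, imputation noise, case/control split, biased-SNP
selection), so identical configs give byte-identical outputs.  Truth
genotypes are i.i.d. Hardy–Weinberg per SNP — calls ~ Binomial(2, MAF) —
with MAF ~ U(0.01, 0.5) by default, matching the validation experiments'
exclusion of rarer SNPs.  No linkage disequilibrium is simulated: every
statistic under test is per-SNP, so LD would add cost without adding
discrimination.  This is the main respect in which the generator is
simpler than real data — passing tests show the statistics behave as
designed per SNP, not that any particular real imputation pipeline achieves
a given IQS.

Three error models:

- `soft_blend(ε)`: rows `(1−ε)·onehot(truth) + ε·π`, `π` the realized
  genotype distribution of the block being corrupted.  Identity:
  IQS = 1 − ε exactly, at any MAF, while `P_o = (1−ε) + ε·Σπ_i²` —
  the sharpest demonstration that accuracy-like measures conflate
  information with allele frequency.
- `random_hardcall(ε)`: keep the true call with probability 1−ε, else draw
  from `π`.  Same expected error rate with sampling noise; used for the
  split-half robustness study (mean IQS recovers 1 − E[ε] to ±0.02 at
  N = 1000 × 1000 SNPs).
- `major_bias(β)`: rows `(1−β)·onehot(truth) + β·onehot(major homozygote)`.
  This mimics cross-platform imputation failure, where hard-to-impute SNPs
  inherit the reference panel's major genotype.  Under HWE marginals the
  resulting IQS is at most `2(1−β)/(2−β)` (0.571 at the default β = 0.6,
  approached as MAF → 0), so every biased SNP falls far below the 0.9
  filter — the filter's effectiveness is analytic, not tuned.

## Experiment protocols and problem sizes

**Cross-platform split experiment** (`run_split_experiment`): the cohort is
halved at random into null "cases" and "controls"; controls keep certain
true genotypes (the denser array), cases are imputed — by default 1% of
SNPs with `major_bias(β=0.6)` and the rest with `soft_blend(ε=0.02)`.
Per-SNP metrics are computed on the case half against truth; the trend test
runs on all SNPs; each filter rule is scored by remaining hits, λ, and
retention.  The package's reference scale is 20,000 SNPs × 2,000
individuals (≈ 8 s on one core), where the unfiltered analysis shows a
grossly distorted tail (hundreds of genome-wide hits from the ~200 biased
SNPs, λ ≈ 1.05–1.10) and the IQS > 0.9 filter removes every false positive
while retaining 99% of SNPs.

A numerical subtlety: blending toward the *realized* case distribution
preserves the case mean dosage exactly while shrinking the within-case
dosage variance by (1−ε)², so well-imputed SNPs carry a small systematic
trend-statistic inflation of ≈ 2/(1 + (1−ε)²) (1.02 at ε = 0.02).  λ after
filtering therefore sits near 1.04 rather than 1.00.  Real imputation
blends toward an external panel frequency, which adds noise instead; the
identity-preserving blend was kept because the exact IQS = 1 − ε mapping is
worth more to the test suite than a perfectly unit λ.

**Split-half robustness** (`run_split_half_robustness`): the cohort is
halved, each half imputed independently under the same per-SNP error level,
and the per-SNP IQS values of the halves are correlated over SNPs with
MAF > 0.01 and defined scores.  With `random_hardcall`, ε ~ U(0, 0.5),
10,000 SNPs and 2,000 individuals per half, the Pearson correlation
exceeds 0.95: between-SNP variance of the error level dominates within-SNP
sampling noise at this depth.  With a single shared ε the correlation
collapses toward 0 — the statistic measures between-SNP heterogeneity, and
a database of per-SNP IQS values is useful precisely because that
heterogeneity is large and stable.

## File formats and conventions

Oxford GEN/SAMPLE and VCF (GP, with GT one-hot fallback) are supported;
genotype columns are (AA, AB, BB) with allele A the first allele of the
input record; positions are 1-based everywhere.  GEN probability rows
within 1e-3 of summing to 1 are renormalised (absorbing 3-decimal files);
rows further off flag the record.  Allele harmonization between two
sources handles swaps (triplet reversal) and strand flips (complement);
A/T and C/G SNPs are strand-ambiguous and excluded by default with a
reason code.  Metrics and the IQS-database interchange format are plain
TSV, round-tripping to 6 decimals, undefined values as "NA".  The database
schema (snp_id, source_platform, target_platform, population, iqs, maf, n)
is this package's own fixed 7-column layout.

## Known limitations

- No LD, no haplotype or reference-panel simulation; the generator
  validates the statistics, not imputation software.
- Per-SNP error models are exchangeable across individuals; real
  imputation error correlates with local haplotype background.
- The trend test has no covariates and no population-structure correction;
  the validation design removes the need (labels are random), but the
  module is not a general GWAS engine.
- IQS values transfer across studies only within a population with a
  stable LD/allele-frequency profile; a database built in one population
  does not filter another.
- BGEN and PLINK bed/bim/fam are not read; use text GEN or VCF.
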