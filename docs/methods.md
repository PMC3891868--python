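# Methods

`audiogene` implements the dry-lab side of a candidate-gene replication
study of quantitative hearing traits: starting from suggestive discovery
GWAS hits, it filters them to candidate genes, derives audiometric
endophenotypes in an independent cohort, adjusts them for sex, age and
genomic relatedness, tests each candidate SNP under four genetic models,
runs a gene-based principal-component test, and profiles audiograms by
genotype. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data studies do and do not show.

## Trait derivation

Air-conduction thresholds are measured in dB at 0.25, 0.5, 1, 2, 4, 6 and
8 kHz. Thirteen traits are derived per individual:

* the 7 single-frequency thresholds;
* three pure-tone averages — unweighted means over the low (0.25/0.5/1 kHz),
  mid (0.5/1/2 kHz) and high (4/8 kHz) bands. 6 kHz enters no PTA but is a
  trait of its own and participates in the PCA;
* scores of the first three principal components of the 7 thresholds.

The PCA runs on the **covariance** matrix of the raw thresholds, before any
covariate adjustment. This was a genuinely open choice: covariance (not
correlation) preserves the dB scale on which audiometric variance is
usually quoted, and raw (not adjusted) thresholds make the first component
an overall-hearing-level axis, which in cohorts with a strong common factor
carries roughly 80% of the variance. Component signs are fixed so every
loading vector has a non-negative sum; higher PC1 then means worse hearing.
Eigenvalue fractions are reported, sum to 1 and are non-increasing.

## Kinship and trait adjustment

Genomic kinship is the centered-and-scaled allele-sharing (VanRaden /
Astle–Balding) estimator,

    K_ij = (1/M) * sum_m (g_im - 2 p_m)(g_jm - 2 p_m) / (2 p_m (1 - p_m)),

with monomorphic SNPs skipped, missing dosages excluded pairwise and
negative eigenvalues clipped to zero (bending, logged). The diagonal is ~1
and a full-sib pair sits near 0.5 — twice the kinship coefficient of 1/4.

Each trait is adjusted once per cohort with the two-stage (GRAMMAR-style)
strategy: a REML fit of `y = Xb + g + e` (X = intercept, sex, age;
`Var(g) = s2_g K`, `Var(e) = s2_e I`) followed by subtraction of the fixed
effects and the polygenic BLUP. The REML likelihood is profiled over the
total variance and maximized in `h2 = s2_g/(s2_g + s2_e)` on [0, 0.99] by
bounded scalar minimization (tolerance 1e-6) on the eigenbasis of K, so
each extra trait costs only O(n) per likelihood evaluation. When K has a
constant eigenvalue spectrum (e.g. K = I) the ratio is not identifiable;
the fit warns and returns the OLS solution with h2 = 0.

Because BLUP residuals are shrunken, naive per-SNP regression on them is
conservative. The test statistic is therefore divided by a scalar
calibration factor gamma — the average over a panel of up to 1000 SNPs of
the ratio between the naive residual-regression score statistic and the
exact mixed-model score statistic. For a centered coded genotype g the
ratio is `(1-h2)^2 * s2 * (g' V0^-1 g) / (g' g * s_r^2)`, which is free of
the phenotype draw. One gamma is estimated **per genetic model**: the
binary dominant/recessive/overdominant codings align differently with the
kinship eigenstructure than raw dosages, and a single additive gamma
demonstrably leaves them anticonservative (empirical alpha 0.07–0.10 in
the null studies) while per-model gammas restore all four models to
0.048–0.055. When no genotype panel is supplied the trace form
`tr(V0^-1 K)/tr(K)` is used. At h2 = 0 every gamma is exactly 1 and the
per-SNP test collapses to plain OLS (betas, SEs and p-values agree to
better than 1e-8).

## SNP association and replication

Codings: additive uses the raw dosage (0..2 effect-allele copies);
dominant, recessive and overdominant first hard-call the dosage at
0.5/1.5 and then code carrier, minor-homozygote or heterozygote status.
Hard-calling imputed dosages for the non-additive models is the
transparent choice where no convention is printed, and is logged. Binary
codings with a non-reference cell under 10 are flagged low-confidence
rather than suppressed. p-values use the large-sample normal reference by
default (n ≈ 500 justifies it); a t reference is available by flag.
Missing genotypes are dropped per test (complete cases).

A discovery hit replicates when the replication beta has the discovery
sign and the replication p-value is below the nominal 5% level. No
correction is applied across the four genetic models — they are not
independent tests. Allele books are reconciled before comparison: a
swapped effect/other pair negates the beta; an irreconcilable pair is an
error.

## Gene-based test

Per gene and trait: (1) the adjusted trait from the stage above; (2) only
intragenic SNPs — positions inside the annotated interval, 1-based
inclusive, no flanking margin; (3) PCA of the individual × SNP matrix of
genotypes hard-called to 0/1/2 (columns centered; raw-dosage PCA behind a
flag), keeping components whose variance fraction strictly exceeds 1/N,
N = intragenic SNP count; if the strict rule selects nothing (e.g. N = 1)
PC1 is kept with a warning; (4) joint multiple regression of the adjusted
trait on the selected scores, with the overall F test as the gene p-value.
Variance explained is reported as 100 × the sum of selected fractions.

## Candidate-gene funnel

Discovery hits are pruned greedily: repeatedly keep the globally
most-significant remaining hit and drop every hit within ±250 kb on its
chromosome (ties break to the smaller position, so the result is
order-independent). Hits with no gene inside the window are gene deserts
and are dropped. Each survivor is assigned its closest gene (distance 0
if intragenic, else the gap to the nearest interval edge); in multi-gene
mode every gene in the window is kept, so one SNP can anchor several
candidates. Genes matching name-exclusion patterns (default `LOC*`,
`FAM*`) or a configurable disease-exclusion list are removed. A candidate
is shortlisted when an antibody is available for expression work **and**
at least one supporting criterion holds (highly suggestive p, similarity
to hereditary-hearing-loss gene families, database-reported inner-ear
expression, pathway link, or suggestive p). Criteria flags are inputs;
the package queries no external databases. Every stage logs in/out counts.

## Audiogram profiles

For one SNP, thresholds at 0.25, 0.5, 1, 2, 4 and 8 kHz (6 kHz excluded
from profiles as printed; re-includable by flag) are adjusted for age and
sex by fixed-effect OLS only — profiles stay on the dB scale of the
audiogram, so no kinship BLUP is subtracted — and stratified into AA/AB/BB
(A = sample major allele, hard calls at 0.5/1.5). Groups under 30
individuals are flagged underpowered (the smallest minor-homozygote group
in the motivating data had 34). Per-group per-frequency means and
standard errors (sd/√n) form the three curves.

The original profiles were classified by eye; the classifier here is an
explicit stand-in, and its two constants are exposed in the API. A class
is called when (a) the BB−AA per-frequency differences agree in sign at
≥5 of 6 frequencies, and (b) the deviating homozygote's across-frequency
composite differs from **both** other groups by more than 1.96 pooled
standard errors (composite = each individual's mean threshold across the
six frequencies, so inter-frequency correlation is handled exactly).
Requiring separation from both other groups is what distinguishes
`deterioration_BB` / `improvement_BB` (BB deviates) from `improvement_AA`
(AA deviates) — a single BB-vs-AA contrast cannot tell these apart — and
it halves the chance-call rate relative to a single contrast. Underpowered
groups force `none`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not any real population. Genotypes: two haplotypes per individual, each a
Gaussian-copula AR(1) latent vector thresholded at per-SNP allele
frequency quantiles — the simplest model with closed-form local LD (note
the latent correlation 0.8 yields adjacent-dosage correlation ≈ 0.57
after thresholding). Relatedness: sibling pairs only, sharing each
haplotype with probability 1/2 (expected kinship coefficient 1/4); richer
pedigrees are out of scope. Defaults: 500 individuals, a quarter of them
in sibling pairs, MAF uniform on [0.05, 0.5], sexes Bernoulli(0.5), ages
uniform on [18, 80] (adults only).

Thresholds follow
`baseline + age*slope + sex*effect + sum(coded genotype * effect)
+ loading*factor + polygenic + noise` per frequency. The default baseline,
age slopes (0.10–0.65 dB/yr, rising with frequency) and male/female
offsets (0–5 dB, rising with frequency) are typical adult audiometric
magnitudes. One common factor (default loading 6 dB everywhere, noise SD
3 dB) reproduces the dominant first principal component of real
audiograms (~80% of variance at the defaults). The polygenic term is
`Z u` over the simulated standardized genotypes with u iid normal — i.e.
multivariate normal with covariance h2-scaled twice-genomic-kinship —
scaled so `h2 = s2_g/(s2_g + noise_sd^2)` per frequency, with independent
draws across frequencies. Injected SNP effects are in dB per coded unit
under any of the four codings and apply to all frequencies.

What the generator does **not** emulate: population stratification,
genotyping error, imputation uncertainty, realistic haplotype diversity,
shared polygenic architecture across frequencies, ear asymmetry, and
clinical exclusions. Passing calibration/power studies on these cohorts
shows the machinery is correct under its own assumptions, not that real
cohorts satisfy them.

## Simulation studies and their problem sizes

`audiogene.studies` packages the operating-characteristic checks run by
`scripts/acceptance.py` and the acceptance tests; all randomness flows
from one seed. Sizes were chosen so the full battery completes in a few
minutes on one CPU:

* gene-test null calibration: 1000 cohorts, n=400, 40 SNPs, latent rho 0.8;
* SNP-test calibration: 1000 trait replicates over 25 genotype cohorts
  (n=400, 500 SNPs, 25% sibling pairs, h2=0.4), 10 panel SNPs × 4 models
  per replicate; kinship and its eigendecomposition are fitted once per
  cohort and reused across trait draws;
* beta recovery: 200 cohorts, n=1000, causal SNP explaining 1% of variance
  at MAF 0.3; h2 recovery: 50 cohorts, n=800, 2000 SNPs, 200 sibling pairs;
* gene-test power: 200 seed-paired cohorts per standardized effect size
  {0.1, 0.25, 0.5} (the causal genotype term has SD = effect × trait SD,
  i.e. beta = effect/sqrt(2pq) per allele), n=500, 40 SNPs;
* profile classifier: 100 replicates each for detection (8 dB recessive
  deterioration, noise 10 dB, n=1000, 500-SNP panel) and false calls
  (genotype-independent traits, h2=0). The detection panel is deliberately
  not tiny: with very few SNPs the profiled SNP's LD block tags a visible
  share of the polygenic background and the "null" stops being null.

In the recovery and calibration studies the common factor is switched off
so the simulated h2 is the trait-level h2; with the factor on, h2 refers
to the noise-plus-polygenic part only.

## Known limitations

* The gamma calibration is scalar per model, not per SNP; SNPs in unusual
  LD or MAF strata may be slightly mis-calibrated.
* The REML fit uses a single relatedness component; dominance kinship,
  GxE and longitudinal structure are out of scope.
* Multi-allelic VCF records keep the first ALT only (warned).
* The profile classifier is an operationalization of a visual judgement;
  its thresholds (5/6 frequencies, 1.96 SE) are conventions, not fitted
  quantities.
* Hard-call thresholds 0.5/1.5 for non-additive codings of imputed
  dosages discard imputation uncertainty.
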