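# Methods

This note documents the models, numerical choices and limitations of
`prsphewas`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and what the synthetic
validation does and does not demonstrate.

## Synthetic cohort model

**Genotypes.** Independent SNPs with allele frequencies drawn uniformly from
`maf_range` (default 0.05–0.5); genotypes are binomial(2, p) per individual
(Hardy–Weinberg equilibrium), with missing calls at `missing_rate`
completely at random. No linkage disequilibrium is simulated between loci
(see Limitations). All draws flow through one `numpy.random.Generator` built
from the config seed; nothing uses global random state, so every generator is
exactly reproducible.

**Disease.** A liability-threshold model: the standardized genetic score over
`n_causal` SNPs (effects drawn standard normal) contributes `h2_liability` of
the variance of a latent liability, the rest is independent standard normal
noise, and individuals above the standard-normal (1 − prevalence) quantile
are cases. The threshold is the theoretical quantile rather than the
empirical one, so the realized case fraction fluctuates binomially around
`prevalence` — which is what a real cohort does. Binary disease scales are
rarely stated in applied papers; the liability threshold is the standard
quantitative-genetics stand-in and makes `h2_liability` interpretable.

**Diagnosis records.** A boolean phecode status table is converted to ICD10
records by sampling one mapped ICD10 code per flagged phecode. Two special
columns exist so the endometriosis case-definition logic (N80.1–N80.9 case;
N80.0-only excluded, as adenomyosis is a distinct disease) is exercised:
`endometriosis` emits one of N80.1–N80.9 and `adenomyosis` emits N80.0.
Misdiagnosis noise adds a random *non-N80* code per individual at the
configured rate: coding noise should not silently flip disease status, since
the point of the generator is a known case/control truth.

**Biomarkers.** Latent values are lognormal with biomarker-specific location
and scale (centred on plausible UK-biobank-like magnitudes). Each individual
has an enrolment and a first-repeat visit; statin users split evenly into an
"enrolment-onward" and a "repeat-visit-only" stratum, reproducing the paired
design from which statin correction factors are estimated. On-statin values
are latent × `statin_effect` × lognormal(0, `statin_noise_sd`) noise; the
default effect 0.75 corresponds to the strong LDL-lowering class of effects,
and noise SD 0.05 keeps the mean on/pre ratio within 0.25% of the effect
(E[ratio] = effect · exp(sd²)). Covariates (age, a Townsend-style deprivation
stand-in, fasting time, inter-visit age gap) are attached but causally inert.

**Female-specific factors.** Menarche, menopause, cycle length, parity, age
at first birth and first-child birth weight are drawn around realistic
centres (13 ± 1.6 y, 50 ± 4 y, 28 ± 3 d, Poisson(1.8), 26 ± 4 y,
7.4 ± 1.2 lb). A configurable fraction (default 5%) is replaced by values
outside the QC windows so the filters are exercised; parities ≥ 4 occur so
the collapsing rule fires. Age-like factors are integer-rounded and birth
weight reported in half-pound increments — as coarse as self-reported data,
and necessary for the proportional-odds model to have a sane number of
categories. A random third of individuals has a second visit (parity may
grow; other factors are re-reported with noise) so the visit-selection rules
(last value for parity, first otherwise) are testable.

**Two-sample GWAS pairs.** Instrument effects on the exposure, γ_j, have
magnitudes uniform on `gamma_abs_range` (default 0.03–0.10) and are oriented
positive: harmonized instrument sets are conventionally expressed on the
exposure-increasing allele, and without this convention "directional"
pleiotropy would be unidentifiable (it averages to zero under random
orientation). Standard errors use the large-sample GWAS approximation
se ≈ 1/√(2 p q N), which makes F-statistics behave as in real summary data.
Outcome effects are `true_b`·γ_j + α_j + noise. Pleiotropy modes: `none`
(α ≡ 0), `balanced` (mean-zero normal), `directional` (mean
`pleiotropy_mean`, default 0.01), `inside_violating` (α correlated 0.7 with
γ, violating the InSIDE assumption that MR-Egger needs). `n_outliers`
instruments additionally receive a common-sign gross shift (`outlier_shift`,
default +0.1 ≈ 20 outcome SEs): common-sign, because a sign-balanced outlier
pair can cancel in the raw IVW estimate and make "adjusted closer to truth
than raw" an ill-posed comparison. The effect-size distribution of real
risk variants is unknown; all of these are config fields, not constants.

Instrument positions are spaced > 2 Mb apart so that the default
distance-based clumping treats them as independent, matching the "unlinked
instruments" premise of the generator.

## GWAS summary-statistics handling

QC follows the conventions of meta-analysing public downloads: rows with
missing beta/SE dropped; p outside (0, 1] dropped (p = 0 cannot be
represented under the record invariant, so p ≤ 0 is removed, not clamped);
duplicated rsIDs resolved keeping the lowest p; missing per-SNP N filled
with the published total; missing allele frequencies filled from a reference
set by rsID with allele alignment (swap → 1 − f, strand flips via
complement). Genomic control computes λ = median((β/se)²)/0.4549 (the 1-df
χ² median) and, only when λ > 1, inflates SEs by √λ and recomputes p —
deflating well-calibrated statistics would be anti-conservative in the other
direction and is standard practice to skip.

Fixed-effect meta-analysis combines cohorts per SNP by inverse variance; the
SNP's N is the sum over the cohorts carrying it. Alleles are harmonized to
the record from the largest-N cohort (ties broken by cohort label), a
deterministic anchor that makes the result invariant to the order in which
cohorts are supplied. SNPs with irreconcilable alleles are dropped and
reported, never silently.

Multi-mapped ICD10 → phecode entries keep the numerically smallest phecode:
the upstream convention ("one combination was selected") does not pin down a
rule, so the package uses one that is deterministic and auditable.

## Genotype tools

The Hardy–Weinberg test is the exact conditional test (probabilities of all
heterozygote counts of the observed parity given the allele counts; p is the
mass of configurations no more likely than the observed one, with the usual
1 + 1e−12 tolerance factor). Variant QC keeps MAF > 5%, missingness < 5%
and HWE p ≥ 1e−6. LD pruning is greedy within sliding windows (50 kb,
advancing 5 variants): the lower-MAF member of any pair with dosage r² > 0.2
is removed, ties broken by removing the later position — plink's internal
order is not reproducible, so a fixed tie-break is used instead. PCA
mean-imputes, standardizes by √(2p(1−p)) and takes exact economy SVD; the
randomized ("approx") variant is unnecessary at package scale and exact SVD
trivially satisfies any agreement tolerance. Component signs are fixed by
making the largest-magnitude loading positive.

PRS scoring follows plink1.9 `--score` defaults: counted-allele mismatches
flip dosage to 2 − d, missing dosages impute at 2 × effect-allele frequency,
and the score averages over 2 × (matched SNPs). Whether the original
analysis averaged or summed is not stated anywhere; averaging is the plink
default and a `average=False` flag provides the sum.

## PheWAS

Phecode case/control tables include every phecode carried by ≥ 100
individuals; controls are simply everyone without the phecode — the phecode
framework's exclusion-range logic is deliberately not applied (the source
design never mentions it) and would be a one-line switch to add. Logistic
fits are maximum likelihood via statsmodels with Wald SEs; non-converged or
separated fits are flagged rows, never silent drops.

Statin machinery: the correction factor is the mean on/pre ratio among
individuals on statins at the repeat visit only, per sex and biomarker.
Which biomarkers to correct is decided by regressing log(pre/on) on the
deprivation index, PCs, age and inter-visit age gap in the same stratum and
testing the intercept at p < 0.05/34 — the published description
("modelling the effect of each biomarker on the log ratio") is ambiguous
about the regression's direction; the intercept test is the reading that has
the right null behaviour (flag rate ≈ α under no statin effect) and high
power under a real multiplicative effect. Correction divides flagged
biomarkers by the factor for individuals on statins at enrolment only;
everything else is returned unchanged. Biomarker PheWAS regresses the
natural log of the (corrected) value; non-positive values are rejected
rather than offset, because a silent offset is not auditable.

Female factors: linear factors (menarche, age at first birth) are
inverse-rank-normal transformed with the Blom offset (r − 3/8)/(n + 1/4)
(ties share average ranks) and fit by OLS; ordinal factors use the
proportional-odds logistic model (statsmodels `OrderedModel`, BFGS,
gradient tolerance 1e−8) with p = 2Φ(−|t|), i.e. t-values compared to a
standard normal, matching the convention used with `polr`. Age at menarche
is an additional covariate for age at first birth. The age covariate is
analysis year − year of birth; the anchor year is a config field
(`analysis_year`) because nothing pins it down.

## Mendelian randomisation

Instrument selection takes p < 5e−8 (strict) and clumps greedily in p
order: with an LD matrix, neighbours within 10 Mb at r² > 0.001 are removed;
without one, a 1 Mb distance-only fallback applies. These are the ecosystem
defaults for this tooling; the source design says only "independent SNPs".
Harmonization aligns outcome records to the exposure effect allele with
sign flips, strand complements, and frequency-based resolution of
palindromic SNPs, dropping them when either frequency lies in (0.42, 0.58).

IVW is fixed-effect with multiplicative random-effects SE inflation when
Q/(k−1) > 1 — the variant that remains significant in the presence of
moderate heterogeneity, matching how overdispersed instrument sets are
conventionally reported; at k = 1 it reduces exactly to the Wald ratio.
MR-Egger orients to positive exposure betas, floors the residual scale at 1
and uses t(k−2) p-values. The weighted median interpolates the ratio at
cumulative weight 0.5 with first-order ratio variances and takes its SE from
a seeded parametric bootstrap. MR-PRESSO compares the weighted leave-one-out
residual sum of squares to parametric simulations under the fitted model;
per-SNP outlier p-values are Bonferroni-corrected over k; the distortion
test compares the raw-vs-adjusted shift against removing random same-size
inlier subsets. All Monte-Carlo p-values use the (1 + #{≥})/(n + 1)
estimator, which is exactly uniform under exchangeability. Multivariable MR
is weighted least squares of outcome betas on the exposure-beta matrix
without intercept; rank deficiency raises an error naming the collinear
exposures. Benjamini–Hochberg FDR is applied independently within each
(direction × method) group.

## Pipeline

`run_all` executes cohort simulation → per-cohort GWAS replicates →
genomic-controlled fixed-effect meta-analysis → PRS weights and scoring →
genotype QC/pruning/PCA → three PheWAS trait sets in the female, male and
female-sensitivity (females without an endometriosis diagnosis) cohorts →
two-sample MR in both directions, and writes TSVs plus a JSON manifest with
every threshold, seed and filter count (input = kept + removed at each
stage). Floats are written at 10 significant digits and the manifest has
sorted keys, so reruns under one seed are byte-identical. The shipped
default profile uses 2 000 individuals × 300 SNPs and two GWAS cohorts of
15k/25k — sizes chosen so a complete run takes seconds while every count
(phecodes above the inclusion threshold, instruments surviving filters)
stays comfortably non-degenerate. The package's command-line entry points
(`prsphewas run/simulate/phewas/mr`) are thin wrappers over these library
functions.

## What the synthetic validation shows — and does not

Passing tests demonstrate that each stage recovers the quantities it is
pointed at under the generator's assumptions: independent instruments,
normal sampling error at the stated GWAS sizes, multiplicative statin
effects, a logistic phecode link. They do not demonstrate robustness to LD
between instruments, population stratification or assortative mating
(no stratification confounder is generated), winner's-curse in instrument
selection, sample overlap between exposure and outcome GWAS, or phenotype
misclassification structure beyond uniform coding noise. The LD-aware
clumping path is exercised with constructed LD matrices only.

Other known limitations: no liftover between genome builds; no ICD9
mapping; no relatedness handling (cohorts are assumed pre-filtered to
unrelated individuals); GSMR/HEIDI and LD-score genetic correlation are out
of scope because they require individual-level LD reference data or
precomputed LD scores; Bayesian shrinkage of PRS weights is consumed as an
input (a weight table), not re-estimated.
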