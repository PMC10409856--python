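# Methods

Statistical models, parameter defaults, and numerical choices, stage by stage.
Notation: genes *g*, samples *j*; BH denotes Benjamini–Hochberg step-up FDR
control, applied at q < 0.05 unless stated otherwise.

## Core statistics (`stats.py`)

**BH FDR.** `bh_fdr` implements the step-up definition
q(i) = min over j ≥ i of min(1, m·p(j)/j) on the sorted p-values. `NaN`
inputs propagate to `NaN` outputs and are excluded from *m*, so partially
missing test columns do not deflate the correction.

**Fisher exact test.** Delegates to `scipy.stats.fisher_exact` (two-sided,
"probability at most that observed" rule). The returned odds ratio is the
sample ratio ad/bc (∞ when b·c = 0 with a·d > 0, `NaN` with a degenerate
margin, where p = 1 by convention).

**HWE exact test.** Conditional on observed allele counts, heterozygote-count
probabilities are built by the stable two-sided recurrence from the modal
count; p is the summed probability of configurations no more probable than
the observed one. Monomorphic sites return p = 1.

**Trend in proportions.** Cochran–Armitage chi-square with 1 df, computed as
in R's `prop.trend.test`: the weighted-regression sum of squares of the score
term divided by p̄(1 − p̄). Default scores are 1..k.

**Quantile normalization.** Columns are replaced by the across-column means
of order statistics. Ties are broken by stable *ordinal* ranks rather than
rank averaging, which makes the operation exactly idempotent and preserves
within-column order; the tie-averaging variant used elsewhere (e.g. limma) is
not idempotent.

**Batch adjustment.** Parametric empirical-Bayes location(/scale) adjustment
in the ComBat style: gene-wise batch means (and variances in `mean-variance`
mode) are shrunk toward their across-gene priors by the standard iterative EB
update, then removed. Every batch needs ≥ 2 samples.

**Effect pooling.** Fixed-effect inverse-variance pooling on the log scale.
Printed odds-ratio summaries are converted with se = (ln U − ln L)/(2·1.96),
the standard back-transformation of a 95% Wald CI.

## Differential expression (`diffexpr.py`)

Counts are modeled as NB(μ_gj, φ_g) with log link,
log μ_gj = log s_j + x_jᵀβ_g, where s_j are median-of-ratios size factors
(geometric-mean reference over genes with all-positive counts) entering as
offsets. Fitting is iteratively reweighted least squares on the natural-log
scale; reported coefficients are log2 fold changes. The linear predictor is
clipped at ±30 to avoid overflow; non-convergence is flagged and the gene's
tests are `NaN`.

**Dispersion.** Per-gene dispersion maximizes the Cox–Reid adjusted profile
likelihood APL(φ) = ℓ(φ; β̂(φ)) − ½ log det(XᵀWX). At the pipeline's sample
sizes (5 + 5), raw per-gene APL maxima are noisy enough to inflate the null
LRT type-I rate to 0.075–0.11; with the true dispersion the rate is 0.055, so
the inflation is purely estimation noise. `run_de` therefore uses tagwise
weighted-likelihood shrinkage toward the common dispersion —
maximize APL_g(φ) + (d₀/d_res)·mean_g APL_g(φ) with prior weight d₀ = 10
residual-df equivalents on a 17-point log grid with quadratic interpolation —
which restores the null rate to ≈ 0.05. `fit_nb_gene` with
`dispersion=None` still exposes plain per-gene CR-APL estimation.

**Testing.** The LRT compares nested fits sharing the full-model dispersion;
the statistic max(0, 2Δℓ) is referred to chi-square with df equal to the
parameter difference. `test="disease"` drops the disease term from the
additive model; `test="interaction"` adds disease × population to it. Genes
with total count < 10 are excluded before testing.

**Classification.** With BH q-values within each test:
*shared* = significant in both diseases with equal nonzero direction;
*sca_specific* = significant in SCA and in the interaction test, with no
nominal comparator evidence (p ≥ 0.05); remaining genes fall to *ce_only*,
*interaction_only*, or *null*. Later rules override earlier ones, so a gene
meeting both the shared and SCA-specific conditions is called shared.

## Stage concordance (`stages.py`)

For each maturation transition (ProE–EB, EB–LB, LB–Poly, Poly–Ortho), the
evaluable genes are DE genes (nonzero DE direction) whose transition change is
significant; concordance is direction agreement. The decrease of the
concordance proportion across ordered transitions is tested with the trend
chi-square using evaluable-n weights and scores 1..4; transitions with zero
evaluable genes are excluded with a warning. Transition-profile clustering
uses average-linkage hierarchical clustering under correlation distance;
zero-variance profiles go to a reserved flat cluster (label 0) because their
correlation is undefined.

## Deconvolution (`deconvolution.py`)

The erythroid signature is the first principal component of the 16 marker
genes (gene-centered), scored per sample, standardized to zero mean and unit
variance, and oriented so the mean marker loading is positive. Unit variance
fixes the scale of all downstream interaction coefficients, making planted
and estimated effects directly comparable.

Candidate genes must first show a positive association with the signature
(BH q < 0.05 on the one-sided-by-sign slope) — only genes with an erythroid
component can be deconvolved. For each gene and hydroxyurea stratum the OLS
model of the README is fit on non-transfused samples (≥ 10 per stratum);
`q_pheno` is the within-stratum quartile code (0–3) of hemoglobin or
hematocrit, with cuts from non-transfused samples and a value equal to a cut
assigned to the lower quartile (`searchsorted(..., side="left")`). The
interaction is tested by the 1-df F test (identically the squared t). Strata
are pooled by inverse variance and BH-corrected; a gene is *called* when the
pooled interaction is significant for both hemoglobin and hematocrit with
agreeing signs. The per-stratum scans share one design matrix across genes
and are solved vectorized.

## eQTL mapping (`eqtl.py`)

QC order: samples with genotype call rate < 0.95 are dropped first, then SNPs
failing the HWE exact test (p < 1e-4) or MAF < 0.01 are removed; the eQTL
stage additionally requires MAF > 0.1 and imputation r² > 0.9. Surviving
missing dosages are mean-imputed; the filter is idempotent.

Local SNPs lie strictly within 100 kb of either gene end: with BED 0-based
half-open coordinates and 1-based VCF positions, the first body base is
start + 1, distance is 0 inside the body, and a SNP exactly 100,000 bp away
is excluded. Per gene–SNP pair the OLS model
y = α + x_ery·b₁ + dose·b₂ + (x_ery·dose)·b₃ + SVs + ε is fit and b₃ tested
(F = squared t, 1 df); BH correction is applied study-wide over all pairs.

Surrogate variables are the leading right-singular vectors of expression
residualized on known covariates, with the number of components chosen by the
Buja–Eyuboglu permutation criterion (singular values exceeding the 95th
permutation percentile, 20 permutations).

## Cohort association (`assoc.py`)

Per cohort, logistic regression (statsmodels binomial GLM) of the binary
severe-pain outcome on allele dosage adjusted for age, sex, and
α-thalassemia copy number, with Wald SE/p. Fitted |β| > 10 raises a
separation error rather than reporting a meaningless estimate. Cohorts are
pooled by fixed-effect inverse variance; an optional Bonferroni flag marks
pooled p < 0.05/m for a caller-declared m tests. Printed per-cohort OR/CI
cells can enter the same pooling via `result_from_summary`.

## Enrichment (`enrich.py`)

Each gene set is intersected with a caller-supplied universe (never inferred
from the GMT, since odds ratios depend on it) and tested by Fisher's exact
test on the hit × membership table, with BH across sets; sets empty after
intersection are skipped with a log entry.

## Synthetic data (`simulate.py`)

One master seed, with independent named substreams per stage
(CRC32-of-name spawn keys), so stages are reproducible independently.

- **Counts**: NB with gene means log-normal around 200, dispersions
  log-normal around 0.1, sample depths log-normal (σ = 0.2). Planted classes:
  disease main effects (shared), pure disease × population interactions
  (SCA-specific), and independent population effects, all at
  ±`effect_log2fc`.
- **PBMC expression**: a latent erythroid fraction Beta(2, 5)·0.2 per sample
  (a minority component); its standardized score drives the markers through
  positive loadings of unit joint norm scaled by 4, so PC1 of the markers
  recovers the latent score on the same unit-variance scale the analysis
  standardizes to — planted interaction coefficients are therefore directly
  the estimands. Hemoglobin is N(86, 14) g/L; ~13% of samples are flagged
  transfused; hydroxyurea is balanced.
- **Genotypes**: Hardy–Weinberg dosages at allele frequency 0.29, SNPs placed
  in gene bodies and flanks plus decoys beyond the window; imputation r²
  uniform on (0.91, 1.0). Planted eQTL effects reuse `effect_log2fc`; tests
  use β = 0.3, chosen by a power calculation (SE(β̂) ≈ 0.038 at n = 151,
  noise SD 0.3, so β = 0.3 gives z ≈ 8 and > 99% study-wide recovery, while
  β = 0.15 would be marginal under BH).
- **Cohorts**: outcomes from logit P = b₀ + ln(OR)·dose + small covariate
  effects with b₀ targeting 30% prevalence; default sizes (399, 207, 168).
- **Stage fixture**: per-transition directions agree with per-gene DE
  directions at planted rates (0.82, 0.83, 0.70, 0.52), with 90% of
  transitions significant.

Limitations of the generators: genes are independent (no co-expression or LD
beyond per-gene SNP placement), library-size effects are purely
multiplicative, the erythroid fraction acts linearly on log expression, and
cohort covariates are independent of dosage — adequate for verifying
estimator properties, not for benchmarking against real data.

## Verification

`tests/test_acceptance.py` checks, in order: reproduction of the pooled OR
1.7 (1.3–2.2) from the three per-cohort summary cells; the derived summary
arithmetic (1226/11,813 → 10.4%, 300 + 153 → 453); exhaustive-enumeration
oracles for the Fisher and HWE exact tests on all tables with n ≤ 40, the
step-up definition for BH, and a WLS matrix oracle for the trend test
(1e-10); null NB LRT type-I fraction within [0.03, 0.07] at 2000 genes and
5 + 5 samples, plus Poisson-limit coefficient agreement with statsmodels to
1e-6; unbiased recovery of the planted deconvolution interaction
(β = 0.05, n = 150, 200 replicates) and KS-uniform null interaction p-values;
eQTL recovery in ≥ 80 of 100 replicates with a permuted-genotype null near
5% nominal positives; ≥ 90% classifier recovery of planted shared and
SCA-specific genes; and concordance proportions within binomial bounds of the
planted rates with the decreasing trend detected.
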