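# Methods

This note records the statistical model, the generative model behind
the synthetic cohorts, the numerical choices, and the design decisions
taken where the procedure was genuinely open.

## Outcome model

All biomarker models are ordinary least squares on the natural log of
plasma F2-isoprostanes (FiP, pg/mL); FiP is treated as log-normal.
For a categorical exposure (genotype, score tertile, joint GRS cell)
the model is

    ln FiP_i = α + Σ_k γ_k · 1[cat_i = k] + x_i'δ + ε_i

with the lowest/reference category omitted. The *adjusted geometric
mean* of category k is `exp(lsmean_k)`, the least-squares mean
evaluated with every covariate at its analytic-sample mean;
categorical covariates enter as treatment-coded dummies and are held
at their observed proportions. The 95% CI is
`exp(lsmean ± t_{0.975,df} · SE)` with `SE = sqrt(x'Σx)` from the
coefficient covariance. Without covariates this reduces exactly to the
raw per-group geometric mean and the closed-form t-interval on the log
scale (tested against that closed form).

The *proportional difference* between a comparison and a reference
mean is `(comparison − reference)/reference × 100`, reported to one
decimal. It is anti-monotone in the reference and zero iff the means
are equal.

Two p-values accompany each category table: the highest-vs-reference
contrast p (the headline, matching how a single p is usually printed
beside the top-category difference) and a median-scored ordinal trend
p. Both are two-sided; 0.05 is the conventional significance line.

## Hardy-Weinberg exact test

Conditional on the observed allele counts, the heterozygote count
under equilibrium has the distribution

    P(h | n, m) ∝ n! / (hom_r! h! hom_c!) · 2^h

over counts h with the parity of the minor-allele count m. The
two-sided p-value is the total probability of all heterozygote counts
no more probable than the observed one. Probabilities are computed by
the stable ratio recurrence between adjacent counts, anchored at the
mode and normalized; against an exact-integer enumeration the p-values
agree to ~2 × 10⁻¹⁵ relative over every table with total ≤ 200.

Numerical choice — **tie tolerance**: counts whose probability is
within a factor 1 + 10⁻⁹ above the observed probability still count as
"as extreme". Exactly tied counts (symmetric configurations) are
therefore never split by floating-point rounding; the tolerance is far
above arithmetic error and far below any genuine probability gap.

Monomorphic SNPs return p = 1. The test is symmetric in allele
labels. HWE failure is *reported* (flag + p), not acted on, because
the procedure specifies testing but no exclusion action; an optional
`hwe_exclude_alpha` switch drops failing SNPs for sensitivity
analyses. The exact test is the default because collapsing triggers
precisely when cells are sparse — where the chi-square approximation
(provided as a comparator) is least trustworthy.

## Sparse-genotype collapsing

If the heterozygote **or** the variant-homozygote cell holds ≤ 10
participants, the two variant-containing categories merge into one
carrier category; the common homozygote is never merged. "Either
genotype" is read as either *variant-containing* genotype. The
threshold compares with ≤, so a cell of exactly 10 collapses and 11
does not.

## GRS selection and scoring

Per SNP, the genotype model above (covariates: sex, BMI) yields a
proportional difference and a contrast p for each variant category
versus the common homozygote. A SNP enters the pathway score when
**any** variant category satisfies the pathway rule on the *absolute*
proportional difference — AE: (|Δ| > 5%, p ≤ 0.05) or (|Δ| > 10%,
p ≤ 0.15); BER: (|Δ| > 10%, p ≤ 0.15) — with the magnitude strict and
the p non-strict, mirroring how the thresholds are printed. The
absolute value matters: inversely associated variants enter with
negative sign (score category medians can be negative). The sign
comes from the qualifying category with the largest |Δ|; conflicting
qualifying signs resolve toward the larger magnitude with a warning.

Scoring: dosage-coded SNPs contribute sign × (0/1/2); carrier-coded
SNPs contribute sign × (0/1), since collapsing erases the het/hom
distinction. Missing genotypes contribute 0 by default (subjects with
heavy missingness were already excluded upstream); mean-dosage
imputation is available. |score| is bounded by Σ(2 per dosage SNP,
1 per carrier SNP).

Design decisions: the *category-specific* contrast p is used for
selection, not the omnibus F — the rule pairs a p with each
proportional difference, which is category-specific; the omnibus
alternative is switchable. No multiple-testing correction is applied
in selection, faithfully to the pilot design — a caveat users should
understand (see "False-positive behavior").

### False-positive behavior of the selection rule

For a single variant-category contrast under the null, the selection
probability is at most the rule's p-threshold (0.15 for the BER rule);
the magnitude condition can only lower it. But a SNP with *two*
non-sparse variant categories is selected when **either** qualifies, a
union of two correlated tests, so its per-SNP null selection rate can
reach roughly twice the threshold. Measured at n = 245, MAF 0.3,
residual SD 0.35 (variant-homozygote cell ≈ 22, above the collapse
threshold): ≈ 0.17–0.19 per-SNP over 500 replicates, versus ≤ 0.15
when the SNP collapses to a single carrier contrast (e.g. MAF 0.1).
Both regimes are property-tested. This is a real feature of the
published rule, not an implementation artifact.

## Oxidative balance score

Continuous components are z-scored within study × sex strata using the
sample SD (n − 1) — the denominator is unstated in the source
procedure; the sample SD is the conventional choice and is pinned for
reproducibility. Categorical lifestyle components enter as dummies
against their first (referent) level. One joint multivariable OLS of
ln FiP on all 17 components (the "multivariable linear regression" is
read as a single joint model, not 17 marginal ones; a per-component
option exists) gives β per 1 SD (continuous) or per level
(categorical). Weight = 10 × β; the factor 10 is cosmetic and
configurable. Collinearity is checked (rank, condition number, VIF).

**Orientation.** The score is the *negated* weighted sum,
`OBS_i = −Σ_j w_j x_ij`. Summing +10β-weighted values would make
higher scores track higher predicted FiP, the opposite of the stated
"higher score = antioxidant predominance" convention, so the global
negation enforces it; it is switchable (`negate=False`) and logged.
Consequence (tested to machine precision): OBS correlates exactly −1
with the fitted linear predictor minus intercept.

The fitted scorer stores the training strata means/SDs, so new cohorts
are scored on the training scale; a stratum unseen at fit time is an
error, not a silent refit.

## Categories, strata, joint cells

Tertiles cut at the empirical 1/3 and 2/3 quantiles with ties
unsplit — every copy of a tied value lands in one category, so integer
scores produce unequal tertile sizes, and heavy mass on one value can
leave a middle tertile empty (reported as such, not an error).
Dichotomies cut at an integer cutpoint, low < c ≤ high. GRS category
models adjust for sex and the OBS; OBS category models adjust for
total energy, sex, current HRT use (women; men are structural
non-users), education and regular NSAID use. Complete-case handling
throughout — records missing a model variable drop from that model.

The interaction p for effect modification comes from a pooled model
adding (GRS dichotomy) × (OBS tertile as a single ordinal 1–3 term),
two-sided Wald test; "dichotomized GRS × OBS tertiles" is ambiguous
between one ordinal term and two dummy interactions, so both are
computed and the ordinal version is the headline. The joint analysis
fits the four AE × BER cells with the joint-low cell as reference,
adjusted for sex and OBS.

## Synthetic cohorts

The generator emulates a pooled pair of cross-sectional studies:

* Genotypes: Binomial(2, MAF) per SNP — Hardy-Weinberg proportions —
  with multiplicative planted effects on the FiP geometric mean per
  variant allele; missing genotypes inserted MCAR after the phenotype
  is generated (assay-failure missingness; the true mechanism in such
  studies is unknown).
* ln FiP = baseline + Σ dosage·ln(effect) + Σ exposure βs +
  N(0, noise_sd); the noise-free linear predictor is retained as
  per-subject truth.
* Continuous exposure components: multivariate normal z-scores with a
  configurable exchangeable correlation (default 0 — no source for the
  real covariance, and independence keeps recovery tests
  interpretable), mapped to raw scale by per-stratum mean/SD.
* Categorical lifestyle components: multinomial draws with planted
  per-level log-linear effects; continuous BMI is drawn consistently
  with the drawn BMI category.

Default conditions mirror the pooled analytic sample where values are
known: n = 245, male fraction 0.457, first-study fraction 151/245,
HRT prevalence among women 0.56, baseline geometric-mean FiP ≈ 80
pg/mL, residual SD of ln FiP 0.35, genotype missingness 2%. Component
means/SDs loosely follow the reported dietary intake table; their
scale is immaterial because the pipeline re-standardizes. The default
SNP panel is a synthetic stand-in (plausible gene symbols, synthetic
rsIDs, common-variant MAFs).

What the generator does **not** emulate: linkage disequilibrium,
population stratification, FFQ measurement error, real
exposure–exposure or exposure–genotype correlation, or informative
missingness. Passing recovery tests therefore demonstrate that the
estimation machinery is correct under the stated generative model —
not that the scores would behave identically on real cohort data,
where confounding and LD can move estimates.

## Gene-level genotype-missingness exclusion

The cascade excludes participants "missing genotyping on more than 20%
of the panel genes". When a gene counts as missing is not defined by
the source; here a gene is missing for a participant when **all** of
its SNPs are uncalled (the whole-gene assay-failure pattern), and the
20% is a strict inequality over the panel's genes. The per-gene
criterion is configurable. Exclusions are attributed sequentially to
the first matching rule; because every rule is record-local, rule
order changes attribution only, never the final retained set (tested).

## Problem sizes in tests and validation

Recovery experiments run 500 replicates at the analytic sample sizes
(n = 245 for selection scenarios, n = 386 for OBS weight recovery),
with binomial Monte-Carlo standard errors attached to every simulated
rate; the dose-response monotonicity property uses 200 replicates of a
12-SNP score at n = 245; the Hardy-Weinberg cross-check sweeps all
~692,000 genotype configurations with total ≤ 200. These sizes were
chosen to match the emulated study and keep every check reproducible
in minutes on one CPU.

## Known limitations

* Selection inherits the pilot design's lenient, uncorrected
  thresholds; the per-SNP false-positive rate is characterized above
  but not corrected.
* The OBS weight model assumes linear, additive component effects on
  ln FiP; no interactions or splines.
* Cross-sectional only: no survival or longitudinal models, single
  biomarker outcome.
* The exact HWE test covers autosomal bi-allelic SNPs; multi-allelic
  and X-linked variants are out of scope.
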