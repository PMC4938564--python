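# Methods

## Variant catalog and scores

The packaged catalog (`data/table1_catalog.tsv`) lists 94 common breast-
cancer susceptibility variants with their published per-allele odds
ratios, the risk-allele frequency observed in the genotyped chemotherapy
cohort, and the imputation quality r² (1 for directly genotyped variants).
The per-allele weight β = ln(OR) is derived at load time and never stored,
so the fixture and the computation cannot drift. Odds ratios are kept
exactly as printed (2–3 decimals); the catalog does not distinguish the
two effect-size provenances the table mixes (covariate-adjusted estimates
for the original 77 loci, unadjusted meta-analysis estimates for 17 newer
loci) because the analysis treats them uniformly. Positions are 1-based
build 37; no liftover.

Scores are plain and β-weighted sums of risk-allele dosages. Under
Hardy-Weinberg (dosage ~ Binomial(2, p)) the analytic moments are
mean Σ2p, variance Σ2p(1−p) (non-weighted) and mean Σβ·2p, variance
Σβ²·2p(1−p) (weighted); for this catalog the weighted SD is 0.4568 and the
non-weighted mean/SD are 87.1/5.87. Missing dosages are mean-imputed with
2p by default (keeps cohort moments unbiased); `skip` and `fail` policies
are available. Standardisation uses the analysis cohort's sample SD
(ddof 1), matching the per-SD reporting convention.

## Synthetic cohorts

The generator emulates the cohort the analysis was designed for; its
defaults are the study conditions, not tuning knobs:

- **Genotypes**: independent Binomial(2, p) dosages at the catalog
  frequencies. Independence across variants is a simplification — real
  loci have LD neighbours, but the catalog's variants are genome-spread
  index SNPs, so cross-variant correlation is negligible for score-level
  behaviour.
- **Imputation noise** (r² < 1): D = 2p + r²(G − 2p) + e, with
  e ~ N(0, r²(1−r²)·2p(1−p)), clipped to [0, 2]. The construction is ours;
  it reproduces the two properties that matter downstream, Var(D) = r²·2p(1−p)
  (variance deflation) and corr(D, G) = r, before clipping. Clipping
  shaves a little additional variance from rare, poorly imputed variants.
- **Toxicity**: binary first — case indicators from
  logit P = α + θ(s − s̄) on the non-weighted score, with α solved by
  Brent root-finding so the marginal case rate hits the target prevalence
  (0.30 by default) to 1e-6 in expectation; grades second — drawn within
  the case/control strata in proportion to the observed grade counts
  (neutropenia 733:199:245 controls, 293:206 cases; neuropathy 271:648
  controls, 304:56 cases), so marginal grade distributions are matched in
  expectation and a case can never get a control-stratum grade. The
  default θ = ln 0.98 per allele; effects on the weighted score are
  whatever this induces (weighting genuinely changes the estimand).
- **Covariates**: age ~ N(50, 8²) on [25, 75], BMI ~ N(26, 4.5²) on
  [16, 45], trial multinomial (0.40/0.30/0.27/0.03 across the three trial
  arms and a non-trial stratum), PC1/PC2 ~ N(0, 1). These are plausible
  defaults for an early-breast-cancer trials population; the generator
  draws them independently of genotype, so adjusted and unadjusted fits
  should agree on synthetic data — which is itself a tested property.
- **Survival**: exponential event times with hazard
  h₀·HRᵖᵉʳ ᵃˡˡᵉˡᵉ^(s − s̄), h₀ = 0.05/yr, HR 1.02/allele by default;
  independent exponential censoring with its rate set so the censored
  fraction is approximately the configured 0.7. Real relapse-free survival
  is not exponential and censoring is administrative, but a Cox fit only
  needs proportional hazards, which this satisfies exactly.

One `SeedSequence` per run spawns independent per-stage streams: outputs
are bit-identical given (config, seed), and stages can be rerun alone.

What passing tests on these cohorts shows: the estimators recover the
parameters the generator injects, at the study's n, under the model the
analysis assumes. What it does not show: robustness to LD, genotyping
batch effects, population stratification confounding, non-proportional
hazards, or informative censoring — none of which the generator emulates.

## Quality control

Filters mirror standard array QC: variant fails iff missingness > 5%,
MAF < 1%, (MAF < 5% and missingness > 1%), or HWE exact p < 1e-5; sample
fails iff > 10% of variants missing. All thresholds are strict
inequalities, so boundary values (exactly 5%/1%/10%) pass; missing
fractions are computed as integer-count ratios to keep those boundaries
exact in floating point. MAF comes from the non-missing dosage mean,
folded at 0.5. Variant and sample filters are iterated to a fixed point,
which makes the result order-independent.

The Hardy-Weinberg test is the exact conditional test: given the
minor-allele count, the heterozygote count's distribution is enumerated
(log-space factorials, normalised with logsumexp) and the p-value sums all
outcomes no more probable than the observed one (probability-ordering,
two-sided; relative tie tolerance 1e-12). It runs on hard calls — rounded
dosages when necessary — because HWE is a property of called genotypes;
in the pipeline, QC precedes imputation-noise injection. The test suite
verifies agreement with exact integer-arithmetic enumeration for every
configuration up to 200 samples.

PCA standardises each variant column (zero-variance columns dropped,
missing values mean-imputed), takes the SVD, and fixes signs by making
each component's largest-magnitude loading positive so results are
reproducible across runs.

## Association models

Grades dichotomise at neutropenia ≥3, neuropathy ≥2; missing grades are
excluded and counted. Logistic fits are Newton MLE (statsmodels) with Wald
95% CIs and two-sided Wald p-values — the symmetric-CI convention; fits
require ≥10 cases and controls, and separation or non-convergence raises a
typed failure (recorded per variant in the scan rather than fatal). Trial
enters as indicators with the largest trial as reference; reference choice
cannot affect score inference. Complete-case handling for missing
covariates, with n reported. The per-variant scan defaults to α = 5e-4
(≈ 0.05/94) and orders results by p for the gene ranking. The Cox model
(lifelines) reports the per-allele hazard ratio; per-k rescaling is
HRᵏ = HR^k applied to the estimate and CI bounds.

## Pathway enrichment

Each variant maps to exactly one gene (packaged best-effort mapping:
38 assignments fixed by the published ranked table; remaining multi-gene
labels take their first/target gene; 9 intergenic variants keep `chr_pos`
locus labels — override with your own file for serious use). A gene is
ranked by its most significant variant; ties break by rsid so the ranking
is deterministic. The top 50% uses the floor convention (76 → 38; 7 → 3).
Overrepresentation is the one-sided hypergeometric upper tail on the
(in-top × in-set) table against the mapped-gene background — the ranked
list is its own universe; a genome-wide background would be wrong for a
pre-selected risk-locus panel. Bonferroni multiplies by the number of sets
actually tested (sets with no background overlap are skipped). This is a
plain Fisher test, not an annotation-database tool with a penalised
variant; enrichment p-values from such tools are not comparable.

## Power

Two-sample two-sided normal approximation (above). The score SD defaults
to the catalog-analytic weighted SD, 0.4568, which with Δ = 0.1, 30%
cases, α = 0.05 gives 95% (n = 1,279) and 98% (n = 1,676). The choice of
score and SD convention behind such power statements is genuinely open; we
use the weighted analytic SD because it is derivable from the catalog
alone and lands within a point of the conventional report for this design.
σ is overridable. The normal approximation versus a noncentral-t differs
by < 0.5 points at these group sizes. A Monte-Carlo check
(`simulated_power`, Welch t-test per replicate) agrees with the analytic
value within binomial error.

## Problem sizes and numerical choices

Simulation-based checks use: 50,000 samples for moment/HR recovery checks,
500 replicates of n = 1,676 for effect recovery, 1,000 replicates for
type-I error, 10,000 replicates for Monte-Carlo power. Intercept
calibration is Brent on [−40, 40], xtol 1e-12. Exact-test tie comparison
uses 1e-12 relative tolerance. PCA rank tolerance is the SVD default
(max-dimension × eps × largest singular value).

## Known limitations

- The synthetic generator's independence and distributional
  simplifications (above).
- The variant→gene mapping is best-effort where not fixed by the
  published ranking; enrichment results depend on it.
- VCF dosage reading trusts the ALT allele as the counted allele and can
  only flip (D → 2−D), not strand-resolve ambiguous A/T and C/G variants;
  these are flagged, not fixed.
- No phasing, imputation, genotype calling, liftover, or ancestry
  exclusion; PCs are furnished as covariates only.
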