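# Methods

## Scope and data model

The package analyses cohorts of full sibling pairs: every retained
individual belongs to exactly one pair of size two, genotypes are
minor-allele dosages in {0,1,2} (missing allowed), quantitative traits are
carried both in mg/dl and as z-scores computed **once on all non-missing
individuals before any stratification**, and the covariate roster is age
(years), sex, location (urban/rural), city (4-level factor) and a
median-split fat-intake class.  Genotypes travel as whitespace PED/MAP text
(missing allele `0`, 4-column MAP); phenotypes as a TSV that carries the
pair id explicitly, because the design recruits sibling pairs without
parents and sibships cannot be inferred from PED parental columns.  The
minor allele is determined once on the full sample (alphabetical
tie-break) and fixed for every downstream analysis, so coding is stable
across strata.

## The association model

Dosages are decomposed per pair into b = (g₁+g₂)/2 and w = g − b.  The
quantitative-trait model is

y_ij = μ + β_b b_j + β_w w_ij + covariates + u_j + e_ij,
u_j ~ N(0, σ²_pair), e_ij ~ N(0, σ²_resid).

**Estimation.** REML with the intraclass correlation
ρ = σ²_pair/(σ²_pair+σ²_resid) profiled by scalar search on [0, 0.999]
(bounded Brent, xatol 1e-6).  For fixed ρ the pair covariance is known up
to scale, so fixed effects come from exact GLS: the pair sum and difference
are independent with variances 2(1+ρ) and 2(1−ρ), giving a whitening
transform without any matrix factorisation; clusters reduced to one member
enter unwhitened.  With two-member clusters this profiling is exact, and
the fit agrees with `statsmodels.MixedLM(reml=True)` to ~1e-6 on
coefficients (tested).  Boundary solutions (ρ at 0 or 0.999) are reported
with a flag, never hidden.

**Inference.** Wald normal: 95% CI = β̂_w ± 1.96·se, p from the standard
normal.  Samples in the intended regime number in the thousands, so t vs z
is immaterial; the published intervals are z-style.

**Covariates.** Age, sex, location and city enter every model as fixed
effects (city one-hot with the first sorted level as reference).  Columns
constant over the analysis rows are dropped with a warning rather than
producing a singular design.

**Missing data.** Pairwise deletion per SNP-trait combination: a pair
missing either sib's dosage is excluded for that SNP (w undefined); an
individual missing trait or covariate drops only that row, its sibling
remaining as a singleton cluster whose w is still defined from the
genotypes.  Fits require ≥ 30 complete pairs.

**Why the within component.** w is a pure sibling contrast, so any term
constant within a family — including hidden-subpopulation trait shifts —
is orthogonal to it.  In the canonical design (intercept, b, w), β̂_w is
numerically invariant to adding arbitrary pair-constant offsets to the
trait (tested to 1e-10); with individual-varying covariates the invariance
is no longer an algebraic identity, but the simulation suite shows the
within component remains unbiased under confounding that severely biases
the between component.

**Binary outcomes.** A logistic model on the same b/w design with a
cluster-robust (sandwich) covariance grouped on pair id; the reported
effect is exp(β̂_w).  A random-intercept logistic model would estimate a
subject-specific rather than population-averaged odds ratio; the sandwich
choice is deterministic, assumption-light, and its estimand matches the
marginal odds ratios that replication studies quote.  Perfect separation
raises an error rather than returning a pseudo-estimate; so does a
single-class outcome.

**Gene–environment interaction.** w×modifier and b×modifier join the fixed
effects (with the modifier's main effect); inference is reported on the
w×modifier coefficient.  Modifiers are the binary factors sex, location and
fat intake.

**Stratified screens.** Independent fits per stratum, dropping the
stratifier from the covariates.  A pair contributes only when *both* sibs
carry the stratum level; for location this means migrant pairs (one urban,
one rural sib) drop out of both location strata — a deliberate,
conservative reading of individual-level stratification, chosen because a
pair split across strata cannot supply a within-stratum sibling contrast.
Strata under 30 complete pairs are reported not-assessable and the screen
continues.

**Multiple testing.** Bonferroni α/m, kept unrounded internally; reports
additionally render the one-significant-figure form (0.05/21 = 0.00238 →
"0.002") that matches how such thresholds are usually printed.

## SNP quality control

HWE uses the conditional exact test: given the allele counts, heterozygote
counts of matching parity are enumerated with the standard probability
ratio recurrence accumulated in log space (overflow-safe to cohort sizes in
the thousands), and the p-value sums all configurations no more probable
than the observed one.  The plain tail is used, not the mid-p variant,
matching common tool behaviour.  Monomorphic data give p = 1.  The test is
evaluated on a deterministic unrelated subset — the first-listed sib of
every pair — overall and within each city; a SNP is excluded when any of
those p-values is ≤ 0.001 (configurable), with the exclusion reason naming
the most significant failing stratum.  Strata with fewer than two
genotyped unrelated subjects are not assessable and never trigger exclusion
alone.  Call rate is computed on all individuals with a default 0.95
threshold; duplicate concordance is the discordance fraction over
pairwise-complete entries.

## LD comparison

Pairwise LD is composite r²: the squared Pearson correlation of dosages,
pairwise-complete over missing data.  This phase-free convention was chosen
over EM haplotype phasing because it is deterministic and the comparison is
matrix-level; tools that phase will give slightly different matrices.
Monomorphic SNPs are not assessable and their pairs are skipped in both
matrices.  z₂ sums squared element-wise differences over unordered
off-diagonal pairs.  The permutation test pools subjects, reassigns
population labels preserving group sizes, and recomputes both matrices and
z₂ per permutation; ties (z₂_perm = z₂_obs) count in the "greater" tail,
and the one-sided p uses the add-one rule (1+greater)/(n_perm+1) — the
convention under which published greater/lower counts sum to n_perm+1.
Which SNPs form a locus window is the caller's decision; the module takes
an explicit panel.

## The synthetic cohort generator

The generator's defaults are the study conditions: 3,178 pairs; seven SNPs
with the published minor-allele frequencies (0.07–0.21) and standardized
primary-trait effects (|β| 0.08–0.18); lipid scales from the all-participant
means/SDs (TG 134.1/69.1, TC 183.2/45.1, HDL 43.5/9.5, LDL 113.2/52.4
mg/dl); four cities; 57.6% male, same-sex pairs; age ~ N(40.8, 10.3²) with
a within-pair component; 73% of pairs split urban/rural (matching the
36.6% rural share) and the rest fully urban.

* **Genotypes.** Subpopulation allele frequencies follow Balding–Nichols
  (Beta with mean q and variance Fst·q(1−q); Fst = 0 copies q exactly);
  parental genotypes are drawn per pair and offspring receive one random
  allele from each parent, which yields the full-sib dosage correlation of
  1/2 (tested).
* **Traits.** y = Σ β_k·(g_k − 2q_k) + covariate terms + subpopulation
  shift + pair effect + residual.  The pair-shared and residual variances
  are rescaled so total variance is 1, with `icc` setting the pair-shared
  share of the non-systematic variance — this keeps planted betas
  recoverable without attenuation after z-scoring, at the cost that the
  realized pair-shared variance is icc·(1 − systematic share) rather than
  icc exactly.  Covariate effects default to 0.15 s.d. per SD of age, 0.10
  for male, 0.13 for urban (the direction and rough magnitude of the
  published urban/rural trait differences).
* **Confounding.** The per-subpopulation trait shift is proportional to the
  standardized aggregate allele-frequency deviation across SNPs, so allele
  frequency and trait mean covary *systematically* — the structure that
  biases a pooled regression in every realization, not merely in noisy
  expectation.  The magnitude knob `confounding_shift` is the SD of the
  shifts in trait-SD units.
* **Blood pressure and hypertension.** SBP ~ N(123.3, 14²) and
  DBP ~ N(79, 9²) with correlation 0.6 and a shared-pair component; these
  scales were solved analytically so that P(SBP ≥ 140 or DBP ≥ 90) equals
  the published 18.1% prevalence.  For planted binary-effect studies the
  label can instead be drawn from a logistic model with per-SNP log-odds
  effects.
* **Fat intake** is a continuous score (part pair-shared) median-split into
  low/high, mirroring how such an exposure is dichotomised in practice.

What the generator does **not** emulate: real LD between the seven loci
(SNPs are independent), assortative mating, measurement error, the food
frequency instrument, or the migration sampling frame.  Passing tests
therefore certify the estimators' statistical behaviour under the assumed
model, not properties of the original data.

The LD panel generator draws latent Gaussian haplotypes with a target
correlation matrix (validated symmetric, unit-diagonal, PSD) and thresholds
them at allele-frequency quantiles; two haplotypes sum to a dosage.
Thresholding attenuates correlations relative to the latent target, so the
realized dosage r² approaches a discretised version of the target — which
is immaterial here because the comparison machinery only requires the two
panels' generative targets to be equal or different.

## Effect translation and power

β_natural = β_sd × SD(trait); Va = 2pqβ² with q the minor-allele frequency,
equal to the proportion of variance explained on a unit-variance trait, and
the additive special case of the classical genotype-means formula
2pq[p(X₁₁−X₁₂)+q(X₁₂−X₂₂)]² (equality tested on a grid).  Power uses the
1-df chi-square approximation for unrelated samples, NCP = n·pve/(1−pve);
it ignores the sib-pair correlation structure and is intended for
back-of-envelope design numbers only, documented as approximate and
excluded from any headline claim.

## Problem sizes used in verification

The test suite and acceptance script measure estimator behaviour at these
sizes, chosen to give Monte-Carlo standard errors small enough for 3-sigma
checks while keeping a full run in the minutes range on one CPU:

* parameter recovery and CI coverage: 200 (tests) / 100 (script) cohorts of
  3,000 pairs, β = 0.18, MAF 0.19, icc 0.3;
* substructure robustness: 200 / 120 cohorts of 1,500 pairs, Fst = 0.05,
  confounding shift 0.5 s.d., null SNP;
* type-I error and p-uniformity: 500 cohorts of 2,000 pairs (tests);
  300 of 1,000 (script);
* HWE exact test vs log-gamma enumeration oracle: every genotype
  composition to n = 60 (tests) / n = 40 (script);
* permutation exchangeability: 200 replicates × 999 permutations (tests);
  100 × 499 (script).

All randomness flows through explicit integer seeds; replicate seeds are
spawned from a single base via `numpy.random.SeedSequence`, so every number
is bit-reproducible.

## Known limitations

* Sib pairs only: no parent-offspring or extended pedigrees.
* Designed for candidate panels (seven to a few hundred SNPs), not
  genome-wide scans.
* The binary-trait estimator is marginal (sandwich logistic); a
  conditional random-intercept logistic would give larger subject-specific
  odds ratios for the same data.
* Composite r² differs from haplotype-phased r² when phase matters.
* The power calculation is an unrelated-sample approximation.
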