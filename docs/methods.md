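# Methods

This note documents the models, defaults and numerical choices behind
`cellprs`, and what the synthetic-data generator does and does not emulate.

## Expression specificity and gene sets

The specificity of gene *i* for cell type *j* is
`Sg_ij = E_ij / Σ_j E_ij`, where `E_ij` is the mean expression of gene *i*
over the cells of type *j*. Two normalisations for `E` are available:

* `cp10k` (default): each cell's counts are scaled to a library size of
  10,000 before averaging. The source protocol does not pin the
  normalisation; CP10K is used because raw means conflate expression
  specificity with sequencing-depth differences between cell types, and the
  package's scale-invariance test (multiplying one type's counts by a
  constant) only holds under a per-cell normalisation.
* `raw`: plain mean counts, for comparison.

Genes enter the pool iff detected (count > 0) in strictly more than
`min_fraction` (default 0.01) of the cells of at least one type — the
inequality is strict, so a gene at exactly 1% everywhere is dropped. Genes
with zero mean in every type cannot be row-normalised and are excluded with
a warning rather than an error. Region exclusion (default the extended APOE
locus, GRCh38 chr19:43,905,781–45,909,393, 1-based inclusive; any ≥1 bp
overlap removes a gene) is applied *before* ranking, so excluded genes
never occupy top-decile slots.

Per-type sets take the `floor(fraction × N_retained)` genes with largest
`Sg_ij` (default fraction 0.10; 13,438 retained genes give sets of 1343).
Ties at the boundary break by descending Sg then ascending gene ID, which
makes the selection deterministic across platforms. Sets may overlap:
a gene can be specific to two types at once.

## Variant partition

Gene windows are `[max(1, start − margin), end + margin]`, merged per
chromosome (touching intervals coalesce). The default margin is 30 kb,
chosen to cover most cis-regulatory variation; 10 kb and 100 kb are the
standard sensitivity settings, and membership is provably monotone in the
margin. Bounds are inclusive on both ends — a variant exactly at
`start − margin` is a member — matching the most literal reading of
"within ± margin". Membership depends on position only; alleles are the
scorer's concern. Chromosome names are normalised (`19` ≡ `chr19`) at read
time. Variants inside the excluded APOE region are ineligible for every
score including the all-autosome one; APOE risk enters the downstream
models as ε4/ε2 dosage covariates instead.

## Scoring

Scores are plain weighted sums `Σ β_v d_iv` of integer dosages, not
per-allele averages. Because every score is z-standardised (sample SD,
n − 1 denominator) before any model, the two conventions are affinely
related for complete data and give identical downstream statistics; the
test suite asserts this equivalence explicitly so results can be reconciled
with tools that average by default. Summation runs in sorted-variant-ID
order to pin floating-point determinism under input reordering.

Allele reconciliation: if the genotype's counted allele equals the weight
table's effect allele A1, the weight is used as-is; if it equals A2, the
dosage is reflected (2 − d), tracked as a sign flip plus constant offset so
raw scores remain exact. Mismatching pairs are dropped with a logged count.
Palindromic (A/T, C/G) variants are dropped by default, mirroring their
usual pre-imputation removal; the flag is configurable for data where
strands are known. Missing dosages can only arise from VCF input and are
mean-imputed per variant and rounded — fully imputed dosage data never hit
this path.

## Association models

Continuous endophenotypes use OLS; the binary dementia outcome uses ML
logistic regression. Wald two-sided p-values are reported for the score
term. Effect size is ΔR²: adjusted-R² difference for linear models, and for
logistic models the Nagelkerke pseudo-R² difference, where each model's
R²_N is computed against the intercept-only null
(`R²_N = [1 − (L₀/L₁)^(2/n)] / [1 − L₀^(2/n)]`). Every linear fit asserts
the raw-R² monotonicity invariant.

ΔR² confidence intervals come from a case-resampling bootstrap (default
B = 1000, percentile 95%). Resampling is implemented as multinomial
frequency weights, which is exactly equivalent to index resampling for
point estimates but lets all B linear refits be batched into one einsum +
batched solve; logistic resamples are refit individually and are stratified
by outcome so no draw has a constant outcome (degenerate linear draws are
redrawn and logged). Comparing two scoring methods uses the one-sided
empirical p `(1 + #{ΔR²_alt,b > ΔR²_primary,obs}) / (B + 1)`; the +1
correction avoids exact-zero p-values (the uncorrected `k/B` form is a
plausible alternative; the corrected form is the package's choice).

Multiplicity uses Benjamini–Hochberg within a configurable analysis family
at FDR 0.025 (0.05 split across two discovery datasets). Moderation by age,
sex or ε4 dosage is tested by adding a score × moderator product term with
main effects retained, flagged at p < 0.017 (0.05 over three moderators).
Per-outcome covariate maps encode that education enters only the dementia
and cognition models. Rows with missing modelled values are dropped
listwise per analysis.

## Mediation

Treatment (a standardised score), mediator and outcome are continuous, and
the models contain no treatment × mediator interaction, so the average
causal mediated effect equals the product of coefficients: fitting
`M ~ T + C` (coefficient a) and `Y ~ T + M + C` (b, c′) gives ACME = a·b,
ADE = c′, and the total effect — the T coefficient of `Y ~ T + C` — equals
ACME + ADE exactly on the same rows. This analytic identity is asserted to
1e-9 on every fit and is why the simulation-based estimator used by common
mediation software can be replaced by direct computation inside each
bootstrap draw (B = 10,000 by default), making the bootstrap a pair of
batched weighted regressions. Intervals are percentile (BCa would also be
defensible; percentile is the simplest choice matching empirical two-sided
p-values `2·min(P(θ*≤0), P(θ*≥0))` with the (1+k)/(B+1) correction).

Proportion mediated is ACME/total. When ACME and ADE have opposite signs
the ratio is ill-behaved; when |total| < 1e-8 the estimate is reported as
unstable (NaN point estimate, no CI) rather than a misleading number. The
standard four-triplet configuration conditions the NFT → cognitive-decline
model on upstream neuritic-plaque burden by appending it to the covariates
of both regressions.

## Path-model SEM

The model is a recursive (acyclic) system of linear regressions over
observed variables, default graph:

```
DP ~ AstScore
NP ~ DP + AstScore + MicScore
NFT ~ NP + MicScore
CogDec ~ NFT + NP + MicScore
AstScore ~~ MicScore
```

The NP → CogDec edge is included by default because glial effects on
cognition beyond tangle pathology imply direct pathology → cognition paths;
it is toggleable in the model text. No residual covariances among
endogenous variables are freed by default.

For such models ML point estimates equal per-equation OLS, so estimation is
deterministic: coefficients fill the path matrix B, ML (n-denominator)
residual variances and the sample (co)variances of exogenous variables fill
Ψ, and the implied covariance is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ. The test statistic
is χ² = n·F_ML with F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p and S the
n-denominator sample covariance — the dialect of the reference SEM software
(n, not n − 1). The baseline model frees variances only. CFI and TLI follow
the standard noncentrality formulas, RMSEA = √(max(χ²−df,0)/(df·n)), and
SRMR is the RMS of `(S_ij − Σ_ij)/√(S_ii S_jj)` over the lower triangle
including the diagonal. A saturated model (df = 0) reports CFI = TLI = 1,
RMSEA = 0 and near-zero χ²/SRMR. The completely standardised solution
rescales each coefficient by model-implied SDs, and bootstrap SEs/CIs come
from case resampling with full refits (default B = 10,000).

Variables are residualised (OLS) against ε4/ε2 dosage, age, sex, batch and
PCs before model fitting, with per-variable covariate maps (education only
for the cognition variable). Modelling the residuals rather than adding
covariates to every equation matches the residualise-then-fit convention of
the reference analysis.

## Synthetic-data generator

The generator's role is to produce inputs with the *statistical* structure
the analysis assumes, at known ground truth — it is not a biological
simulator.

* **Expression**: negative-binomial counts (variance μ + φμ², dispersion
  φ = 0.5 by default) with lognormal library-size variation (σ = 0.3) over
  six cortical cell types at roughly cortical proportions (480 cells
  total by default, 2000 genes — a desk-scale stand-in for a
  tens-of-thousands-of-nuclei atlas). Each type gets `n_specific_per_type`
  planted markers whose mean is multiplied by `fold_change` (default 20) in
  the home type only; `fold_change = 1` makes markers statistically
  indistinguishable from other genes, the generator's own negative control.
* **Annotation**: non-overlapping GRCh38-style gene intervals round-robin
  across four chromosomes; chr19 placement starts upstream of the APOE-like
  region and the first chr19 gene is pinned inside it so the exclusion path
  is always exercised.
* **Genotypes**: independent variants in Hardy–Weinberg proportions, MAF ~
  U(0.05, 0.5), dosages Binomial(2, MAF), positions uniform over the
  annotation's chromosomes, non-palindromic allele pairs with A1 as the
  counted effect allele. Real LD is deliberately absent — partition scores
  are sums, so no implemented statistic needs LD — but an exchangeable
  within-block correlation mode exists for robustness experiments.
* **Weights**: a `weight_sparsity` fraction of variants get N(0, scale²)
  weights; inside the causal cell types' gene windows (astrocytes and
  microglia by default) the SD is multiplied by `causal_inflation`, so the
  matching partitioned scores carry real signal.
* **Phenotypes**: the standardised Ast/Mic scores drive the chain
  DP → NP → NFT → CogDec with standardized path coefficients (defaults
  around 0.1–0.55 on score → pathology and pathology → pathology edges,
  echoing the ordering of reported effects); residual SDs are calibrated so
  each endophenotype is roughly unit-variance. IHC-style Aβ and PHFtau are
  generated as noisy functions of the plaque/tangle variables. Dementia is
  Bernoulli with a logistic predictor on NP, NFT and CogDec, with the
  intercept set for a prevalence of roughly 0.4. Covariates (age, sex,
  education, ε4/ε2 ~ Binomial(2, q), batch, three PCs) are mutually
  independent with additive effects — they reproduce the adjustment set's
  algebraic role, not its joint distribution (no age–APOE correlation, for
  instance). The cognitive-decline slope is emitted directly, already
  age/sex/education-adjusted, rather than derived from longitudinal
  trajectories.

Every generator is a pure function of `SimulationConfig`: one seed, keyed
per stage, gives byte-identical outputs. Consequences for interpretation:
passing tests show the estimators recover planted structure under the
assumed model (independent variants, linear effects, Gaussian noise,
complete data); they do not certify behaviour under LD, confounded
covariates, missingness or model misspecification in real cohorts.

## Problem sizes and numerical choices

Default test and acceptance problem sizes (hundreds of individuals and
cells, thousands of variants, B in the hundreds to thousands; coverage
simulations at n = 2000 with 100 replicates, SEM recovery at n = 5000) were
chosen as the smallest scales at which the checked quantities are stable;
the full-size defaults (n_individuals = 1457, B = 10,000) remain the
package defaults for real use. Other numerics: normal-equations solves are
used throughout (designs here are tiny and well-conditioned; singular
designs raise immediately rather than being silently regularised);
standardisation refuses zero-variance vectors; bootstrap percentile CIs use
the 2.5/97.5 empirical quantiles; all p-values are reported unclipped
except empirical bootstrap p-values, which are bounded away from 0 by the
(1+k)/(B+1) correction.

## Known limitations

* No LD-aware variant-to-gene assignment or eQTL mapping — distance margins
  only, by design.
* No penalised logistic regression: separation raises an error.
* No latent variables, FIML missing-data handling, or robust (scaled) SEM
  test statistics; listwise deletion throughout.
* The Bayesian shrinkage estimation that produces posterior variant weights
  is out of scope; weights are consumed as input (the generator's Gaussian
  sparse weights are a stand-in, not an implementation of it).
* Proportion mediated is reported but unstable when the total effect is
  near zero; the instability flag should be respected.
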