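# Methods

## Overview

`gatescore` implements a genome-wide aggregated trans effects (GATE)
analysis: genotypic predictors of a gene's transcript or circulating
protein level are built from *trans*-QTL summary statistics, and the
resulting per-individual scores are tested for association with a binary
disease.  The motivating model is the omnigenic / sparse-effector
hypothesis: most polygenic effects on a complex trait are mediated by
many weak *trans* effects of common variants that converge on the
expression of a relatively small set of "core" effector genes.  If that
is so, a score that aggregates a gene's *trans*-QTL effects genome-wide
should associate with the disease for core genes and behave like noise
for the rest.

The pipeline stages, in run order:

1. **Ingestion** (`ingest`): univariate SNP-on-expression summary
   statistics are filtered at the extraction threshold P < 1e-5; the
   HLA region (chr6:25–34 Mb, closed interval) is removed because it is
   a *trans*-QTL hotspot whose disease associations are confounded by
   direct HLA effects; associations are classified cis vs trans by
   distance to the transcription start site; remaining SNPs are grouped
   into clumps anchored by a lead SNP at P < 1e-6.
2. **LD weights** (`ldweights`): within each clump the univariate betas
   are multiplied by the (pseudo)inverse of the reference-panel SNP
   correlation matrix, converting marginal effects to multivariable,
   LD-corrected weights.
3. **Scoring** (`scoring`): locus scores = centered cohort dosages ×
   weights; the GATE score is the sum of a gene's *trans* locus scores;
   cis loci are scored separately.  The Hill number of the locus-score
   variances gives the effective number of *trans*-QTLs.
4. **Association** (`association`): one covariate-only logistic null
   (sex + 20 genotypic PCs) is fitted per cohort; every score is tested
   with the efficient score test; log odds ratios are standardized to a
   one-SD score increase.
5. **Mendelian randomization** (`mr`): per-locus instruments
   (gamma = effect on exposure, Gamma = effect on outcome) enter a
   marginal likelihood in which Gaussian pleiotropy is integrated out;
   the causal effect is profile-maximized over (theta, tau).
6. **Reporting** (`reporting`): strict filters (effective_n > 5,
   P < 1e-5), GWAS-hit proximity (200 kb), measured-protein validation
   (same direction, ≥ 2× magnitude), MR support (P < 0.01, ≥ 10
   instruments), and curated annotations assemble the validation table.

## Statistical details

### Efficient score test

With null fit mu-hat and W = diag(mu(1−mu)):

    U = s'(y − mu),    V = s'Ws − s'WX (X'WX)⁻¹ X'Ws,
    chi² = U²/V  ~  chi²(1 df) under H0.

V is the information of the score after projecting out the covariate
space, so the test is invariant to covariates orthogonal to both score
and residuals.  The reported effect is the one-step estimator U/V
(consistent with the test, O(1) per score after the shared null fit),
multiplied by the score SD.  For weak effects it agrees with a full ML
refit to within a few percent; a refit is available via `refit=True`.
With an intercept-only null and a binary score the statistic is exactly
the Pearson chi-square of the 2×2 table.

### Hill number (effective number of trans-QTLs)

For locus-score variances σ1²..σK², p_i = σ_i²/Σσ_j², the index is
2^(−Σ p_i log2 p_i): K when variances are equal, 1 when one locus
dominates; invariant to permutation and rescaling.  Variances are
computed in the target cohort, not the reference panel, so the index
describes the scores actually tested.

### Pseudoinverse LD weights

Weights solve R w = beta by truncated SVD: singular values below
`svd_rtol` (default 1e-6) × the largest are dropped.  The default
removes only numerically null directions; for a duplicated SNP the
rank-1 pseudoinverse splits the weight evenly, leaving the locus score
unchanged.  No ridge shrinkage is applied by default (`ridge` is an
off-by-default sensitivity option), and correlations are computed on
centered dosages only, keeping weights on the per-allele scale of the
input betas.

### Attenuation law

If a measured mediator x causes the outcome with standardized log OR b,
a score with correlation r to x has standardized log OR → r·b in large
samples, so the ratio of measured-to-score effect sizes is ≈ 1/r.  A
score explaining r² = 2% of the mediator's variance therefore predicts
a ratio of 1/√0.02 ≈ 7.07.  `reporting.attenuation_check` compares this
prediction with the observed ratio (consistency band a configurable
factor of the prediction, default [0.5, 2]).

### Mendelian randomization

Direct (pleiotropic) instrument effects alpha_j ~ N(0, tau²) are
integrated analytically:

    Gamma_j ~ N(theta·gamma_j, se_Gamma_j² + theta²·se_gamma_j² + tau²).

The fit profiles tau ∈ [0, 3·SD(Gamma)] at each theta on a grid centred
on the IVW estimate, refines theta by bounded scalar optimization, and
reports a profile-likelihood 95% CI and a 1-df LR p-value for theta = 0.
With tau = 0 and negligible se_gamma the MLE equals the IVW closed form
exactly.  Design choices: the pleiotropy density is zero-mean Gaussian
(transparent default; the likelihood interface accepts alternative
scales), there is no Egger-style intercept (directional pleiotropy is
absorbed into tau), and genes with fewer than 10 instruments are
flagged ineligible — with few instruments the pleiotropy scale cannot
be learned, so a null result never excludes causality.  In simulations
with 20 instruments the LR test is mildly anti-conservative at
P < 0.01 (empirical type-I error ~2–3%); coverage of the 95% profile
CI is at or above nominal.

## Synthetic data

The generator produces everything the pipeline consumes, with the
statistical structure the analysis assumes:

- **LD panel**: AR(1) blocks of common variants.  Per haplotype, a
  latent Gaussian AR(1) chain is thresholded at the allele-frequency
  quantile; dosage = sum of two haplotypes (Hardy–Weinberg by
  construction).  The latent correlation is calibrated via the
  bivariate normal CDF so the *dosage* correlation of adjacent SNPs
  equals the requested rho rather than an attenuated tetrachoric value.
  High rho combined with very unequal MAFs is rejected as unattainable
  (the thresholded-Gaussian bound).
- **QTL study**: a fresh, non-overlapping sample from the same
  generative process (two-sample design); expression = Σ effect×dosage
  + Gaussian noise; univariate OLS per SNP yields beta/se/p rows,
  optionally restricted to a designated trait-associated SNP panel
  (emulating designs that test trans effects only at such SNPs).
- **Cohort**: disease liability = intercept + Σ core-gene coef ×
  standardized expression + direct SNP effects; the intercept is solved
  numerically for the target prevalence; outcome is Bernoulli.
  Expression is standardized before the coefficient is applied, so
  core-gene coefficients are log odds ratios per SD of expression.
  Covariates (sex, 20 PCs) are simulated independent of genotype: they
  are nuisance adjustments, not objects of study.

`sparse_architecture()` is the canonical configuration used by the
examples and the acceptance script: 50 genes (3 core), 7 trans blocks
of 3 SNPs per gene plus one cis block, per-allele causal effect 0.3 on
expression (total variance ~1), adjacent-SNP LD rho = 0.4, MAF
0.25–0.45, core-gene coefficient 0.7 log-odds per SD of expression,
prevalence 1% (the rare-disease regime of a biobank autoimmune
phenotype).  The QTL-study noise model and effect-size distribution are
package defaults, not estimates from any dataset: effect sizes are
chosen so clump anchors are detected with near-certain power at the
simulated study size (non-centrality ≈ n·β²·2f(1−f)/σ² ≈ 340 at
n = 20,000), which is the regime the analysis presumes.

Problem sizes in the shipped checks — reference panel n = 2,000, QTL
study n = 20,000, cohort n = 50,000, and n = 200,000 for the
attenuation simulation (run at ~10% prevalence so both effect sizes are
estimated precisely) — are the package's demonstration scale; all are
configurable.

What the generator does **not** emulate: realistic allele-frequency
spectra or recombination maps, population structure and
genotype-correlated covariates (available only as an option),
cross-gene sharing of trans-QTLs, case-control ascertainment, and
linkage between blocks.  Passing tests therefore demonstrate
correctness of the machinery under the assumed architecture, not
robustness to confounding present in real cohorts.

## Numerical choices and degenerate inputs

- Coordinates are 1-based with closed intervals throughout (VCF
  convention); all threshold comparisons are strict where the protocol
  says "greater than"/"less than" (effective_n > 5, P < 1e-5), and
  window comparisons are inclusive (|distance| ≤ window).
- Clumping is PLINK-style greedy: p-ascending, ties broken by
  (chromosome, position); members require same chromosome, |pos − lead|
  ≤ 1 Mb and panel r² ≥ 0.1 (both configurable).  The published
  protocol does not print its clumping rule; this is the field-standard
  choice.  The cis window defaults to 1 Mb from the TSS (the protocol
  uses 200 kb only for GWAS-hit validation, not to define cis).
- Dosages are centered at twice the allele frequency before weighting;
  missing dosages are mean-imputed per SNP with a logged fraction.
- Monomorphic columns are rejected at panel construction and at
  correlation time; constant scores and scores collinear with
  covariates (V ≤ 1e-10 × s'Ws) are rejected by the score test;
  separation in the null fit raises with advice to use a penalized fit.
- The null model is fitted once per (outcome, covariates) and reused
  across all scores; its gradient is checked at the optimum.
- MR optimizer: 41-point theta grid spanning ±max(8 IVW SE, |theta|+4
  SE), bounded Brent refinement, profile-CI bounds located by expanding
  bracket + root-finding; non-convergence is flagged, never silent.

## Known limitations

- The one-step U/V log OR underestimates very large effects (it is
  exact only as effects → 0); use `refit=True` where effects are large.
- The MR pleiotropy model is a zero-mean Gaussian; heavy-tailed or
  directional pleiotropy is only partially absorbed by tau.
- Clumping can split one LD block into two correlated loci when the
  within-block correlation decays below the r² threshold; the Hill
  number then counts them separately (it measures score-variance
  diversity, not haplotype blocks).
- Scores explain a few percent of expression variance at realistic QTL
  effect sizes, so GATE analysis identifies genes; it is not a
  predictive risk score.
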