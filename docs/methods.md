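# Methods

This note documents the statistical model, the generative assumptions of
the simulator, the numerical choices made where the design was open, and
the limits of what the simulations demonstrate.

## The two-step interaction analysis

**Model.** Case/control status is modelled by logistic regression.  The
step-two model for a variant with dosage *G* and a binary exposure *E* is

    logit P(D=1) = β0 + βE E + βG G + βGE (E·G) + Σ βc C + Σ βcE (C·E) + Σ βcG (C·G)

with covariates *C* entering with main effects and both product terms, so
that confounding of the interaction itself (not only of the main effects)
is adjusted for.  Categorical covariates are expanded to indicator
contrasts against their first (sorted) level, and the same contrasts are
reused in the product terms.  Dosage enters log-additively (one log-odds
increment per alternative allele).  `exp(βGE)` is the reported interaction
odds ratio with a Woolf-type Wald 95 % interval `exp(βGE ± 1.96·SE)`.

**Step one** regresses exposure status (1 = exposed) on dosage per
variant, unadjusted, in the combined case–control sample.  Under
retrospective sampling a true interaction induces a G–E association in
this sample (cases are hugely over-represented relative to a ~1/1500
prevalence population, and exposed carriers are over-represented among
cases), which is what the screen detects.  Because the screen conditions
on *E* while the interaction test conditions on *D*, the two statistics
are nearly independent under the null; this is verified empirically
(correlation of the two z-statistics across simulated replicates).

**Selection and threshold.**  Screening hits at p ≤ 1×10⁻⁵ are pruned
greedily in ascending p order (ties broken by genomic position), accepting
a variant only if its squared Pearson dosage correlation with *every*
previously accepted variant is ≤ 0.6.  Undefined r² (zero variance,
insufficient overlap) is treated as "not shown independent", i.e. the
candidate is dropped.  The step-two significance threshold is 0.05/m at
full precision for the m variants retained; two-significant-figure
rounding is applied only for display.  Interactions with p < .05 above the
threshold are reported as suggestive.

**Complete cases.**  Each exposure contrast maps raw labels onto
`exposed / unexposed / excluded / missing`; excluded and missing samples
are dropped from that exposure's analyses only.  The `excluded` level
exists so that contrasts that remove a category by design (for example
subfertile couples who did not use assisted reproduction, when the
exposure of interest is assisted reproduction itself) are expressed as
data rather than special-cased code.

## Logistic fitting

Maximum likelihood is obtained by Newton/IRLS with step halving,
convergence declared at |Δ log-likelihood| < 1e-10 within 100 iterations.
With separated data the likelihood plateaus while coefficients diverge, so
separation is detected by any |coefficient| > 15 on the log-odds scale (an
odds ratio beyond 3×10⁶); such fits are redone with Firth's Jeffreys-prior
penalised likelihood, which always has a finite maximiser, and the result
records `method="firth"`.  Wald covariance comes from the inverse observed
information at the final estimate.  Screening uses the same Newton
iteration vectorised across variants (closed-form 2×2 information
inverse, Newton steps damped to length ≤ 5 to stabilise separated
variants); per-variant missingness is handled by zero-weighting, and
variants monomorphic on their complete cases are skipped with a reason.
The batch solvers are checked coefficient-by-coefficient against the
single-fit path and against `statsmodels.Logit` in the tests.

## Quality control

Filters and defaults follow common genotyping-array practice: variant call
rate ≥ 0.98, MAF ≥ 0.01 on non-missing dosages, and an exact
Hardy–Weinberg test within cases (p ≥ 1e-10) and controls (p ≥ 1e-6)
separately — the case threshold is looser-in-effect because true
disease-associated variants can deviate in cases.  The HWE test is the
standard exact conditional test (not mid-p): given the allele counts, all
attainable heterozygote counts are enumerated through a log-scale
recurrence and the p-value sums the probabilities of tables no more
probable than the observed one.  The filter order is fixed (call rate →
MAF → HWE) and each variant's first failing rule is recorded, so order
effects remain visible in the report.

Relatedness uses the KING-robust estimator; pairs above the conventional
third-degree boundary 0.0442 are broken greedily (drop the sample in the
most flagged pairs; ties go to the lower call rate).  Kinship estimates
need thousands of markers to be meaningful — with a few hundred SNVs the
estimator's standard error (~0.04) swamps the cutoff — so the pipeline
skips the relatedness filter below a configurable marker count (default
2000) with a logged warning.  Ancestry adjustment uses the top principal
components of the dosage matrix, mean-imputed per variant and standardised
by √(2p(1−p)); scores are U·S from the SVD of the centred matrix, with
each component's sign fixed by its largest-magnitude loading.  A
PC-outlier flag (> 6 SD on any component) is available but off by default;
reference-panel ancestry matching is out of scope.

## The cohort simulator

The generator produces exactly the data structure the analysis assumes:

* **Genotypes.**  Biallelic variants with specified MAFs; within an LD
  block, haplotype allele indicators come from a thresholded latent AR(1)
  Gaussian (a Gaussian copula) with adjacent-variant correlation `ld_rho`,
  and the genotype is the sum of two independent haplotypes, so
  Hardy–Weinberg proportions hold marginally at every variant by
  construction.  This is a deliberately parameter-sparse LD model: r² is
  tunable and monotone in `ld_rho`, but no attempt is made to mimic human
  recombination maps.
* **Exposures and covariates.**  Bernoulli exposures; covariate defaults
  are child sex ~ Bernoulli(0.5), a three-level maternal-education factor
  (0.15/0.45/0.40), and four standard-normal ancestry scores, all with
  null effects unless configured.
* **Disease.**  Bernoulli with logit-linear risk in the configured main
  and interaction effects.  The intercept is solved so the *population*
  disease probability equals the target prevalence: the risk expectation
  is computed by exact enumeration over the joint cells of all
  risk-bearing discrete predictors (Gauss–Hermite quadrature, 41 nodes,
  for any normal covariate with an effect) and the monotone root is found
  by Brent's method to ~1e-13.
* **Retrospective sampling.**  Cases and controls are drawn until the
  fixed quotas are met.  Two interchangeable samplers exist: a literal
  batch rejection sampler, and an exact conditional sampler that computes
  each discrete risk-cell's probability among cases and controls by
  Bayes' rule, draws cell counts multinomially, and fills everything
  independent of disease from its marginal distribution.  The two are
  distributionally identical (verified by a chi-square comparison in the
  tests); the exact sampler is used automatically when eligible (all
  risk-bearing predictors discrete, causal variants not LD-linked), which
  makes low-prevalence designs tractable — at prevalence 1/1500 the
  rejection sampler needs ~570 000 population draws per replicate.
* **Missingness** is injected completely at random per exposure after
  sampling.  Real questionnaire missingness is plausibly not MCAR; since
  all analyses are complete-case, MCAR suffices for testing the machinery
  but the simulator does not emulate informative missingness.

What passing simulation tests do **not** show: robustness to genotyping
batch effects, imputation dosage uncertainty, realistic LD structure,
population stratification beyond a two-subpopulation toy, or non-random
exposure misreporting.  Results on real cohorts depend on those.

## Power analysis

Power is estimated by Monte-Carlo simulation rather than an analytic
expected-information formula: each replicate draws a fresh retrospective
cohort and applies the two-sided Wald test to βGE in
`status ~ E + G + E:G` (no covariates enter the power model).  The
reference scenario uses 381 cases / 598 controls, prevalence 1/1500, a
log-additive variant with MAF 0.05, and an exposure with prevalence 0.20
and main-effect OR 1.5.  By convention the headline odds ratios 3.0 / 2.0
are *interaction* ORs, 1.5 the exposure main OR, and the variant marginal
OR is 1.0; the alternative reading (the OR attached to the variant's
marginal effect) is exposed as `power_scenario_marginal`.

Under this model the estimated powers are ≈ 74 % (interaction OR 3.0) and
≈ 34 % (OR 2.0) at α = .05 — the tolerance on the "approximately 80 % /
40 %" planning figures is set at ±7 percentage points, because analytic
power calculators use expected-information (score-type) approximations
that run slightly anti-conservative relative to the finite-sample Wald
test: with MAF 0.05 and exposure 0.20 the exposed-carrier cell holds only
a couple of dozen individuals and the Wald test is visibly conservative
there.  Consistent with that reading, the test's empirical size equals the
nominal α in the well-populated regime (checked at MAF 0.20 / exposure
0.30) while the sparse scenario sits slightly below nominal.  The
likelihood-ratio version recovers roughly two points of power but is not
the reported statistic.

`two_step_design_power` runs the whole two-step pipeline and the
exhaustive one-step Bonferroni scan on the same replicates, pairing the
comparison.  The design property — two-step power at least matches
one-step power, with a large advantage when the screening signal is
strong — is demonstrated on a genome of 1000 null variants plus one causal
variant (interaction OR 2.5, MAF 0.12, exposure prevalence 0.18, 1400
cases / 1400 controls), a regime chosen a priori so that both designs have
non-degenerate power; the screening step typically reduces the testing
burden from 1001 variants to one.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen so Monte-Carlo error is small
against each tolerance: the two power scenarios use 8000 replicates in the
test suite and 12 000 in `scripts/acceptance.py` (MC SE ≤ 0.5 points);
null calibration uses 1000 replicates; interaction-parameter recovery uses
500 replicates at 1000 + 1000 samples; the two-step versus one-step
comparison uses 120 paired replicates of a 1001-variant genome; the
end-to-end pipeline recovery check uses 100 seeded runs of a 501-variant,
900 + 900-sample cohort with the causal variant planted at interaction
OR 3.  The end-to-end fixture uses a larger cohort than the reference
power scenario because selecting a variant through the p ≤ 10⁻⁵ screen
with high per-run probability requires a screening z-mean near 5; at
979 samples no admissible MAF/exposure combination reaches that for an
interaction OR of 3.

## Known limitations

* The exact conditional sampler requires discrete risk-bearing predictors;
  continuous covariates with non-null effects fall back to rejection
  sampling (feasible only at non-rare prevalence).
* Crude stratified ORs are unadjusted by design; strata smaller than 10
  samples or with an empty cell are reported n/a with counts.
* The clumping is a greedy all-pairs prune on the analysis sample's
  dosages, a local stand-in for reference-panel-based "independent
  significant SNV" selection; with reference LD it may keep or drop
  borderline pairs differently.
* Genotype imputation, liftover, CNV and monogenic analyses are out of
  scope; genotypes are taken as hard calls in {0, 1, 2}.
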