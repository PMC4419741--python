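# Methods

## The biometric model

The package fits linear-Gaussian variance-component models to same-sex
MZ/DZ twin pairs. For k phenotypes, per-twin scores are modelled as
path-weighted sums of latent additive genetic (A), shared-environmental
(C), non-additive genetic (D) and nonshared-environmental (E) factors.
Component covariance matrices are Cholesky-parameterized (A = XXᵀ with X
lower-triangular, etc.), which enforces positive semi-definiteness
without inequality constraints. Cross-twin sharing follows the standard
biometric coefficients: A is shared fully between MZ co-twins and half
between DZ co-twins; C fully in both; D fully in MZ and one quarter in
DZ; E not at all. The DZ coefficient of 0.25 for D is the classical
result for dominance deviations between full siblings. C and D cannot be
estimated together from same-sex MZ/DZ pairs alone (the design supplies
too few distinct covariance equations), so model specs admit A, E, and
one of C or D; E is always present because it absorbs measurement error.

Assumptions inherited from the classical twin design: random mating,
no gene-environment correlation or interaction, equal environments for
MZ and DZ pairs, and multivariate normality of the (transformed) scores.

### Likelihood and missing data

Fitting is by raw-data (full-information) maximum likelihood: each pair
contributes the log-density of its observed sub-vector under the group's
implied 2k-dimensional moments, with rows/columns of missing entries
dropped. Pairs with no observed scores contribute nothing. This accepts
partially missing phenotypes (e.g. incomplete language batteries)
without imputation, under a missing-at-random assumption. Degrees of
freedom follow the observed-data-points convention: the total count of
non-missing phenotype values minus the number of free parameters.

Means are equated across co-twins and zygosity groups (per sex under
quantitative sex limitation). This choice reproduces the parameter
counts of the reference fit table exactly (50 for a 5-phenotype ACE
model with sexes equated, 100 under sex limitation, 260 for the
four-group saturated model), which is how it was inferred.

### Sex limitation

`equated` shares one parameter set across the four zygosity-sex groups;
`quantitative` frees the path magnitudes (and means) per sex while
keeping the same structure. Qualitative sex limitation (distinct factors
per sex) and opposite-sex pairs are out of scope.

### Optimization

-2LL is minimized with L-BFGS-B over the flattened path entries and
means. Diagonal path entries are bounded below at zero to remove the
reflection indeterminacy of the Cholesky factors (E diagonals at 1e-6 to
keep the implied covariance invertible). The first start is a
method-of-moments solution — component covariances from MZ/DZ cross-twin
covariance contrasts (e.g. A = 2(C_MZ − C_DZ) for ACE), projected to the
nearest PSD matrix and Cholesky-factored; further restarts (5 by
default) perturb that start with seeded noise and the best optimum is
kept. Convergence tolerances: ftol 1e-12, gtol 1e-7 on -2LL. A non-PSD
observed sub-matrix during search is penalized rather than regularized;
the public likelihood function raises instead.

The saturated model (free means, unstructured covariance per group —
four groups under sex limitation, two zygosity groups when sexes are
equated) uses the closed-form MLE (sample mean, 1/n covariance) for
complete-data groups and the same FIML optimizer over a mean +
Cholesky-of-covariance parameterization otherwise.

### Model comparison

The deviance difference between a nested and a fuller model is referred
to chi-square with df equal to the parameter-count difference, and
AIC = χ² − 2·df summarizes each contrast; lower is better. p-values are
taken from the plain chi-square upper tail with no boundary-mixture
correction — conservative for variance components tested at zero, and
matching common practice in the literature this package mirrors. A
sub-model fitting better than its full model beyond tolerance raises a
refit advisory rather than returning a negative χ².

The bundled reference fit table contains three printed AIC entries that
are internally inconsistent with χ² − 2·df (the AE and CE rows versus
the saturated model print −70.11 and 391.01 where the formula gives
−90.11 and 371.01, and AE versus the best full model prints 13.86 versus
17.86); the sex-limited ACE deviance difference likewise prints 216.02
where the −2LL values differ by 216.00. The formula as printed is what
the package implements; the discrepant entries are documented here and
not reconciled. Arithmetic checks use only the internally consistent
rows.

### Standardization and intervals

The correlated-factors solution divides each component's diagonal by the
total phenotypic variance (proportions summing to one by construction)
and reports etiological correlations r_comp = Comp₁₂/√(Comp₁₁Comp₂₂). A
component with (numerically) zero variance yields an undefined — not
zero — correlation, with a flag. Bivariate shares Comp₁₂/Σ₁₂ decompose
each model-implied phenotypic correlation and sum to one; they equal the
textbook form (√p₁·r_comp·√p₂)/r_ph. Confidence intervals are
profile-likelihood: the quantity is fixed on a grid, the remaining
parameters re-optimized (SLSQP with an equality constraint), and the
bound located by bisection where −2LL rises by the chi-square(1)
quantile. Profiles that never cross within the parameter space (common
for shared-environment proportions near zero) return the space boundary
with a flag.

## DF extremes analysis

Probands are all individuals (either twin may qualify) at or beyond the
empirical quantile of a z-scored phenotype in its declared tail; ties at
the threshold are included, and the population mean is taken over all
scored individuals. Scores are rescaled so the proband mean is 1 and the
population mean 0. The univariate regression uses the coefficient of
relatedness (1 MZ, 0.5 DZ) as the zygosity regressor so that its weight
literally equals twice the MZ−DZ difference in transformed co-twin means
(a 1/0 dummy coding would halve it and break that identity). Concordant
pairs are double-entered, once per ordering — the standard DF practice —
with a switch to disable it for sensitivity checks. Group heritability
is capped at the transformed MZ co-twin mean; an excess is flagged as
possible non-additivity. Sex and age enter all DF regressions as
covariates; their coefficients are reported, not interpreted.

The extremes genetic correlation combines the two bivariate estimates
with the univariate ones as √(β_xy·β_yx/(β_x·β_y)), carrying the sign of
the cross-products; the source expression for this quantity omits its
operator, and the square root of the ratio is the convention in the DF
literature. Values beyond ±1 are clipped with a flag; non-positive
univariate heritabilities make the quantity undefined (flagged invalid).

Two details of the extremes procedure are not specified by the source
analysis and are fixed choices here: scores are z-transformed once on
the full analysis sample before selection, and the "population mean" is
taken over all individuals (probands included).

## Preparation chain

Order is fixed and logged: exclusions → log transform of declared skewed
scales → residualization on sex and age → z-transformation. The log
offset defaults to 1 because count-like trait scales include zero.
Residualization pools both twins of every pair and all zygosity groups
in one OLS fit, keeping co-twins on a common scale; constant covariates
degrade to mean-centering with a warning. Sex is coded 0/1 and age kept
in years. Re-running the chain (without the log step) on its own output
is an identity to numerical tolerance, and residualize/z-score commute
up to scale. One twin per pair is selected by a seeded draw for
phenotypic correlations, to respect the non-independence of co-twins.

## The synthetic generator

The generator is the exact generative dual of the fitted model:
multivariate normal latent factors per twin with the sharing
coefficients above, weighted by per-sex lower-triangular paths, plus
linear age and sex effects. On top of the linear-Gaussian core it
emulates two features of questionnaire/web-test data: positive skew
(exponential or ordinal-binning monotone transforms, which preserve rank
order) and missing-completely-at-random dropout per phenotype. One
master seed is split into an independent stream per zygosity-sex cell,
so cells are reproducible in isolation.

The `study_like` preset mirrors the published study conditions: five
phenotypes (a trait scale plus four language tests), the published
per-group pair counts (1113/1102/1293/1188) and per-sex standardized
A/C/E proportions, a genetic correlation of −0.13 between traits and
language, stronger negative shared-environment overlap (−0.6), near-zero
nonshared overlap (−0.05), positive within-language overlap, skew on the
trait scale, and 25% missingness on the language measures (the published
completion counts imply roughly a quarter of scored individuals lack any
given web test). The `two_trait` preset is a scaled-down version for
fast end-to-end runs.

What the generator does not emulate — and hence what passing tests do
not establish about real data: rater effects and informant bias,
assortative mating, gene-environment interplay, selective attrition
(missingness correlated with scores), opposite-sex pairs, and
floor/ceiling measurement artifacts beyond the monotone skew transforms.
Parameter-recovery results show the estimator is correct under the
model, not that the model is correct for any particular cohort.

## Problem sizes and tolerances used in validation

Monte-Carlo checks of generator moments use 50,000 pairs per group
(cross-twin correlations match analytic expectations within 0.02).
Parameter recovery uses 5,000 pairs per group over a grid of generating
(a², c², e²), with mean absolute error required ≤ 0.05; observed error
is about 0.01. Likelihood-ratio null calibration uses 60 replicates of
800 pairs per group (Kolmogorov-Smirnov test against uniform). Profile
interval coverage uses 200 replicates of 2,000 pairs per group, with
empirical coverage required in [0.90, 0.99] for a nominal 0.95 interval.
DF checks select the top 5% of 25,000 pairs per group; capped group
heritability must track the generating a² within 0.07 (observed
deviation about 0.01), and the truncated-normal oracle for the
phenotypic group correlation is matched within 0.05. Exact identities
(FIML versus a brute-force density sum, saturated MLE versus sample
moments, correlated-factors reconstruction of the implied covariance)
hold to 1e-8 or better.

## Known limitations

* Ordinal/threshold liability models are not implemented; heavily
  skewed scales are handled by monotone transforms plus the Gaussian
  likelihood, which is an approximation for strongly discrete scores.
* Profile CIs re-optimize per grid point and are slow for large k; the
  pipeline computes them only when requested.
* The chi-square reference for boundary parameters is conservative (no
  0.5/0.5 mixture correction).
* DF standard errors are taken from plain OLS on double-entered rows
  and ignore the within-pair dependence of entries; point estimates are
  unaffected, and only point estimates are reported in the tables.
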