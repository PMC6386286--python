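# Methods

This note records the statistical models implemented in `twinmr`, the
defaults and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Twin structural equation model

### Moment structure

A pair's 2p phenotype vector is modelled as multivariate normal. With
loadings Λ (p×k), causal-path matrix B (k×k, zero diagonal), latent
innovation covariances A_f, C_f, E_f (k×k, symmetric), specific
variances A_s, C_s, E_s (p-vectors) and means μ equated across co-twins
and zygosity groups:

- reduced form of the latent system: η = (I−B)⁻¹ζ, requiring the
  spectral radius of B to be below 1 (checked; violations are rejected
  with a diagnostic rather than silently producing a meaningless
  covariance);
- within-person block: Λ(I−B)⁻¹(A_f+C_f+E_f)(I−B)⁻ᵀΛᵀ + diag(A_s+C_s+E_s);
- cross-twin block: the same with A replaced by r_A·A and E dropped,
  where r_A = 1 (MZ) or 0.5 (DZ). The specific variances follow the
  same convention (r_A·A_s + C_s): phenotype-specific genetic effects
  are as shared between co-twins as latent ones. This cross-twin
  treatment of specific components is the standard twin-model
  convention; nothing in the model's description forces it, but no
  defensible alternative exists short of adding parameters the design
  cannot identify.

Two builders cover the analyses:

- `build_doc_model` — one latent factor per domain (metabolites ×3,
  lipids ×2, BMD ×2), all six directed paths free, diagonal latent
  A/C/E (9), first loading per factor fixed at unity and the remaining
  four free, 21 specific variances, 7 means: 47 free parameters.
- `build_saturated_ace` — identity measurement model, no paths, full
  symmetric A/C/E matrices free (3·p(p+1)/2) plus p means; specific
  variances fixed at zero. For p = 8 this is 108 covariance parameters.

### Likelihood and missing data

The objective is full-information maximum likelihood on raw pairs:
each pair contributes the normal log-density of its *observed* entries,
with mean and covariance subset to the pair's missingness pattern.
Pairs are grouped by pattern so each pattern's Cholesky factorization
is computed once per objective evaluation; fully missing pairs
contribute nothing. A non-positive-definite subset covariance raises an
error naming the zygosity and pattern (inside the optimizer this is
caught and converted to a penalty).

### Optimization

L-BFGS-B with numerically estimated gradients, convergence tolerance
1e-10 on the relative change in −2LL, at most 5000 iterations. Start
values are data-driven and documented: means at sample means, loadings
at their constructed value (unity), causal paths at zero, latent
variance components splitting the anchor indicator's sample variance
equally across components (across six shares when specific variances
are also free). An optional multi-start (`n_starts`) jitters the start
vector (SD 0.1 on the working scale) and keeps the best optimum;
spot-checks on fitted models show the single-start optimum is already
global for the models shipped here.

Phenotypes are rescaled to unit sample variance before optimization and
all estimates are mapped back exactly (latent factors rescale through
their unit-fixed anchor indicator, so the identification constraints
survive the round trip); the reported −2LL includes the change-of-
variables correction and therefore refers to the original units.

Variance components are estimated **unbounded**. A negative
shared-environment variance is interpretable in the classical twin
design (it indicates a DZ correlation below half the MZ correlation,
i.e. possible dominance) and clipping it would bias the remaining
components; a caller wanting boundary-respecting estimates can fix
offending parameters to zero via `drop_parameter` and refit.

### Standardization and reporting

`standardize` rescales every latent and observed variable to unit
implied variance; causal paths, loadings, variance components and means
are rescaled consistently, leaving the implied correlation structure
unchanged (checked to 1e-10 in the tests). `variance_shares` reports
per-phenotype A/C/E shares, which sum to one by construction;
`standardized_components` emits the phenotypically standardized A/C/E
covariance matrices whose diagonal entries are heritabilities and
environmental shares. Wald standard errors, when requested, come from a
central-difference observed-information matrix; a condition number
above 1e10 flags weak identification instead of failing, because
reciprocal path pairs are known to sit on flat likelihood ridges when
the factors' A/C/E profiles are similar.

### Model comparison

`lrt` computes diff(−2LL) between a full and a nested fit (guarded by a
data fingerprint so fits on different data cannot be compared), floored
at zero — a dropped parameter already at zero can leave the nested
optimum fractionally *below* the full one through optimizer noise — and
refers it to the χ² upper tail at the difference in free-parameter
counts. `bonferroni(alpha, m, decimals)` returns α/m, optionally
rounded half-up to a stated number of decimals for display.

## Longitudinal adjustment

Repeated measures collapse to one score per individual via the
random-intercept model y_ij = β0 + β1·(age−ā) + b_i + e_ij. Age is
centred at the sample mean so the intercept is an age-typical level
rather than an extrapolation to age zero. REML estimation profiles the
likelihood on θ = σ_b²/σ_e²: for fixed θ the GLS fixed effects and σ_e²
have closed forms through per-individual sufficient statistics
(Woodbury identity on the exchangeable within-individual covariance),
leaving a bounded one-dimensional search over log θ in [−25, 25] with
the θ→0 boundary checked explicitly. The score is β0 + b̂_i with the
empirical BLUP b̂_i = (θn_i/(1+θn_i))·(mean residual), so individuals
observed once are retained with strongly shrunken scores. The
implementation agrees with an off-the-shelf REML mixed-model fit to
~1e-5 in the tests (kept as an independent oracle, not a dependency).
One model is fitted per phenotype; a joint multivariate mixed model
would share age information across phenotypes but is not identified as
the intended procedure and is not implemented.

`derive_ldl` implements LDL-C = ¾(TC − HDL-C) in mmol/L and returns
negative values unfiltered: filtering is a data-cleaning decision that
belongs to the caller.

## Mendelian randomization

All ratio variances use the first-order delta method
(se_out/|b_exp|); second-order terms would change little at GWAS-scale
precision and the first-order form keeps Q and the mode weights
consistent with the Wald ratios. P-values are two-sided: normal for
Wald/IVW/weighted mode, Student t with n−2 df for MR-Egger.

- **Harmonization** intersects on SNP id and aligns the outcome to the
  exposure's effect allele, flipping the outcome beta (and
  complementing its frequency) for swapped coding and resolving strand
  flips by complementing. Palindromic SNPs default to frequency
  inference: kept when both frequencies are clearly on the same (or
  clearly opposite, implying a flip) side of 0.5, dropped when either
  falls in [0.42, 0.58]. Policies `drop` and `keep` are available. The
  operation is idempotent on its own output and every flip/drop is
  logged.
- **Clumping** is greedy p-value pruning against a caller-supplied r²
  matrix (threshold default 0.001, mirroring the common summary-MR
  platform default); the package does not compute LD from reference
  panels.
- **IVW** is weighted regression through the origin with weights
  1/se_out²; multiplicative random effects inflate the SE by the
  residual scale floored at 1 (never deflating below fixed-effect).
- **MR-Egger** orients each SNP so b_exp ≥ 0 before fitting the free
  intercept, with the same residual-inflation floor.
- **Weighted mode**: per-SNP ratios smoothed by a normal kernel with
  bandwidth φ·0.9·min(sd, mad)·n^(−1/5) (modified Silverman; φ = 1 by
  default), density maximized on a 2048-point grid spanning the ratios
  ±3 bandwidths; SE from 1000 parametric-bootstrap resamples
  Normal(ratio_i, se_i) with a caller-supplied seed. If all ratios
  coincide the common ratio is returned with a bootstrap SE rather
  than failing on the zero bandwidth.
- **Cochran's Q**, leave-one-out IVW, and the single-SNP table (Wald
  ratio, 95% CI, inverse SE — the data behind forest and funnel
  displays) complete the suite.

## Synthetic data

- **Twin pairs** are drawn directly from the model-implied 2p-variate
  normal per zygosity (distributionally identical to simulating latent
  A/C/E variables with their cross-twin correlations and pushing them
  through the structural system, which the tests verify by Monte
  Carlo). Missingness is applied completely at random, element-wise;
  real cohort missingness is visit-driven and almost certainly not
  MCAR, so passing tests here say nothing about informative-missingness
  bias. Default pair counts (1909 MZ, 1994 DZ) match a large adult
  registry.
- **Longitudinal tables** place baseline ages uniformly in 40–60 years
  with up to 17 years of follow-up and add a linear age trend,
  individual random intercepts and i.i.d. residuals. No random slopes,
  practice effects, or covariates — matching exactly the model the
  adjustment stage fits, which is the point of the fixture and also its
  limitation.
- **GWAS summary statistics**: true exposure effects
  Normal(0.3, 0.1), observed effects adding noise at the reported SE
  (0.01 by default — typical of meta-GWAS with ~1e5 samples); outcome
  effects are causal_effect × true exposure effect plus, for the
  invalid fraction, pleiotropy Normal(mean, sd). Effect-allele
  frequencies are uniform(0.05, 0.95) with A/G coding (A/T palindromes
  on request), emitted identically in both tables so harmonization is
  the identity unless a test scrambles coding. The generator does not
  simulate genotype-level LD; clumping takes its r² matrix from the
  caller. The mostly-positive exposure effects are deliberate: with
  effects centred at zero, the Egger orientation step (b_exp ≥ 0) flips
  the sign of pleiotropic outcome effects for half the instruments,
  turning planted *directional* pleiotropy into balanced pleiotropy —
  the intercept then correctly estimates ~0, and no estimator could
  (or should) recover the planted mean.

All generators consume a single PCG64 (`numpy.random.default_rng`)
stream fully determined by the config seed; identical configs reproduce
byte-identical outputs.

## Problem sizes used in the shipped checks

Parameter-recovery checks run the DoC model at 1000+1000 pairs over 8
replicates (registry scale, 1909+1994, in the acceptance script) and
the saturated ACE model at p = 3 over 5 replicates — the counting
identities that depend on p (108 parameters at p = 8) are verified
symbolically, so the heavier p = 8 fit adds nothing to the recovery
evidence. "Recovery" means the replicate-mean of every free parameter
lies within three replicate-spread standard errors of its generating
value; for the reciprocal path pair this spread is wide by nature
(single-seed estimates of a reciprocal pair trade off along a
likelihood ridge), which is a property of the design, not of the
optimizer. MR behaviour checks use 200 replicates of 50-SNP studies
(1000 for the type-I error rate).

## Known limitations

- No dominance (ADE), sex-limitation, ordinal-phenotype or
  definition-variable support; age is handled by pre-adjustment only.
- DoC identification degrades continuously as the latent A/C/E
  profiles of two factors approach each other; the package flags weak
  identification via the information condition number but cannot
  manufacture information the design does not contain.
- MR: no Steiger filtering, multivariable MR, or weighted median; LD
  must be supplied, not computed. The delta-method ratio variance
  ignores exposure-side uncertainty, which is the convention for the
  estimators implemented but understates variance for weak
  instruments.
- The mixed-model adjustment assumes a linear age effect; curvature in
  age would leak into the scores.
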