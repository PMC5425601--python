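# Methods

## Model and estimation

Both parameterizations are recursive linear-normal path models, so the joint
likelihood factors into per-equation Gaussian regressions (and, in the
multi-group case, per-group blocks). Consequences we rely on:

- Coefficient point estimates of unconstrained fits equal per-equation least
  squares; the test suite checks this against an independent OLS oracle.
- The information matrix of the mean parameters is block-diagonal across
  equations and groups — the cross second derivatives of the log-likelihood
  vanish identically, not merely in expectation. `asymptotic_cov_products`
  assembles the joint covariance of the a- and b-paths from these blocks and
  is verified against a finite-difference Hessian rather than assumed.
- Residual variances use the ML denominator (RSS/n, not RSS/(n−p)) so that
  −2 log-likelihood differences are exact Gaussian deviances and LR
  statistics are meaningful. Coefficient standard errors are therefore
  ML-scaled; the OLS-scaled versions differ by the factor n/(n−p) (≈1.3% at
  the study's n), and none of the study's conclusions are sensitive to the
  choice at those sample sizes.
- Intercepts are always estimated even though the catalog populations are
  zero-mean: real data are not, and no estimand involves intercepts.

**Constrained multi-group fits.** The linear equality constraints
(`a_equal`, `b_equal`, `cprime_equal`) share a slope across groups while
keeping per-group intercepts and residual variances. Given the variances
this is weighted least squares; given the coefficients the ML variances are
per-group mean squared residuals; we iterate to convergence (relative −2logL
change below 1e−12, cap 500 iterations).

The nonlinear product constraint `ab_product_equal` (equal indirect effects)
is fitted by maximizing the concentrated likelihood over
(a_G1, b_G1, b_G2) under the reparameterization a_G2 = a_G1·b_G1/b_G2, with
intercepts, c′ paths and variances profiled out in closed form, using BFGS
multi-started from the unconstrained and the {a_equal, b_equal} solutions.
When |b̂_G2| < 1e−6 the symmetric reparameterization solving for b_G2 is
used instead. A constrained deviance more than 1e−6 *below* the nested
unconstrained one is treated as an optimizer failure, not clamped away.
When `ab_product_equal` is combined with `b_equal`, the pair is fitted as
{a_equal, b_equal}: with a shared nonzero b, equal products are equal a
paths — this also makes the LR test for the product constraint coincide
exactly with the LR test for the a-path constraint in that configuration.

Note that the single-group fit and the multi-group fit with
{b_equal, cprime_equal} share the same *fixed-effect specification* but are
not numerically identical on finite data: the multi-group model keeps
per-group Y-intercepts and residual variances, so its shared b is a
variance-weighted estimate. They coincide exactly when the two groups carry
identical data (tested), and agree to sampling precision otherwise.

**Rank checks.** A design whose standardized condition number exceeds 1e10
raises a collinearity error naming the offending column. One corollary: data
with an *exactly* deterministic M = a·X make the Y-equation design
[1, M, X] singular, so fully noiseless datasets are rejected rather than
fitted; degenerate-but-fittable cases (Y an exact function of M, with M
carrying variation beyond X) are supported and recover b with zero residual
variance.

## Inference methods

- **z test (za3S)**: a3/se(a3) against the standard normal, two-sided.
- **Wald tests (WdiffS, WdiffM)**: delta method. avar(a3·b) =
  b²v(a3) + a3²v(b) + 2·a3·b·cov(a3,b); the four-parameter version adds the
  group-2 terms with a minus sign in the gradient. Covariances come from the
  computed joint block matrix. χ²(1), upper tail.
- **LR tests (LRaM, LRdiffM)**: deviance difference between nested fits,
  df = difference in free-parameter counts; negative differences within
  1e−6·(1+|−2logL|) are clamped to zero.
- **Bootstrap (PC/BC, ind/diff, S/M)**: resampling is stratified by group by
  default (group sizes fixed — matching the multi-group scheme and the
  study's fixed-n design); pooled resampling is available for the
  single-group approach. Replicate refits are vectorized closed-form least
  squares. A replicate with a degenerate design (zero X variance or a
  singular Y-equation cross-product) is redrawn up to 10 times, then dropped
  and counted; more than 1% drops flags the result, more than 10% is an
  error. Percentile and bias-corrected intervals computed from one shared
  draw set are the convention.
- **Quantile rule**: order statistics at index ⌊(B+1)·p_lo⌋ from below and
  ⌈(B+1)·p_hi⌉ from above, clamped to [1, B] — the symmetric resampling
  convention (25th and 976th of 1,000 draws at 95%). The rule matters: at
  B = 500 it places 12/501 ≈ 0.024 in each tail, a visible conservative bias,
  which is why calibration runs keep B = 1000.
- **BC adjustment**: z0 = Φ⁻¹(fraction of draws below the point estimate),
  ties counting one half (reduces bias from discrete estimates on small
  data); adjusted levels Φ(2z0 + z_{α/2}), Φ(2z0 + z_{1−α/2}); fractions of
  0 or 1 are clamped to 1/(2B), 1 − 1/(2B) and flagged.
- **Monte Carlo (MCind/MCdiff)**: draws of (a_G1, b_G1, a_G2, b_G2) from the
  normal centered at the estimates with diagonal covariance of squared
  standard errors — within-group cov(a,b) is zero because the coefficients
  come from different equations; cross-group covariance is zero by sample
  independence. Zero standard errors are legal and give degenerate point
  draws. Requires the unconstrained fit.
- Defaults B = R = 1000 draws, level 0.95; all draw machinery is bit-for-bit
  reproducible given a seed.

## The synthetic-data generator

`population_catalog()` defines 21 populations: three structural settings
(equal indirect effects 0.165/0.165; effects 0 vs 0.055; effects 0 vs 0.165
— coefficients a ∈ {0, 0.141, 0.424}, b = 0.390, c′ = 0) crossed with seven
residual-variance patterns (homogeneous; mediator variance 0.5 vs 1.0/1.5/
2.0; outcome variance 0.5 vs 1.0/1.5/2.0). X ~ N(0,1) per group: the unit
variance is pinned by the catalog's explained-variance table
(0.424²/(0.424² + 1) = 0.152). X is drawn fresh per group per replication
(random-X design, consistent with row resampling in the bootstrap).
Errors and X are exactly normal and intercepts are zero, so passing
calibration tests certifies behaviour under the stated generative model —
not under skewed errors, heteroscedasticity within group, measurement error
in M, or latent-variable structure, none of which the generator emulates.

Group sizes in the study grid are (150,150), (200,100), (100,200).

## The replication engine

`run_condition` derives per-replication seeds from the master seed through a
counter scheme (`SeedSequence(master, rep, stream)`), so conditions and
replications are independently reproducible and no method's draws depend on
which other methods run. Per replication it generates a dataset, fits what
the requested methods need, and records rejections (p < α for tests,
zero-exclusion for intervals), interval endpoints, and parameter estimates.
Failed replications are counted and excluded; more than 2% failing aborts
the condition. Aggregates carry Monte Carlo standard errors
sqrt(p(1−p)/n) on every rate. Coverage counts use closed intervals; a truth
strictly below the interval is a left-side miss, strictly above a
right-side miss, so coverage + left + right partitions the replications
exactly (the left/right orientation is a convention; the ratio inverts
cleanly if the opposite one is preferred).

Estimand conventions: the multi-group difference is G1 − G2 (first minus
second in the fit's group order); the single-group difference is focal −
reference (= a3·b). The engine books truth values per parameterization
accordingly. Group-label swaps leave every test statistic and p-value
unchanged and flip only the sign of the difference estimate.

## Problem sizes and tolerances in the shipped checks

The calibration checks in the test suite and the acceptance script use
1,000 replications for single-condition Type I error rates (the study's own
count), 600 for the inflation/deflation contrast, and 300 replications ×
1,000 bootstrap draws per condition for the 63-condition coverage/width
grid — sizes chosen so the whole suite runs on one CPU in minutes while
keeping Monte Carlo error well below the effects being checked. Rate
comparisons against published 1,000-replication values use three *combined*
standard errors, sqrt(p(1−p)(1/n_ours + 1/1000)), since both sides are
binomial estimates. Grid averages additionally include a between-condition
variance term s²_cond/k in their aggregated standard error, treating the
condition grid as strata of the design average.

## Known limitations

- Exactly two groups; a moderator with more levels (or a continuous one)
  needs a different design.
- Listwise deletion only; no missing-data machinery.
- No latent variables or measurement models: X, M, Y are observed scores.
- No robust/sandwich standard errors; inference is ML under normality
  (within-group heteroscedasticity across the X range is not modeled).
- The average coverage of the percentile-bootstrap difference interval over
  the full condition grid computes to ≈0.95 here; published studies of this
  design report slightly lower averages (≈0.94), a gap consistent with
  unstated percentile conventions in other software. The per-condition
  widths were validated against a 20,000-replication ground-truth sampling
  distribution of the difference estimator.
- The product-constrained fit exposes no analytic covariance matrix
  (standard errors are not defined for it in this package); Wald and Monte
  Carlo methods intentionally require the unconstrained fit.
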