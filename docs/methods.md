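# Methods

## The SWang(h, k) statistic

For a gene with case values `x₁..x_n` and control values `y₁..y_m`, fix a set
of moment orders — a contiguous range `h..k` (default 1..4) or an explicit
list such as `(1, 3, 5)`; write `K` for the number of orders.

1. **Power matrices.** `P₁` is the `K × n` matrix whose row for order `r`
   holds `x_i^r`; `P₂` likewise for the controls.
2. **Moment vectors.** `M₁`, `M₂` are the row means of `P₁`, `P₂` — the raw
   sample moments of each group.
3. **Pooled scatter.** `D₁`, `D₂` are the scatter matrices of the columns of
   `P₁`, `P₂` about their row means (sums of outer products, not divided by
   sample size); the pooled covariance is `S = (D₁ + D₂)/(n + m − 2)`.
4. **Statistic.** `T² = (nm/(n+m)) · (M₁−M₂)ᵀ S⁻ (M₁−M₂)`, with `S⁻` the
   Moore–Penrose pseudo-inverse, and

   `F = ((n + m − K − 1) / ((n + m − 2) K)) · T²`,

   referred to an `F(K, n + m − K − 1)` distribution for the p-value.

This is the classical two-sample Hotelling construction applied to the power
vectors `(x, x², …, x^k)` of each sample. Two exact identities anchor the
implementation and are enforced in the test suite:

- **SWang(1,1) ≡ t².** With a single first moment the statistic equals the
  squared pooled-variance t statistic and the p-value equals the two-sided
  t-test p-value (machine precision; verified to 1e-10 over thousands of
  random instances).
- **Affine invariance.** For contiguous designs `1..k`, mapping both groups
  through `x ↦ ax + b` (a ≠ 0) leaves the statistic unchanged, because the
  affine map acts as an invertible linear map on `(1, x, …, x^k)` and the
  Mahalanobis form is invariant under invertible linear maps. Verified to
  1e-8 relative over random maps including negative scales.

**Sample-size rule.** The reference distribution needs `n + m > k + 1`
(`df₂ = n + m − k − 1 ≥ 1`) and each group needs at least 2 samples for a
within-group scatter. Violations raise `InvalidDesignError`; the CLI exits
with code 3 and the message names the rule ("n + m must be greater than
k+1").

## Numerical choices

- **Preconditioning.** Raw moments of order 4 of values around 7 (typical
  log2 expression) span ~10 orders of magnitude and make `S` terribly
  conditioned. For contiguous designs `1..k` the statistic is affine
  invariant, so both groups are first jointly centered and scaled by the
  pooled mean and SD — mathematically a no-op, numerically decisive. Explicit
  (non-contiguous) designs are not affine invariant and are computed on raw
  powers.
- **Pseudo-inverse.** `S⁻` uses SVD with relative cutoff `K·eps`. On
  nonsingular problems it agrees with a direct solve to 1e-8 relative
  (tested); on rank-deficient problems (e.g. a constant gene) the statistic
  degrades gracefully and the result row is flagged `degenerate`.
- **Vectorization.** `swang_statistic_stack` evaluates all genes at once
  (einsum scatter accumulation + batched pseudo-inverse), keeping
  10,000-gene × multiple-sample-size simulations in seconds.

## Baselines

- **t**: pooled-variance two-sample t, two-sided.
- **F**: variance ratio `s²_case/s²_control` against `F(n−1, m−1)`,
  two-sided p as `2·min(sf, cdf)`.
- **SAM**: mean difference over `(pooled SE + s₀)` with `s₀ = 0.3` by
  default; permutation p-value over group-label reassignments — exhaustive
  when `C(n+m, n) ≤ 20,000` (`p = #{|d*| ≥ |d|}/total`), otherwise seeded
  random permutations with the `(1 + #exceed)/(1 + B)` estimator. The
  vectorized version shares one permutation set across genes.
- **Fold-change**: mean difference of (assumed log2) values; a fixed
  threshold of 1 (i.e. 2-fold) is its only operating point, so it
  contributes a single point rather than a p-value curve.

## Simulation design

Null and alternative draws come from a small distribution family (normal,
exponential, uniform, gamma, triangular, Cauchy, mixtures). The default null
is N(1, 1.5²). The default shape-only alternative is the **matched
exponential**: an exponential with location `mean − sd` and scale `sd`, so
its first two moments equal those of the normal control (for mean 1, SD 1.5:
loc −0.5, scale 1.5) while its skewness is 2 and excess kurtosis 6. FPR runs
use all-null genes and report the empirical exceedance of each p-value cutoff
in 0.01..0.10; power runs mark a 20% fraction of genes as differential and
report detection at α = 0.05, always with the binomial Monte-Carlo standard
error.

### Measured calibration and power (documented limits)

Two honest limits of the method at very small samples, reproduced by the two
deliberately failing tests in `tests/test_acceptance.py`:

- **Small-sample FPR.** At n = m = 5 the F reference is an approximation
  (the power vectors are not multivariate normal), and the tail is slightly
  heavy: measured FPR ≈ 0.015–0.02 at nominal cutoff 0.01 with 10,000 null
  genes, while the t-test stays inside its exact binomial band in the same
  runs. The excess shrinks as cutoffs grow (≈ 0.043 at 0.05, ≈ 0.073 at
  0.10 — conservative there) and with sample size.
- **Power at n = m = 10.** Under the matched exponential, SWang(1,4)
  (power ≈ 0.11) beats t and SAM (≈ 0.05, nominal level — they cannot see
  shape) but trails the variance-ratio F-test (≈ 0.14) and the fold-change
  point (≈ 0.14). Both of the latter are artifacts: the F-test's
  small-sample null is miscalibrated for non-normal data and the fold-change
  "power" is thresholded noise with no error control. From n = m = 15
  SWang(1,4) is ahead of every baseline, and by n = m = 25 decisively so
  (0.28 vs 0.20 for F, with t/SAM/fc at or below 0.05).

## Nonlinear interaction generator

Expression data where shape changes arise mechanistically: each gene has a
latent level `Z = baseline + ε`, `ε ~ N(0, noise_sd)`. In the case group, a
perturbed gene's observed value adds, over its neighbor genes,

`Σ ( a·E + b·E² + c·F + d·F² )`

where `E` is the neighbor's latent expression and `F = E − baseline` its
fluctuation, plus its own noise. Quadratic fluctuation terms (`d·F²`) are the
shape carriers: a pure `F²` gene is chi-square(1)-distributed (skewness √8,
excess kurtosis 12 — verified against Monte-Carlo at 10⁵ draws). Quadratic
*expression* terms at a typical baseline of 7 are dominated by their linear
part (`E² = 49 + 14ε + ε²`) and contribute mostly mean/variance shifts.

`match_moments=True` rescales each perturbed gene's case values to the
control mean and SD (calibrated on 20,000 auxiliary draws), producing the
pure shape-difference regime: the t-test stays at its nominal level while
the moment test detects — the scenario the test exists for.

## Moment estimators

`moments.py` uses the divisor-n ("g-type") conventions: skewness
`m₃/m₂^{3/2}` and excess kurtosis `m₄/m₂² − 3`. Under normality their
asymptotic variances are `6/m` and `24/m`; Monte-Carlo at m = 400 over
20,000 replicates reproduces both within 5% (measured ratios ≈ 0.98–0.99),
pinning the conventions down against a closed form.
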