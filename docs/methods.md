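# Methods

## Model and estimands

`trihet` targets balanced three-level trials: `n_c` clusters, each with
`n_s` subclusters of `m` participants, randomized at the cluster,
subcluster, or participant level with treated fraction `W̄`. The analysis
model is the linear mixed ANCOVA

Y_ijk = β₁ + β₂ W_ijk + β₃ᵀX_ijk + β₄ᵀW_ijk X_ijk + γ_i + u_ij + ε_ijk,

with mutually independent Gaussian random intercepts at the cluster and
subcluster levels. Two estimands are supported: the interaction vector β₄
(treatment-effect heterogeneity across subpopulations defined by the
modifiers X) and, after globally mean-centering X, the covariate-adjusted
average treatment effect β₂.

Conditional on X and W, outcomes within a cluster follow a nested
exchangeable correlation with within-/between-subcluster ICCs (α₀, α₁);
the modifier marginally follows the same structure with ICCs (ρ₀, ρ₁).
All design formulas are functions of the three eigenvalues of each
structure, so every production computation is O(1) in the cluster size;
dense matrices appear only in tests and debugging helpers.

### Assumptions

- Equal subcluster counts and sizes (balance). Unbalanced designs are out
  of scope; variable-size corrections would enter as inflation factors on
  the unit variances.
- Gaussian outcomes with correctly specified random-intercept structure
  (no random slopes), and model-based (not robust) standard errors.
- The modifier's second-moment structure is all that matters for design:
  binary modifiers enter through prevalence p via σ²_x = p(1−p).
- Exact allocation balance at the randomized level (enforced by the
  simulator; required of finalized designs, not during sample-size search).

## Variance formulas and their exactness

The unit variances σ²₄ (HTE) and σ²₂ (ATE) are defined on the
`lim n_c·n_s·m · var(·)` scale so they remain O(1) as any dimension grows,
and always factor into an unclustered base variance times a design effect.

A point documented here because it affects interpretation: we verified
against an exact expected-GLS-information computation (dense R⁻¹,
enumeration over balanced allocations, analytic Gaussian expectation over
X — see `tests/_oracles.py`) that

- the cluster-randomization HTE variance and all three ATE variances are
  **exact** (agreement to 1e−15 on small designs), while
- the subcluster- and participant-randomization HTE variances are
  **large-m approximations**: they drop lower-order contributions of the
  correlation inverse, with relative error on the order of a few percent
  at m ≈ 4 and below 1% for m ≥ 20 (confirmed independently by direct
  Monte Carlo of the GLS estimator). The package implements these
  standard closed forms as its production formulas and keeps the exact
  computation available through `trihet.power.mv_omega4`, which evaluates
  the exact expected information for any number of modifiers (p = 1
  included) and any randomization level.

Consequently `mv_omega4` with p = 1 reproduces `hte_unit_variance/(n_s·m)`
exactly under cluster randomization and up to the approximation above at
the lower levels.

## Power and sample size

- Scalar tests use the two-sided normal Wald power including the minor
  tail (indistinguishable from the one-tailed approximation at practical
  effect sizes, but analytically the correct rejection probability).
- The ATE under cluster randomization uses a noncentral-t criterion with
  the between-within degrees of freedom n_c − 2, solved by upward integer
  search because the critical value moves with n_c. This matches observed
  sizing behaviour where normal-theory rounding is anticonservative by one
  even step.
- Joint tests of p modifiers use the noncentral-χ²(p) power equation with
  noncentrality n_c Δᵀ Ω₄⁻¹ Δ; sample-size solves bracket by doubling and
  bisect over feasible integers.
- Feasibility rounding: under cluster randomization the solved n_c is the
  smallest integer ≥ the raw requirement with n_c·W̄ integral (smallest
  even integer for W̄ = 1/2); other levels take a plain ceiling because
  their randomized dimension is fixed by the design.
- Solving for m (or n_s) re-evaluates the unit variance at each candidate,
  since σ²₄ depends on both. HTE power always reaches any target as
  m grows (the design effect is bounded, θ₍₃₎(n_s, ∞) = (1−α₀)/(1−ρ₀));
  ATE power under cluster or subcluster randomization plateaus (λ₃ and λ₂
  grow linearly in m), and the solver reports this as an explicit
  unattainable-power error rather than returning the cap.
- Tail probabilities delegate to scipy's noncentral distributions; the
  default search cap is 10⁶.

## Simulator

The generator mirrors the analysis model exactly: nested Gaussian
components for the modifier — a_i ~ N(0, σ²_x ρ₁), b_ij ~ N(0, σ²_x(ρ₀−ρ₁)),
c_ijk ~ N(0, σ²_x(1−ρ₀)) — and for the outcome residuals with (α₀, α₁),
plus permutation randomization with exact balance at the randomized level.
Binary modifiers use a beta–beta–Bernoulli cascade whose two beta variance
fractions are chosen to match (p, ρ₀, ρ₁) exactly in second moments, which
is all the design formulas consume.

What the simulator deliberately does *not* emulate: unequal cluster sizes,
missing data, non-Gaussian outcome errors, secular time effects, or
informative treatment assignment. Passing calibration tests therefore
demonstrates internal consistency of formulas and inference under the
stated model, not robustness to violations of it.

Per-replicate seeds derive from (master seed, replicate index) via
`numpy.random.SeedSequence` spawn keys, so any replicate is reproducible in
isolation and results are independent of execution order. Identical seeds
produce byte-identical datasets and reports.

### Marginal ICC approximation

For comparison with covariate-unadjusted planning, the marginal outcome
moments integrate the modifier out conditional on treatment arm: with
b₃ = β₃ + β₄W̄, the modifier contributes c² = (b₃² + β₄²W̄(1−W̄))σ²_x, giving
σ²_y = σ²_{y|x} + c², weight ω = σ²_{y|x}/σ²_y, and marginal ICCs
α̃₀ = ωα₀ + (1−ω)ρ₀, α̃₁ = ωα₁ + (1−ω)ρ₁. The weighted-average form is a
derived reconstruction; tests gate it on a Monte Carlo moment oracle
(pooled within-arm covariances over 2000 simulated clusters) rather than on
the algebra alone.

## REML engine

On balanced data the per-cluster covariance shares eigenvectors with the
nested exchangeable structure, so with g = σ²_γ/σ²_ε and h = σ²_u/σ²_ε the
whitening operator is a three-projection filter (participant deviations,
subcluster-mean deviations, cluster means) applied in O(n). The restricted
likelihood is profiled over the fixed effects and σ²_ε, leaving a
two-parameter bounded optimization:

- start values from ANOVA mean squares of OLS residuals (clipped at zero);
- L-BFGS-B on (g, h) ∈ [0, 10⁴]² with a Nelder–Mead polish if the gradient
  method reports failure (the profiled surface can be extremely flat near
  a variance-component boundary);
- boundary estimates are exact zeros by construction;
- non-convergence is flagged on the result, never raised; the operating-
  characteristics driver refits once from null start values and then counts
  the replicate as failed, reporting rates over converged replicates with
  the failure count attached.

Wald tests use the model-based GLS covariance at the REML estimates: the
interaction against a standard normal (χ²(p) for joint tests), the ATE
against a standard normal or t(n_c − 2). The interaction statistic is
invariant to mean-centering of X and to the centered-vs-raw treatment
parameterization (tested).

On a 3360-observation test dataset the engine's restricted likelihood
optimum weakly dominates statsmodels MixedLM's (which serves as an
independent cross-check in the test suite, never as the implementation),
at roughly a tenth of the runtime.

## Problem sizes used in validation

Analytic checks run on exact closed forms and are instantaneous. The
simulation-backed checks use 500 replicates for empirical power and
parameter recovery and 1000 replicates for empirical size at the reference
scenario (42 clusters × 4 subclusters × 20 participants), chosen to give
Monte Carlo standard errors below 0.02 on a rejection rate — tight enough
to detect miscalibration at the reported tolerances. The full 48-scenario
grid with replication is available through `trihet report --reps N` for
users who want denser evidence.

## Known limitations

- Binary outcomes (GLMM), random covariate slopes, and unequal cluster
  sizes are out of scope.
- The lower-level-randomization HTE formulas are asymptotic in m (see
  above); for very small subclusters (m ≲ 5) prefer `mv_omega4`-based
  power.
- The between-within t correction is applied only to the ATE under cluster
  randomization; HTE tests use the normal reference throughout.
- No sandwich/robust variance option: planning and analysis assume the
  working correlation structure is correct.
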