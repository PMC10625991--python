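# Methods

## The testing problem

Given paired observations z_i = (x_i, y_i), i = 1..n, assumed mutually
independent draws from a bivariate distribution, the null hypothesis is
antipodal (diagonal) symmetry about the origin: z and −z identically
distributed. Under H₀ the sign indicator of each point — whether it lies
above or below the horizontal axis — is Bernoulli(1/2) independently of
the point's magnitude and axis, which is what makes sign tests
distribution-free: all inference conditions on the observed magnitudes
and randomises only the signs.

Both tests implemented here are *linear sign statistics*

    B = Σᵢ βᵢ·Uᵢ + C,     βᵢ iid Bernoulli(1/2) under H₀,

with fixed score vectors Uᵢ ∈ ℝ² and offset C chosen so that the
permutation mean ½ΣUᵢ + C is zero.

* **Angular-rank test** (`blumen`). Each data point defines an axis
  through the origin; axes are ranked by angle in [0, π) and the point
  with angle-rank i receives score 2·(cos(πi/n), sin(πi/n)). Replacing
  raw angles by equally spaced ranks makes the statistic fully
  distribution-free; the null covariance is exactly diag(n/2, n/2) and
  the two components are exactly uncorrelated.
* **Gradient test** (`brown`). The observed statistic is the gradient
  (divided by n) of the spatial-median objective at the origin. With the
  upper-half-plane representatives x₁…xₙ sorted by angle and extended
  cyclically by x_{n+i} = −xᵢ, the scores are the cyclic averages
  wᵢ = (1/n)Σ_{l=1}^{n−1} rot90(x_{i+l}); radii are retained, so the
  statistic is scale-equivariant and its null covariance ¼Σwᵢwᵢᵀ is
  data-dependent, typically with strong negative correlation.

Points exactly on the horizontal axis (y = 0) take γ = sign(x) and
angle 0; points at the origin are rejected as invalid input. Angle ties
are broken by original input order (stable sort), so results are
reproducible for lattice-valued data.

## Mid-p value and tail conventions

The permutation law of B has 2ⁿ equally likely atoms. The package's
mid-p at the observed B₀ = (τ, υ) is, by default, the **lower-orthant
mid-probability**

    mid-p(B₀) = Pr(b₁ < τ, b₂ < υ) + ½·Pr(boundary),

where "boundary" is the attainment boundary of the closed orthant
(outcomes tying B₀ in at least one coordinate while not exceeding it in
the other). Half-weighting the whole boundary is the two-dimensional
analogue of the univariate mid-p rule and centres the discrete value on
the continuum CDF that the analytic approximations target; the
alternative rule that half-weights only the exact joint tie is available
as `tie_rule="joint"`. Equality is judged at absolute tolerance
1e−9·(1+|τ|+|υ|) per coordinate — tight enough that only genuine lattice
coincidences (cosine symmetries, integer data) register.

Because the permutation law is exactly antipodally symmetric
(B and −B have the same distribution), the lower-orthant value at B₀
equals the upper-quadrant value at −B₀; "lower" versus "upper" is a
data-sign convention, not a substantive choice. Three tail conventions
are exposed uniformly across methods:

* `cdf` (default) — the lower orthant at B₀, evaluated by the four-term
  approximation directly (see below). This is the convention calibrated
  against exact enumeration on the bundled refraction data; it
  reproduces the published analysis of that dataset.
* `quadrant` — the upper orthant, via the inclusion–exclusion
  completion 1 − LR₁(τ) − LR₂(υ) + F̂(τ, υ); by default evaluated after
  reflecting coordinates so both observed components are ≥ 0.
* `complement_cdf` — 1 − F̂(τ, υ), the probability that at least one
  coordinate exceeds its observed value (a union event; kept because
  the four-term CDF sum makes it available at no cost).

The orthant mid-p is **directional**: it is small when the observation
is extreme toward the lower-left (equivalently, when the sign-flipped
data are extreme toward the upper-right). It is *not* a uniformly
distributed p-variable under H₀ — see the level study below.

## Saddlepoint machinery

The joint CGF of (b₁, b₂) is

    K(t, u) = Σᵢ log{½ + ½ exp(t·U₁ᵢ + u·U₂ᵢ)} + t·c₁ + u·c₂,

finite, smooth, and strictly convex on the span of the scores;
marginals are K₁(t) = K(t, 0), K₂(u) = K(0, u). Evaluation uses
`logaddexp`, so exponents of ±800 are routine. Per-term weights
pᵢ(1−pᵢ) with pᵢ = logistic(t·U₁ᵢ + u·U₂ᵢ) give the analytic gradient
and Hessian.

**Root solving.** The joint saddlepoint (t₀, u₀) solves ∇K = (τ, υ):
damped Newton from (0, 0) with the analytic Hessian and step-halving on
the residual norm (the Newton direction is a descent direction for the
residual by convexity); convergence at residual ≤ 1e−10·(1+|τ|+|υ|),
200-iteration cap. The marginal saddlepoint solves the strictly
increasing K₁′(t) = τ by bracketed Newton with bisection safeguard.
A root exists iff the target lies strictly inside the convex hull of
the 2ⁿ attainable statistics; outside/boundary targets raise a
descriptive no-root error.

**Four-term tail approximation.** The lower-orthant CDF is approximated
by the four-term sum F̂ = I₁₁ + I₂₁ + I₁₂ + I₂₂ built from the joint
saddlepoint, the marginal saddlepoint, and the transformed coordinates

    τ₁ = sgn(t̂₀)·√(−2(K₁(t̂₀) − t̂₀τ)),
    w_{u₀} = sgn(t₀)·√(−2(K(t₀,u₀) − K₂(u₀) − t₀τ)),
    υ₀ = sgn(u₀)·√(−2(K(t₀,u₀) − K₁(t̂₀) − (t₀−t̂₀)τ − u₀υ)),
    b = (w_{u₀} − τ₁)/υ₀,  G = √(K_uu − K_tu²/K_tt),
    ρ₁ = −b/√(1+b²),  υ₁ = (υ₀ − b·τ₁)/√(1+b²),

with I₁₁ = Φ₂(τ₁, υ₁; ρ₁), I₁₂ = Φ(w_{u₀})·φ(υ₀)·(1/υ₀ − 1/(u₀G)),
I₂₁ = Φ(υ₀)·φ(τ₁)·(1/w_{u₀} − 1/(t₀√K_tt)), and
I₂₂ = exp(K(t₀,u₀) − t₀τ − u₀υ)·(1/w_{u₀} − 1/(t₀√K_tt))·(1/υ₀ − 1/(u₀G))/2π.
All square-root arguments are non-negative in exact arithmetic
(convexity along lines in (t, u)-space); arguments within 1e−12 of zero
are clipped, anything worse raises a numeric-inconsistency error.
When the two coordinate supports are disjoint (K_tu ≡ 0) the orthant
forms factorize exactly into products of univariate Lugannani–Rice
tails Φ(ŵ) + φ(ŵ)(1/ŵ − 1/û); this identity is enforced in the tests to
1e−10.

**Degeneracies.**

* *Near-zero saddlepoints* (|t₀|, |u₀| or |t̂₀| < 1e−6): the I-terms have
  removable singularities at zero. The observed value is perturbed by
  ±1e−4 of the statistic's null standard deviation and the two results
  averaged; a diagnostic flag records this. Evaluation exactly at the
  permutation mean returns a finite, flagged value close to the
  centred orthant probability.
* *Support-boundary observations* (e.g. every sign identical — the
  statistic is a vertex of its support hull, no finite saddlepoint) and
  *saturated expansions* (extreme interior saddlepoints driving the
  four-term sum outside [0, 1]): the approximation is abandoned for
  exact counting (enumeration for n ≤ 25, else seeded Monte-Carlo),
  with a diagnostic flag. This keeps every simulation-study evaluation
  finite and in (0, 1).

The four-term expansion is anchored at the lower-left corner of the
orthant; it is accurate when the evaluated orthant probability is small
or moderate, which the default convention guarantees for observations
in the direction of interest. For targets deep in the upper-right
region of a strongly correlated system the direct sum degrades; the
package keeps the direct evaluation (matching the published analyses)
rather than switching anchors by region, and the accuracy studies
quantify the consequences.

## Reference computations

* **Exact enumeration** — all 2ⁿ indicator vectors in integer
  arithmetic, chunked at 2¹⁸ rows; guarded at n ≤ 25 (≈3.4e7
  evaluations), beyond which the error message points to Monte-Carlo.
* **Monte-Carlo permutation** — seeded iid Bernoulli(1/2) indicator
  matrices, same counting rule, binomial standard error
  √(p̂(1−p̂)/n_perms); default 10⁶ permutations.
* **Normal approximation** — the limiting Gaussian with mean 0 and
  covariance ¼ΣUᵢUᵢᵀ; orthant probabilities via the Genz bivariate
  normal CDF (absolute accuracy well below 1e−7; |ρ| = 1 by closed
  forms). Two correlation conventions are exposed: `standardized`
  (default; covariance over the product of standard deviations) and
  `unnormalized` (covariance over the product of *variances*). The
  latter is not a correlation in the usual sense; it reproduces
  published baselines that standardized without the square root, and it
  materially changes results exactly when |ρ| is large — i.e. for the
  gradient test, not the angular-rank test (whose ρ is identically 0).

## Synthetic data and the simulation harness

Generators (all seeded, returning `BivariateSample`):

* `gen_bvnormal(n, rho, seed)` — standard normal marginals, correlation
  ρ by Cholesky.
* `gen_bvpoisson(n, rho, seed)` — trivariate reduction X = Y₁+Y₃,
  Y = Y₂+Y₃ with λ₁ = λ₂ = λ(1−ρ), λ₃ = λρ and base intensity λ = 5
  (configurable), giving correlation exactly ρ; the all-zero pair is
  redrawn since a point at the origin has no sign.
* `gen_bvexponential(n, seed)` / `gen_bvlogistic(n, seed)` —
  independent unit-rate exponential / standard logistic marginals.
* `symmetrize_null(sample, seed)` — multiplies each point by an
  independent ±1, making the symmetry null hold *exactly* for any base
  distribution while preserving magnitudes.

Both studies symmetrize every generated dataset. For the accuracy study
this is a deliberate design choice: with raw all-positive exponential
or Poisson data every sign indicator equals +1, the observed statistic
sits on a vertex of its support hull (no finite saddlepoint) and the
angular-rank statistic is the same for every dataset — the benchmark
would be degenerate. Symmetrizing is exact for the permutation law
(which conditions on magnitudes) and leaves the antipodally symmetric
normal generator distributionally unchanged.

**Accuracy study** (`run_accuracy_study`): per dataset, the saddlepoint,
normal and reference ("exact") mid-p; reported are Sad.P — the
percentage of datasets where the saddlepoint is closer to the reference
than the normal (ties ½) — and E.sad/E.nor, the mean relative absolute
errors with the reference as denominator (reference-zero datasets are
excluded and counted). The reference is full enumeration when
configured and n ≤ 25, else seeded Monte-Carlo with `n_perms`
permutations. The reference's noise is part of the Sad.P metric: at
n = 20 a 10⁵-permutation reference (se ≈ 1.6e−3) is as noisy as the
saddlepoint's own error and randomises roughly 40% of the per-dataset
comparisons (Sad.P ≈ 72), a noise-free enumeration reference gives
Sad.P ≈ 95, and a 10⁶-permutation reference — the benchmark design the
package's headline numbers use — gives ≈ 89.

**Level/power study** (`run_level_study`): the orthant mid-p is a
bivariate probability-integral-transform value, and for independent
components P(F(B₀) < α) = α(1 − ln α) — about 0.195 at α = 0.05 — so
rejecting when the raw mid-p is below α would roughly quadruple the
nominal level. A valid test is obtained by calibration: each method's
orthant score for the observed statistic is referred to the permutation
distribution of the exact orthant score, estimated from
`n_calibration` (default 2048) seeded sign assignments by pairwise
dominance mid-counting, and the method rejects when the calibrated p
falls below α. The `simulation` method feeds its own dominance score
through the same calibration and is an exact-level permutation test up
to Monte-Carlo error; the saddlepoint and normal methods inherit level
deviations only through their approximation error near the rejection
threshold (which sits at orthant probabilities near 0.01, i.e. in the
tail where the approximations differ most). The resulting test is
directional (it detects location shifts toward the lower-left of the
statistic's space; for power against the opposite direction flip the
data's signs). For the null study every dataset is symmetrized; for a
power study a location shift δ is added to every point instead.

Study problem sizes used by the acceptance script: 1000 datasets for
the type-I-error study (binomial se ≈ 0.007) and 300 datasets with the
enumeration reference for the accuracy benchmark.

## Known limitations

* The four-term expansion evaluated directly at the observed statistic
  degrades for strongly correlated score systems when the evaluated
  orthant probability is large (≳0.5); values escaping [0, 1] trigger
  the exact-counting fallback, but moderately inaccurate in-range
  values in that regime do not.
* Against the *corrected* (standardized-correlation) normal baseline,
  the saddlepoint's accuracy advantage for the gradient test narrows at
  very small n: with n = 12 and heavy-tailed (exponential) radii the
  two are comparable. The advantage is clear against the
  unnormalized-correlation baseline and in the tails.
* For integer-valued (Poisson) data the gradient statistic's lattice is
  very coarse at small n and the continuous approximation carries
  median relative errors of order 10%.
* The calibrated level test's threshold is estimated from 2048
  permutations per dataset, adding ≈0.005 noise per rejection decision;
  this averages out over a study but matters for single datasets.
* The exact-enumeration guard (n ≤ 25) caps enumeration at ≈3.4e7
  statistic evaluations — a few seconds of work; beyond it the seeded
  Monte-Carlo path is the documented route.
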