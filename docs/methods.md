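# Methods

## Composite index: projection pursuit with an accelerated GA

The index treats resilience scoring as a dimension-reduction problem:
find the linear projection of the normalized indicator matrix that is
most "interesting", where interestingness `Q(a) = S_z · D_z` rewards
projections that spread samples out overall (`S_z`, the sample standard
deviation with the n−1 denominator) while keeping local clusters dense
(`D_z`). The density term sums `(R − r_ij)` over all *ordered* pairs with
`r_ij = |Z(i) − Z(j)| ≤ R`, including the diagonal `i = j` (each diagonal
term contributes `R`); a configuration switch (`GAConfig.include_diagonal`)
drops the diagonal for sensitivity analysis. Including it follows the
unrestricted double sum of the defining formula and only shifts `D_z` by
the constant `n·R`, which does not move the optimal direction at fixed
`R`; with the spread-proportional default radius it has no practical
effect on the ranking of directions either.

Normalization is direction-aware min–max over the pooled panel (all units
and years jointly) so one index is comparable across time; per-year
normalization would re-base the index every year. Negative-direction
indicators are reversed, so larger normalized values always mean more
resilience and the optimal loadings can be constrained nonnegative.
Constant columns carry no information and are mapped to 0.5 to avoid a
zero division.

**Window radius.** `R` is not identified by the objective itself; the
default recomputes `R = 0.1 · S_z(a)` for every candidate direction, a
common convention in the projection-pursuit literature that keeps the
density window proportional to the current spread. A fixed global `R` can
be supplied instead (`GAConfig.window_radius`). Constant projections get
a floor of 1e−6 with a warning.

**Optimizer.** Real-coded GA over `[0,1]^p` with rank-based selection
(linearly decreasing weights), arithmetic crossover (per-gene convex
combination, probability 0.8), uniform single-gene mutation (probability
0.2 per individual), and two elites carried unchanged. Candidates are
repaired onto the feasible set {`a ∈ [0,1]^p`, `‖a‖₂ = 1`} by clipping to
the box and scaling to unit norm — valid because the Euclidean norm of a
nonnegative vector is at least its largest component, so scaling never
leaves the box; an all-zero candidate is resampled. "Acceleration"
re-bounds the per-coordinate search interval to the span of the top 5% of
the population, padded by 10% of the current interval so the box cannot
collapse prematurely, then reinitializes; the incumbent best is always
retained, making the best-Q trace non-decreasing. Cycles stop after 20
rounds or when a round improves the objective by less than 1e−6.
Defaults (population 400, 30 generations per cycle) converge reliably on
a 360 × 22 panel in seconds; the density term is evaluated in
O(n log n) per candidate via sorting and prefix sums, verified in the
test suite against the brute-force double sum.

Internally the optimizer works in a canonical (name-sorted) column order
and maps the direction back, so results are exactly invariant to the
order indicator columns arrive in.

**Weights.** Reported as squared loadings `a_j²`, which sum to one under
the unit-norm constraint; renormalized raw loadings `a_j / Σ a_j` are
available as an alternative convention. Both are emitted because
published weight tables rarely state which convention they use.

## Causal stage: DML for the partially linear panel model

The target is θ₀ in `Y = θ₀ D + g(X) + U` with `E[U | D, X] = 0` and a
first stage `D = m(X) + V`. Nuisances `ĝ ≈ E[Y | X]` and `m̂ ≈ E[D | X]`
are learned out-of-fold (K-fold cross-fitting; the prediction for a
sample never uses its own fold), and the estimator is the orthogonalized
ratio

```
θ̂ = ( Σ V̂_i D_i )⁻¹ Σ V̂_i (Y_i − ĝ_i),      V̂_i = D_i − m̂_i.
```

Its score `ψ_i = V̂_i (Y_i − ĝ_i − θ̂ D_i)` has exactly zero empirical mean
at θ̂ (asserted to 1e−8·scale in tests) and is first-order insensitive to
nuisance errors. The variance estimate is the sandwich
`J⁻¹ (n⁻¹ Σ ψ_i²) J⁻¹ / n` with `J = n⁻¹ Σ V̂_i D_i`; p-values use the
standard normal reference. The multi-treatment variant stacks the
residualized treatments into a matrix and solves the corresponding linear
system; rank deficiency of the residualized treatment block raises an
error naming the collinear columns.

Concrete choices where the procedure is under-specified in general use:

- **Folds** are stratified by unit: each unit's years are dealt
  round-robin (random offset) across the K folds, so every fold spans
  units proportionally and no unit is concentrated in one fold.
- **Repetitions.** Fold assignment is redrawn `n_repetitions` times
  (default 101, kept odd); the point estimate is the per-coordinate
  median and the variance uses the median-aggregation rule
  `median_r(σ²_r + (θ_r − θ_median)²)`, which charges the split-to-split
  dispersion to the reported uncertainty.
- **Fixed effects** enter as dummy columns appended to the controls the
  learners see (year, unit, both, or coarse-group × year), not as a prior
  demeaning transform — flexible learners can then interact them with the
  controls. The "time–location interaction" variant uses a coarse unit
  grouping (default: the major-producer flag) crossed with year, because
  a full unit × year interaction is saturated on a panel whose
  observational unit is the location itself.
- **Interaction terms** for moderation designs center both factors before
  multiplying, so the main effects stay interpretable as effects at the
  sample mean of the other factor; a no-centering switch exists.
- **Learners.** Random forest: 100 trees (tests and the recovery study
  use 25 for speed), unbounded depth, √p features per split, minimum leaf
  1. Neural net: one hidden layer of 100 ReLU units with linear output,
  Adam (learning rate 0.001), 100 epochs, L2 penalty 1e−4; features and
  the target are standardized inside each training fold (nets require
  scaling; forests receive raw features). `ridge_linear` and `mean_only`
  learners exist for closed-form and hand-oracle checks.
- **Identification guards.** A residual treatment variance below
  1e−12 of the treatment's scale aborts with a non-identification error
  (the controls fully explain the treatment).

## Synthetic panel generator

The generator emulates the *structural assumptions* of the analysis — not
the marginal distributions of any real provincial data. A balanced panel
(default 30 units × 2011–2022, n = 360) is built as

```
FASCR = 1.3 + θ_T·TEMP + θ_R·RAIN + θ_int·(SID_c × TEMP_c)
        + g(X) + unit FE + year FE + ε,
```

with defaults θ_T = −0.015, θ_R = −0.001, θ_int = 0.15,
ε ~ N(0, 0.1²), and unit/year effects N(0, 0.05²).

- **Controls** are seven iid standard normals (internally `Z`), emitted on
  location/scale typical of a provincial panel (urbanization share ≈
  0.60 ± 0.12, etc.). The nuisance and first stages operate on `Z`.
- **Nuisances.** The nonlinear form is piecewise-constant:
  `g(Z) = 0.125·H₁ + 0.10·H₂ + 0.15·H₃ + 0.12·H₄ + 0.10·H₀₁` with regime
  terms `H_j = 1(Z_j > 0) − ½` and `H₀₁ = 1(Z₀>0)1(Z₁>0) − ¼`. Threshold
  nuisances are genuinely nonlinear — a linear adjustment is misspecified
  and naive OLS is measurably biased on these panels — while lying inside
  the function class that tree-ensemble learners estimate consistently at
  panel sample sizes. That alignment is deliberate: consistent nuisance
  estimation is the precondition for the calibrated-recovery and
  CI-coverage guarantees the test suite asserts; smooth
  quadratic nuisances are estimated too poorly by a √p-feature forest at
  n = 360 to support them. A purely linear form
  (`g = Σ α_j Z_j`) is available for closed-form checks.
- **Confounding.** TEMP loads on regimes of Z₀, Z₁ (coefficients 1.5,
  1.0, interaction 0.8) plus N(0, 3²) innovations; RAIN on regimes of Z₁,
  Z₂ (6, 4, interaction 3) plus N(0, 30²). Climate innovations are iid
  across unit-years — no persistent unit component — so the
  influence-function variance estimator is valid without clustering;
  geographic level differences are carried by the controls. Loadings
  scale with `confounding_scale` (0 gives an unconfounded panel).
- **Climate scales** default to the physically plausible convention
  (TEMP ≈ 13 ± 3, RAIN ≈ 77 ± 30); `climate_convention="printed"` swaps
  the two scales to match descriptive tables whose TEMP/RAIN labels
  appear interchanged.
- **Moderator.** Six crop shares per unit-year (Dirichlet(2.5) unit
  profiles with lognormal year jitter; degenerate and equal-share
  profiles available) give a Simpson index strictly inside (0, 1); the
  moderation term multiplies centered SID with centered TEMP.
- **Indicators.** The 22 indicators are monotone noisy transforms of the
  standardized outcome (the latent resilience signal): a signed linear
  form plus N(0, 0.8²) noise, every third passed through an exponential;
  negative-direction indicators receive the opposite sign, so Spearman
  correlations respect the declared directions.
- **Missingness** is injected missing-at-random into indicator columns
  only (default rate 0.02), never into the outcome, treatments or
  controls, and never removes a unit-series' last observation. Repair is
  linear interpolation along year within unit; boundary gaps take the
  nearest observed value, since linear interpolation does not extrapolate.

What the generator does **not** emulate: real marginal distributions,
spatial correlation between provinces, serial dependence in controls,
clustered or heteroskedastic measurement error, and attrition. Passing
recovery tests therefore demonstrate the estimator's correctness under
the model's own assumptions, not its performance on any particular real
panel.

## Other numerical choices

- **Winsorization** clamps to order-statistic cutpoints (the observation
  at or below the lower position, at or above the upper), computed on the
  pooled panel. Interpolated quantiles would make the operation
  non-idempotent (re-quantiling already-clipped data drifts past the
  clipped mass); exact idempotence was judged the more useful contract.
- **Median splits** rank units by their panel mean of the split variable
  and cut at the median of unit means, ties to the lower group, so every
  unit lands wholly in one subgroup and a 30-unit panel splits 15/15.
- **Lagged controls** drop the first `lag` years of each unit from the
  estimation sample (no backfill), shrinking a 30 × 12 panel to 330 rows.
- **Simpson index** renormalizes the six crop shares before squaring, so
  raw planted areas and shares give identical values.
- **Determinism.** Every stochastic component (generator, GA, fold
  draws, learners) descends from explicit integer seeds via seed
  sequences; equal configurations reproduce byte-identical output.

## Problem sizes in the test suite

The suite is sized for a single CPU: the recovery/coverage study uses 100
synthetic panels at n = 360 with 25-tree forests and one split
repetition per panel; GA-versus-grid optimality uses 17 two-indicator
instances (n ≤ 30) and 3 three-indicator instances (n = 15), where the
quarter-sphere can be swept exhaustively at 1e−3 angular resolution; the
orchestration tests run reduced GA populations and ridge learners. These
sizes are the package's own choices for a fast, deterministic suite; all
defaults remain available for full-scale runs.

## Known limitations

- The GA is a stochastic global optimizer; optimality is guaranteed only
  against the tested low-dimensional oracles, not in general.
- Influence-function standard errors assume scores uncorrelated across
  observations; with strongly clustered treatment innovations a
  cluster-robust variant would be needed (not implemented).
- The moderation design treats the moderator as exogenous given the
  controls; no instrument-based variant is provided.
- Forest learners at 25–100 trees retain some smoothing bias; the
  recovery guarantees are calibrated at the shipped defaults, and
  materially harder nuisance classes (high-frequency smooth functions,
  many weak confounders) will degrade them.
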