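# climres

Composite supply-chain resilience scoring and double-machine-learning
(DML) estimation of climate effects on province–year panels.

The package is aimed at applied econometricians and food-systems
researchers who want to (1) collapse a multi-indicator panel into a single
resilience index without hand-picked weights, and (2) estimate how climate
exposures shift that index while adjusting flexibly for confounding
controls. Because the underlying provincial yearbook data are not
redistributable, the package ships a synthetic-panel generator with known
ground truth so every stage of the pipeline is testable end to end.

## The two models

**Projection-pursuit index (RAGA-PPC).** Each of the 22 resilience
indicators is min–max normalized with its declared direction (negative
indicators are reversed), pooled over all units and years. The composite
score of sample *i* is the projection

```
Z(i) = Σ_j a_j X*_ij,      Σ_j a_j² = 1,  a_j ∈ [0, 1],
```

with the direction `a` chosen to maximize the projection index
`Q(a) = S_z · D_z`: `S_z` is the sample standard deviation of the
projections (between-sample spread) and `D_z = Σ_i Σ_j (R − r_ij) · u(R −
r_ij)` their local density inside a window of radius `R` (default
`R = 0.1·S_z`). The maximization runs on a real-coded accelerated genetic
algorithm: rank selection, arithmetic crossover, uniform mutation,
elitism, and interval "acceleration" that shrinks the search box to the
elite span each cycle. Indicator weights are reported as `a_j²` (they sum
to one).

**Partially linear DML.** The climate effect θ₀ in

```
FASCR_it = θ₀ · GCC_it + g(X_it) + U_it,     GCC_it = m(X_it) + V_it,
```

is estimated by cross-fitted partialling-out: random-forest (or
neural-net) learners predict the outcome and the treatment from the
controls out-of-fold, and θ̂₀ = (Σ V̂·D)⁻¹ Σ V̂·(Y − ĝ) uses the treatment
residual as its own instrument, making the score Neyman-orthogonal to
first-order nuisance errors. Standard errors come from the
influence-function sandwich; sample splitting is stratified by unit,
repeated, and aggregated by the median with the median-aggregation
variance adjustment. A multi-treatment variant estimates moderation
designs (climate + Simpson crop-diversification index + centered
interaction) jointly.

Around these two models the package provides the full study battery:
four fixed-effect configurations, unit exclusion, 1/99 and 5/95
winsorization, time–location interaction fixed effects, fold-ratio and
learner swaps, one-period-lagged controls, producer-region and
mechanization subgroup splits, and the moderation analysis — each as a
composable operation and as a `climres` CLI subcommand
(`simulate`, `index`, `estimate`, `robustness`, `report`).

## Worked example

```python
from climres import (
    SyntheticConfig, generate_panel, interpolate_missing,
    ProjectionPursuit, GAConfig, PanelDML, DMLConfig, LearnerSpec,
)

panel, truth = generate_panel(SyntheticConfig(seed=7))   # 30 units x 12 years
df = interpolate_missing(panel.frame)                    # repair indicator gaps

ppc = ProjectionPursuit(df.drop(columns=["FASCR"])).fit(
    GAConfig(population_size=200, n_generations=20, acceleration_rounds=8, seed=7)
)
print(ppc.summary())

model = PanelDML(df, outcome="FASCR", treatments="TEMP")
res = model.fit(DMLConfig(n_folds=5, n_repetitions=11,
                          learner=LearnerSpec(n_trees=25), fe_mode="none", seed=7))
print(res.summary())
```

prints (abbreviated):

```
Projection-pursuit composite index (RAGA)
samples:    360    indicators: 22
Q* = 123.600580   Sz = 0.531963   Dz = 232.348167   R = 0.053196
weights: squared
...

Partially linear DML results
========================================================================
outcome: FASCR   n = 360   folds = 5   reps = 11
learner: random_forest   fixed effects: none
------------------------------------------------------------------------
treatment              coef    std err        t    P>|t|    [0.025    0.975]
TEMP                -0.0139     0.0041    -3.40    0.001   -0.0220   -0.0059
```

The index stage reports the optimized objective `Q* = S_z · D_z`, the
window radius it used, and the per-indicator loadings/weights. The DML
stage estimates the temperature effect at −0.0139 (SE 0.0041): a one-unit
rise in temperature lowers the resilience score by about 0.014, a
significant negative effect whose 95% interval comfortably covers the
generating value −0.015 embedded in this synthetic panel.

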