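# paceshape

Diet changes how long animals live — but does it merely stretch or compress
the mortality trajectory (its **pace**), or does it change the trajectory's
time-standardised topography (its **shape**)? `paceshape` is a Python
library for answering that question on geometric-framework nutrition
experiments: cohorts of individually measured animals (the motivating
design is 1008 female *Drosophila melanogaster* on 28 diets crossing 7
protein:carbohydrate ratios with 4 total concentrations), each with a mean
daily protein intake P, carbohydrate intake C (μg/day) and a lifespan.

It is written for experimental biologists and biodemographers who want to
decouple nutritional effects on lifespan from nutritional effects on
aging itself.

## The measures and models

**Pace** is life expectancy at age zero, the mean observed lifespan:
e(0) = ∫ l(x) dx, computed as the discrete sum over the empirical survival
function. **Shape** comes from the Gini coefficient G of the lifespan
distribution (the normalised area between the Lorenz curve and the
equality diagonal):

- S = 1 − 2G, and the rescaled shape S_r = (1 + S)/(1 − S) = (1 − G)/G.
- G = 0.5 (S_r = 1): mortality constant over age — negligible senescence.
- G < 0.5 (S_r > 1): mortality rises with age — positive senescence; S_r
  reads as the fold increase of mortality over the life course relative to
  its average level.
- G > 0.5 (S_r < 1): negative senescence; G = 0 is the sharp-senescence
  extreme (everyone dies at the same age).

Per-diet pace and shape values are then analysed over the (P, C) intake
plane with Lande–Arnold response surfaces on Z-transformed responses:

    R = α + β_P P + β_C C + ε                                   (linear)
    R = α + β_P P + β_C C + γ_PP P² + γ_CC C² + γ_PC PC + ε     (quadratic)

Two landscapes (e.g. pace vs shape) are compared by sequential model
building — partial F-tests of trait×gradient interactions on the stacked
design at the linear, quadratic and correlational levels, with univariate
follow-ups — and by the angle θ = cos⁻¹(a·b/‖a‖‖b‖) between the two linear
gradient vectors, with a resampling 95% CI. Smooth landscapes for plotting
are penalised thin-plate splines with the smoothing parameter λ selected
by minimising the generalised cross-validation score.

Because raw per-fly data of this kind are rarely deposited, the package
ships a first-class simulator: diet-dependent Gompertz hazards
μ(x) = a·e^{bx} over the 7×4 grid, with per-fly intakes scattered around
diet targets. Its defaults put the lifespan optimum at high-carbohydrate /
low-protein intake and a shallow shape minimum at intermediate
carbohydrate, so every downstream stage is testable end to end.

## Worked example

```python
from paceshape import (SimConfig, SurfaceData, build_default_grid, fit_linear,
                       sequential_compare, angle_credible_interval,
                       simulate_cohort, summarise_cohort)

cohort = simulate_cohort(SimConfig(seed=1))            # 1008 flies, 28 diets
summary = summarise_cohort(cohort, grid=build_default_grid())
pace = SurfaceData.from_summary(summary, "pace")       # Z-transformed
shape = SurfaceData.from_summary(summary, "s_rescaled")
print(sequential_compare(pace, shape).to_frame())
angle = angle_credible_interval(fit_linear(pace), fit_linear(shape), seed=1)
print(angle)
```

prints (seed 1):

```
        level  ss_reduced  ss_complete  df1  df2        F        p
       linear   22.886499    22.261492    2   50 0.701892 0.500464
    quadratic   21.236786    16.764808    2   46 6.135202 0.004346
correlational   16.031078    15.917785    1   44 0.313163 0.578584
theta = 5.83 deg, 95% CI (0.47, 31.39)
```

Per-diet pace here spans 19.3–39.7 days while S_r stays in 2.2–6.0 (all
positive senescence): under the simulator's defaults diet moves life
expectancy strongly, the quadratic (carbohydrate-curvature) difference
between the pace and shape landscapes is significant (F₂,₄₆ = 6.14,
p = 0.004, attributable to carbohydrate in the univariate follow-up), and
the two traits' linear optima point in similar directions (θ ≈ 6°). Each
capability has a narrative script under `examples/`; the same analyses run
from the shell via the `paceshape` CLI (`simulate`, `metrics`, `surface`,
`compare`, `landscape`, `run-all`).

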