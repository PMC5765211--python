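# Methods

## Pace and shape estimators

Pace is life expectancy at age zero, estimated by the sample mean of
observed lifespans — the discrete form of e(0) = ∫ l(x) dx for the
empirical death distribution, with age zero defined as assay start. No
life-table smoothing or radix is applied.

Shape is the Gini coefficient G of the lifespan distribution. The primary
estimator is the mean-normalised pairwise-difference form
G = Σᵢⱼ|xᵢ − xⱼ| / (2 n² x̄), evaluated with the equivalent sort-based
O(n log n) formula; an opt-in `corrected=True` applies the small-sample
n/(n − 1) denominator. Samples with all lifespans equal return exactly 0.
Ties (e.g. from daily recording) need no special handling. Derived
measures: S = 1 − 2G and S_r = (1 − G)/G (reported as infinite at G = 0,
the sharp-senescence extreme). Senescence is classified from G with a
tolerance band: negligible when |G − 0.5| ≤ 0.01 (finite samples never hit
0.5 exactly), positive below, negative above. Note a terminological trap in
the surrounding literature: at G = 0.5 the *rescaled* shape equals 1 while
the non-rescaled S equals 0; prose statements that "negligible senescence
corresponds to S = 1" refer to S_r. Both formulas are implemented exactly
as defined and the classification is keyed to G, on which both agree.

The Lorenz curve is returned as the (n + 1)-point polyline of cumulative
population share vs cumulative lifespan share; twice the trapezoid area
between it and the diagonal reproduces the pairwise Gini to numerical
precision, which the tests exploit as a cross-oracle.

## Synthetic cohorts

The simulator emulates a geometric-framework feeding trial: a factorial
grid of 7 P:C ratios (0:1, 1:16, 1:8, 1:4, 1:2, 1:1, 1.9:1) × 4 total
concentrations (45, 90, 180, 360 g/l), 36 flies per diet (1008 total). A
diet's expected total intake is `intake_scale` × concentration with
`intake_scale` = 0.5 μg/day per g/l, split between P and C by the ratio —
so carbohydrate intake spans 0–180 μg/day and protein 0–118 μg/day.
Per-fly intakes are lognormal around the diet means with CV 0.15
(truncation at zero is automatic for the lognormal); no per-fly intake
distribution is available from real trials of this design, so the CV is a
plausibility choice. Lifespans are drawn from the Gompertz hazard assigned
to the diet's *mean* intake by inverting the survivor function
S(t) = exp(−(a/b)(e^{bt} − 1)) (closed form; the b = 0 branch is the
exponential inverse CDF). Lifespans are continuous by default; an optional
`discretise` flag rounds deaths up to the recording grid (a presentation
detail — the discrete e(0) works either way).

Default hazard map (fully user-configurable):

    a(P, C) = 0.005 · exp(0.010 · P − 0.008 · C)   [per day]
    b(C)    = 0.08 + 4·10⁻⁶ · (C − 90)²            [per day]

Baseline mortality a falls log-linearly with carbohydrate and rises with
protein, so life expectancy (23–38 days median across the grid) peaks on
high-C/low-P diets; the senescence rate b is U-shaped in carbohydrate with
its minimum at 90 μg/day, which gives S_r a shallow minimum at
intermediate carbohydrate. These defaults produce per-diet S_r values of
roughly 2–6 — the positive-senescence range reported for flies — and give
parameter-recovery tests real signal. One RNG stream per run is keyed by
the seed, with per-diet substreams derived from the diet's grid index, so
output is byte-reproducible and independent of iteration order. No
censoring is modelled: such trials follow every fly to death. What the
simulator does *not* emulate: frailty heterogeneity within a diet,
time-varying intake, day-grid recording (by default), or egg-production
trade-offs — so green tests certify the statistical machinery, not those
aspects of real data.

## Response surfaces

Fits are ordinary least squares on per-diet means (the motivating design's
t-statistics imply diet-level aggregation; fly-level records can be fitted
by building a `SurfaceData` from them directly). Responses are
Z-transformed (sample mean 0, SD 1); predictors stay in raw μg/day by
default with an option to standardise them too. Reported residual df are
the true n − 3 (linear) and n − 6 (quadratic) — published tables for this
design sometimes print t₂₇ for both models, which cannot be the OLS
residual df at n = 28 and is not reproduced. p-values are two-sided from
the central t distribution; no multiple-testing correction. In the
quadratic model the linear coefficients are estimated but flagged "not for
interpretation" in the fit metadata. Stationary points solve ∇R = 0 with
Hessian [[2γ_PP, γ_PC], [γ_PC, 2γ_CC]]; a Hessian with an eigenvalue below
10⁻¹⁰ of the spectral radius is reported degenerate (no point). Degenerate
designs (rank-deficient design matrices, e.g. a single ratio) are rejected
at the precondition rather than silently fitted.

## Sequential landscape comparison

Both responses are Z-transformed and stacked over the shared diet grid
with a two-level trait indicator. Three nested contrasts are tested in the
fixed order linear → quadratic → correlational, each level's reduced model
carrying all terms from previous levels:

| level | reduced model | added terms | df (2 × 28 diets) |
|---|---|---|---|
| linear | 1, trait, P, C | trait:P, trait:C | F₂,₅₀ |
| quadratic | + trait:P, trait:C, P², C² | trait:P², trait:C² | F₂,₄₆ |
| correlational | + trait:P², trait:C², PC | trait:PC | F₁,₄₄ |

F = ((SS_R − SS_C)/df1)/(SS_C/df2). The P×C terms enter only at the
correlational level; this bookkeeping reproduces the standard published df
sequence (50, 46, 44) for two traits × 28 diets. Univariate follow-ups run
when a multi-term level is significant at α = 0.05, dropping one trait
interaction at a time from that level's complete model (F₁,df2). Levels
whose complete model is rank-deficient or df-exhausted are skipped with a
warning.

**Calibration caveat.** The partial F-test itself is exact under the
model: simulated at the 28-diet design (σ = 0.3) its size is ≈ 0.05 and
its null p-values are uniform. The *full procedure* — re-estimating each
trait's SD within the sample via the Z-transformation — is conservative
(simulated size ≈ 0.014), because the trait-specific scale estimate
correlates with the gradient estimates it divides. Calibration simulations
in the test suite therefore generate responses on a common scale and
disable within-sample standardisation to probe the F machinery, and
separately verify the standardised procedure is never anti-conservative.
For a single observed dataset the standardisation is the right
preprocessing (it removes unit differences); its conservatism only matters
for interpreting marginal p-values.

## Angle between linear optima

θ = arccos(a·b / ‖a‖‖b‖) between the two traits' (β_P, β_C) vectors, in
degrees, with the cosine clamped to [−1, 1] against floating-point
overshoot; zero-norm vectors are rejected naming the degenerate trait. The
95% interval resamples coefficient vectors from each fit's asymptotic
multivariate-normal sampling distribution (eigen-factorised, so
semi-definite covariances — including exactly zero — are valid), 10,000
draws by default, deterministic given the seed. This replaces an MCMC
posterior with the asymptotically equivalent sampling distribution of the
same target quantity; a nonparametric bootstrap over diets is available as
`method="bootstrap"`. The point estimate is the plug-in angle of the
fitted vectors, not the mean of resampled angles (resampled angles are
biased away from the boundaries 0° and 180°); for the same reason the
quantile interval is widened, when necessary, to include the point
estimate, so a point fit at θ = 0 is never excluded by its own interval.

## Thin-plate-spline landscapes

The penalised TPS in 2D uses the kernel φ(r) = r² log r plus an affine
null space, solved from the bordered system
[[K + λI, T], [Tᵀ, 0]][w; d] = [y; 0] with side condition Tᵀw = 0.
Coordinates are centred and scaled to unit variance internally so one λ
grid suits all datasets; λ = 0 interpolates distinct points, λ → ∞
collapses to the least-squares affine plane. GCV(λ) = n·RSS/(n − tr H)² is
minimised over 60 log-spaced points in [10⁻⁶, 10⁴] (a boundary minimum
warns of under-/over-smoothing); H is formed explicitly — fine at these
problem sizes (tens of diets). Prediction grids span the observed intake
range; cells outside the convex hull of the data are masked by default
because the ray-structured GF design leaves whole rectangle corners
unobserved, and a landscape should not display pure extrapolation.
Accuracy claims (e.g. RMSE below the noise SD for a GCV-selected fit) are
likewise assessed inside the hull. Landscapes are fitted and drawn on raw
response values for interpretability, while all inference runs on
standardised values. Plot export is a basic filled contour, red high /
blue low.

## Pipeline

`run_full_analysis` chains simulate/load → per-diet summary → gradient
tables for both responses (default: pace and S_r, with G and S always
carried in the summary) → sequential comparison + θ → two GCV landscapes,
writing headered CSVs and a JSON manifest (seed, version, estimator
flags, file list, warnings). Runs are byte-reproducible under a fixed
seed. With fewer than 7 diets the quadratic fits and the sequential
comparison are skipped with explicit warnings (insufficient residual df);
fewer than 4 diets aborts. Any stage failure removes partial outputs and
re-raises naming the stage.

## Problem sizes

Simulation-based checks use the design size they make claims about
(28 diets, 36 flies/diet); convergence anchors use 10⁵ draws; recovery,
size and power simulations use 500 replicates; the θ interval uses 10⁴
draws by default. These sizes make Monte-Carlo error small relative to
every tolerance asserted.

## Known limitations

- Gompertz-only simulation engine; no Weibull/logistic hazards, frailty
  mixtures or time-varying diets.
- The comparison handles exactly two landscapes; no canonical rotation of
  fitted surfaces, no cubic terms.
- The θ interval is asymptotic (or bootstrap), not a posterior; with very
  noisy gradients near the 0°/180° boundaries it is wide and asymmetric.
- Intakes enter the hazard map at diet means; individual intake variation
  affects recorded intakes but not, by default, individual hazards.
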