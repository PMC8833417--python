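# Methods

## Scope and estimand

The package estimates the spatial distribution of dung-pellet-group
density from line-transect distance sampling, and treats that density as
a relative-abundance index. Pellet density is the estimand throughout; no
conversion to animal numbers (which would require defecation and decay
rates) is attempted, and the simulator accordingly places pellet groups
directly rather than modelling deposition and decay over time.

## Stage 1 — detection

**Model.** Perpendicular distances on [0, w] (default w = 1.5 m, chosen
so that roughly the farthest 5% of distances are discarded) follow the
conditional density g(x; z)/μ(z), with μ(z) = ∫₀ʷ g dx. Keys: half-normal
g = exp(−x²/2σ²) and hazard-rate g = 1 − exp(−(x/σ)^−b), both with
g(0) = 1; b > 1 is enforced by the parameterisation b = 1 + exp(θ).
Covariates enter the scale as σ(z) = exp(β₀ + Σβₖzₖ) with dummy-coded
categorical levels (first level baseline). Key-only models may carry one
adjustment series — cosine (orders 2–3), Hermite (4, 6) or simple
polynomial (4, 6) on the scaled distance x/w — renormalised so g(0) = 1;
adjusted curves must be non-increasing on a 100-point grid or the fit is
flagged and excluded from selection. Covariate models carry no
adjustments.

**Numerics.** μ(z) has a closed form for the unadjusted half-normal
(σ√(π/2)·erf(w/σ√2)); otherwise adaptive quadrature with absolute
tolerance 1e-8. The likelihood is maximised by BFGS from three starts
(σ₀ = w/4, w/2, w); identical covariate rows are collapsed so μ is
evaluated once per distinct σ. The parameter covariance is the inverse
numeric Hessian of the negative log-likelihood (central differences).

**Observer grouping.** Only the minimum group size (70 detections) and
the effort ordering are fixed by the protocol; the grouping rule here is:
sort observers by descending total effort, accumulate greedily until the
group reaches 70 detections, start the next group, and merge a trailing
undersized group into its predecessor. This is deterministic and respects
the effort stratification; other groupings satisfying the same
constraints would differ only in how mid-effort observers are pooled.

**Goodness of fit.** W² = 1/(12n) + Σ(u₍ᵢ₎ − (2i−1)/(2n))² on the fitted
PIT values u. The p-value is a parametric bootstrap: distances are
re-simulated from the fitted model at each observation's covariates
(inverse-CDF on a 513-point grid), the same model specification is
refitted (warm-started at the fitted σ), and W² recomputed; p =
(1 + #{W²* ≥ W²})/(B + 1). The operation default is B = 499; the
end-to-end pipeline uses B = 99, which resolves p to ~0.01 — ample for a
screen-level test. A weighted variant of W² is sometimes quoted in the
field; absent a defined weighting scheme the standard statistic is used.

**Average detectability.** p̄ = n/Σ 1/p(zᵢ) (the harmonic mean implied by
the Horvitz–Thompson correction), with a delta-method CV over the fit
parameters via numeric gradient. Uncertainty in the covariate
distribution itself is not propagated.

## Stage 2 — density surface

**HT correction.** Each detection contributes 1/p(zᵢ) to its segment;
segments are the pieces of transect between recorded ground-cover
transitions (3–200 m), and the offset is the strip area A = 2·w·l.

**Additive model.** log E[n̂ⱼ] = log Aⱼ + β₀ + Σfₖ(zⱼₖ). The smooths are
penalized cubic B-splines (basis dimension 10 per term by default,
second-derivative penalty) fitted by penalized IRLS through statsmodels
GLMGam — the same low-rank penalized-smooth contract as thin-plate
regression splines, with knots placed automatically from the data.
Smoothing weights are chosen by GCV, n·D/(n − edf)², via a single
coordinate-descent sweep per smooth over a coarse log-grid
(10⁻³ … 10⁵): the GCV optimum in the penalty weight is broad, so locating
its order of magnitude is what matters.

**Families.** Tweedie with log link, power p profiled over
{1.1, …, 1.9}; the dispersion φ is profiled by maximum likelihood using
the Dunn–Smyth series density (the statsmodels implementation of that
series matches mgcv::ldTweedie to 1e-6; a frozen cross-check is in the
test suite). Negative binomial with θ by outer profile likelihood over a
fixed grid; because the NB is a discrete distribution, the non-integer
HT-corrected responses are rounded to the nearest integer with a warning.
AIC = −2ℓ + 2·(1 + Σedfₖ + d), d = 2 for Tweedie (p, φ) and 1 for NB (θ).
Comparing a continuous density (Tweedie) with a discrete PMF on rounded
data is an approximation inherent to this family contest; it behaves
correctly when the HT weights spread the responses away from integers,
which detection probabilities well below 1 guarantee.

**Selection.** Each smooth gets an approximate Wald test: β′V⁻β on its
coefficient block with degrees of freedom rounded from the block edf.
Backward selection removes the largest-p smooth above α = 0.05 (ties →
larger edf), refits reusing the parent model's smoothing weights and
dispersion, and stops when all terms are significant or the model is
intercept-only; a failed refit returns the previous model with a warning.

## Prediction and uncertainty

Cells (1 km² default) get covariates by the same 500-m-disk buffer rule
as training segments (a cell belongs to a buffer iff its centre is within
the radius — the plain zonal-statistics convention). N̂ = A·exp(η̂) with
SE(η̂) from x′Vx; the per-cell regression CV is approximated by SE(η̂)
(the lognormal-mean delta method, accurate for small SE), and the total
CV is √(cv_det² + cv_gam²). Covariate values at prediction points are
clipped to the training range before basis evaluation — how far a point
lies outside that range is the business of the extrapolation
diagnostics, not of the spline basis. Smoothing-parameter uncertainty is
not propagated. Note that the root-sum-of-squares combination can only
increase the larger component; a combined CV below one of its components
is arithmetically impossible under this rule.

## Extrapolation diagnostics

ExDet: UDⱼ = min(xⱼ−minⱼ, maxⱼ−xⱼ, 0)/rangeⱼ, NT1 = ΣUDⱼ; for NT1 = 0,
NT2 = D²(x)/max_ref D² with Mahalanobis distance to the reference mean
and covariance (ridge-regularized if singular, with a warning). Classes:
univariate (NT1 < 0), combinatorial (NT2 > 1), analogue otherwise. The
most influential covariate is the most negative UDⱼ (univariate) or the
largest leave-one-covariate-out reduction of D² (combinatorial). %N uses
the Gower distance (mean |Δ|/range over covariates, zero-range covariates
excluded with a warning) with the mean reference-pair distance as radius.
The reference set is the covariate table of the segments behind the
fitted model. Two phrasings of the discard rule exist — "discard
univariate cells with %N < 5" and "keep only analogue/combinatorial cells
with %N ≥ 5"; the stricter second form, which describes what is carried
into validation, is the default, the looser form is a config switch.

## Validation and gradient summary

Valid cells are assigned to districts by cell centre (nearest Voronoi
seed in the synthetic world — identical to centre-in-polygon for Voronoi
districts). Districts keep their mean predicted density if ≥ 50% of their
area is validly predicted (boundary inclusive). Spearman ρ uses average
ranks with the t-approximation p-value; constant inputs are an error. The
gradient table reports n, median and quartiles (linear-interpolation
quantiles) of predicted density per climate × landscape class; no formal
test is attached, since model predictions are smoothed and not
independent.

## Synthetic world

Continuous covariate fields are Gaussian-blurred white noise (blur σ =
half the stated correlation scale), restandardised to the target
mean/sd — enough spatial structure for recovery tests without a
geostatistical simulator. Compositional families (six land-cover classes;
three forest-ownership classes) are per-cell softmaxes of blurred fields,
so they close to 1 exactly; ownership fractions are down-weighted by the
forest fraction so they never exceed the forested share. The truth is
λ = exp(intercept + Σ effects) with named effect shapes (linear,
quadratic, Gaussian dome); the default intercept log(4e-3) /m² puts cell
densities in the few-thousands per km², the order pellet surveys report.
Defaults: three active effects (coniferous +, arable +, winter-mean-
temperature dome) among 14 candidate covariates.

Designed surveys allocate 75% of the 200-m west–east transects to the
woodland stratum (forest fraction ≥ 0.5) by a systematic sample of
stratum cells with a seeded random offset; undesigned transects start
uniformly within 30 m of their plot centre with random heading.
Observations are an inhomogeneous Poisson process on each 2·w_gen strip
(piecewise-constant intensity at 10-m steps), thinned by g(x) with
per-observer scale factors; the generating half-width w_gen = 2 m exceeds
the 1.5-m analysis truncation. Ground-cover sections follow the dominant
land-cover class under the line (transition where the dominant class
changes), with the five field ground-cover labels drawn per section from
land-cover-conditioned weights — this couples segmentation to the
landscape without pretending to model micro-scale vegetation. Undesigned
transect length is fixed at 200 m.

The default end-to-end problem sizes — 20 × 20 km landscape at 100-m
resolution, 120 designed + 25 undesigned transects (29 km effort, ~340
detections), 400 prediction cells, 40 districts — were chosen so the full
chain exercises every stage at survey-realistic detection counts while a
complete run stays around a minute; the analysis scripts print the sizes
they used.

**What the synthetic world does not emulate:** temporal pellet
accumulation/decay, animal movement, spatially correlated residual
structure beyond the covariates, observer behaviour beyond a scale
factor, real CORINE/climate raster semantics, or CRS/projection handling
(planar metres, axis-aligned). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated sampling
model, not robustness to field-data pathologies such as responsive
movement, mis-measured distances or decay-rate gradients.

## Known limitations

- The NB/Tweedie AIC contest mixes a PMF with a density (above); it is
  reported as the field does, but the QQ data are the sounder basis when
  the two disagree narrowly.
- Smooth p-values are approximate Wald tests; like all such tests after
  penalized estimation they are somewhat anti-conservative at small n.
- The CvM bootstrap refits only the selected specification, not the whole
  selection ladder, so selection uncertainty is not reflected in p.
- District polygons are synthetic Voronoi cells; real management-district
  geometry (holes, enclaves, partial cells) is untested.
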