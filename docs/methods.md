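# Methods

## Problem and model

`bordertrap` analyses border mass-trapping trials for the brown marmorated
stink bug (*Halyomorpha halys*) in apple orchards: pheromone-baited
"mini-sailboat" traps are deployed a few meters outside one orchard border,
and fruit damage is scored at assessment points laid out at increasing
distances from that border, in plots with traps and in control plots
without. The question is not whether total damage drops, but how the traps
reshape its spatial distribution.

Three layers make up the analysis:

1. **Damage metrics.** Each assessed fruit is binned by its feeding-injury
   count into six classes with damage coefficients
   V = (0, 1, 2.5, 5, 8.5, 15.5) (class 1 = no damage, class 6 = 11–20
   injuries; counts above 20 clamp into class 6). Per assessment point,

   - incidence (%) = 100 · (injured fruit) / (assessed fruit),
   - severity = Σᵢ≥₂ Nᵢ Vᵢ / Σᵢ≥₂ Nᵢ, the mean coefficient per *injured*
     fruit.

   Severity is undefined (missing, never 0) when no fruit is injured:
   including uninjured fruit in the denominator would conflate incidence
   and severity. Writing the numerator from class 1 would change nothing
   (V₁ = 0), so both sums run over injured classes only.

2. **Spatial quantities.** The orchard border is a polyline through the
   recorded border vertices; each point's border distance is the minimum
   Euclidean point-to-segment distance (shapely). Point-to-trap distances
   form a matrix (scipy `cdist`); its row minima give nearest-trap
   distances. The catch index aggregates trap pressure at a point from the
   season totals H_x and distances d_xi. Two formulations of the index
   circulate in the field, so both are implemented and selectable:
   `displayed` = Σ H_x/d²_xi (default) and
   `text` = √(Σ (H_x/d_xi)²). Both are 1-homogeneous in H and decreasing in
   every distance. Geometry is planar in meters; lon/lat inputs are
   flattened by a local equirectangular projection (orchards are ≪ 2 km, so
   the projection error is negligible).

3. **Count models and curves.** Injured-fruit counts are modelled by
   log-link negative binomial (NB2) regression with log(assessed fruit) as
   offset, so coefficients act on the per-fruit rate; severity (rounded to
   the nearest integer for fitting, unrounded in outputs) by NB without
   offset; per-trap catches (trap × date × sex × part rows) by NB with sex,
   part, sex:part and a fixed date factor. Random effects (trap identity,
   repeated dates) are intentionally out of scope; the fixed date factor
   absorbs the seasonal trend. The full damage model starts from catch
   index, nearest-trap distance, variety, management, trap presence and
   the trap-presence × border-distance and × management interactions, and
   is reduced by backward elimination on AIC (main effects are never
   dropped while their interaction remains; AIC ties break toward the term
   with the smaller maximum |Wald z|). Analysis of deviance is by
   likelihood-ratio tests (type III = drop from the full model, type II =
   drop ignoring the term's own higher-order relatives), with treatment
   coding. Model adequacy is summarized by the Pearson χ² statistic with
   the family variance and its dispersion ratio χ²/df.

   The selected model is evaluated on a 0.5 m border-distance grid per
   stratum (trap / control), other covariates pinned at stratum-typical
   values — except the nearest-trap distance, which tracks the border
   distance plus the trap offset in the trap stratum, since the traps sit
   just outside the border. Standard errors are delta-method on the
   response scale. From each curve:

   - **d50**: the curve is integrated (trapezoid, response scale, as the
     curve is plotted) and normalized; d50 is the distance where the
     cumulated fraction crosses 0.5, linearly interpolated. It is the
     median of the damage mass over the observed range.
   - **Differential effect**: control minus trap prediction, pointwise,
     with variances added. Its zero crossing (the "point of equal
     incidence") is bracketed by the first sign change between nonzero
     values and refined by bisection to 0.01 m; with no sign change the
     crossover is reported undefined, never guessed. The crossover is
     defined as equal predicted damage in the two strata (a zero of the
     difference curve), not as either stratum's prediction reaching zero —
     log-link predictions never reach zero exactly.

## Statistical engine

GLM likelihoods are maximized by statsmodels' discrete-model MLE (Newton,
then BFGS/L-BFGS/Nelder–Mead fallbacks, NB seeded from the Poisson
solution). NB θ is reported as 1/α. When data are equi- or underdispersed
the NB likelihood is maximized on the α → 0 boundary where the Hessian is
singular; the fit then degenerates cleanly to the Poisson limit (θ capped
at 10⁶, α still counted as a parameter in the AIC). This also realizes the
invariant that an NB fit at θ → ∞ reproduces Poisson coefficients.

## Synthetic trial generator

No field data ship with the package, so a seeded generator produces trials
with the structure the analysis assumes. Defaults emulate a realistic
four-plot border trial and are fixed once:

- Layout: 800 m straight border (28 recorded vertices), 100 m depth, four
  200 m plots alternating trap/control; 8 traps in two groups of four,
  ~45 m apart, 7 m outside the border; 80 assessment points on a jittered
  4 m row grid; management (organic/IPM) and variety assigned per parcel
  strip (two per plot).
- Damage: ~92 fruit per point (Poisson); injured count binomial with
  probability clamp(exp(a + b·d), 0, 1). Trap plots: a = log 0.43,
  b = −0.03 m⁻¹ (≈13.7% mean incidence, steep decay, theoretical d50
  ≈ 21 m). Control plots: a = log 0.073, b = +0.005 m⁻¹ (≈9.4% mean,
  damage drifting weakly inward, d50 > 50 m). These reproduce the
  qualitative contrast the analysis is designed to detect — strong border
  concentration only under traps — at the strata's observed mean levels.
  The implied equal-incidence point of the two generating curves is
  ≈ 51 m. Each injured fruit draws a zero-truncated Poisson injury count
  with mean 2.5 (λ solved numerically so the truncated mean matches),
  binned into classes 2–6; counts above 20 clamp to class 6. Class counts
  always sum to the fruit total.
- Catches: per trap × date × sex NB draws (size 5) around per-date means
  (20, 35, 60, 90, 145, 170 — rising through the season, ≈520 per trap in
  total), sexes split by the 0.85:1 male:female ratio, then sail/bin
  assignment with sail probability 0.689 (males) and 0.471 (females).

What the generator does **not** emulate: insect movement or plume physics,
spatial autocorrelation beyond the distance trend, extra-binomial
heterogeneity in per-point incidence (conditional on distance the injured
counts are exactly binomial, hence the frequent Poisson-limit NB fits),
between-date trap correlation, multi-season dynamics. Passing tests show
the pipeline recovers structure it is pointed at; they do not certify
behavior under real-field heterogeneity.

## Numerical choices

- Curve grid step 0.5 m; crossover bisection tolerance 0.01 m.
- Trapezoidal integration on the response scale (percent), matching how
  the fitted curves are plotted and integrated.
- Optimizer convergence as provided by statsmodels; candidate fits are
  rejected if unconverged, non-finite, or lacking a usable covariance.
- Degenerate inputs are signalled, not patched: zero assessed fruit,
  zero injured fruit, all-zero curves, zero within-group ANOVA variance
  and zero trap distances all raise typed errors.
- One seeded `numpy` Generator drives a whole trial; a scenario plus a
  seed is bit-reproducible.

## Problem sizes in tests

Simulation-based tests use sizes chosen to keep the whole suite
desk-scale while leaving the Monte-Carlo margins comfortable: coefficient
recovery uses 200 replicates at n = 500; LRT calibration 1000 null
replicates at n = 80; the end-to-end d50-ordering check 100 seeded
replicates of the default 80-point trial; geometry oracles 50 random
28-vertex polylines against 10⁴-per-segment dense sampling.

## Known limitations

- No random effects: repeated measures on the same trap are treated as
  independent given the date factor, which understates catch-model
  standard errors relative to a GLMM.
- Severity is fit as a rounded count; a gamma or quasi-likelihood model
  would avoid rounding but is deliberately out of scope.
- d50 and crossover carry no confidence intervals beyond the pointwise
  band; the curves' pointwise delta-method band is not simultaneous.
- Type III deviance uses treatment coding; with sum-to-zero contrasts the
  main-effect tests in the presence of interactions would differ.
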