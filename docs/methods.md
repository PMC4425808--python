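# Methods

## The paradigm being simulated

A single-object-tracking display: `n ∈ {20, 40, 80}` identical 32×32 px
trinary-noise squares move inside a square window of side
`{190, 268, 380}` px on a 100 Hz display where one pixel subtends
2 minarc (viewing distance 59 cm). One object (the target) carries a
black-and-white border for the first 1000 ms, then all objects move
unbordered for 4000 ms; at the end every object is outlined in black and
the observer clicks the one they believe was highlighted. A click inside
the target's 32×32 footprint is a *hit*. Crossing items with window area
gives nine conditions spanning five distinct densities, with an
equal-density diagonal (20/190², 40/268², 80/380² agree within 1%).
Unpredictability σ — the SD of the per-frame heading change — takes
seven evenly log-spaced values `π/2⁶ … π/2³` rad (ratio √2).

## Motion model

Each object starts at a uniform position in the admissible region (the
window inset by half the object side, so the whole object stays inside)
with a uniform heading, and moves at constant retinal speed 6.67°/s,
i.e. 6.67·60/2/100 = **2.001 px per frame** — positions are kept
continuous precisely so this non-integer step is not aliased. Each
frame, the heading is redrawn from a *wrapped normal* centred on the
previous heading: draw ε ~ N(0, σ²), add, wrap to [0, 2π). We chose the
wrapped normal over the von Mises because the design parameterises
dispersion directly by an SD in radians, which is the wrapped normal's
native parameter; at σ ≤ π/8 the two families are practically
indistinguishable (mean resultant length `exp(−σ²/2)` vs
`I₁(κ)/I₀(κ)`).

Boundary rule: a step that would leave the admissible region reflects
the heading specularly off the violated wall (vertical wall
θ → π−θ, horizontal θ → −θ, corner θ → θ+π) and clamps the position
inside. Reflection preserves speed on all non-clamped steps and keeps
the long-run positional distribution close to uniform (checked by a χ²
test on pooled final-frame positions). A `boundary="resample"` option
instead redraws the heading increment until the step is legal.

## Rendering

Objects and background are i.i.d. three-level noise
(32.75/65.5/98.25 cd/m², each w.p. 1/3; mean 65.5), so a static,
unbordered object is statistically invisible — the tests assert that
level histograms inside and outside object footprints agree to sampling
error. Textures are frozen per trial (one draw for the background and
one 32×32 patch per object); a per-frame background refresh exists
behind `dynamic_background=True` but is off by default, the minimal
reading of "objects and background share one texture process".
Distractors are drawn in a seed-stable shuffled order and the target
last, so the target is never occluded; borders are rings drawn *outside*
the footprint (2 px white + 2 px black for the highlight, 1 px black at
trial end), so the target's own texture stays fully visible on every
frame. Sub-pixel centres are rendered at the nearest integer with no
anti-aliasing, keeping every rendered pixel exactly on the three-level
set; the 8-bit export maps the three luminances linearly to 64/128/192.

## Synthetic observers

**Psychometric generator.** The hit probability for subject *s* is

    logit p = β₀ + u_s + γ₁D + γ₂D² + (β_u + δ₁D + δ₂D²)·σ,
    u_s ~ N(0, τ²),

with D the density centred at 7.55 and scaled by 7 items/10⁴px²
(roughly the design mean and spread; centring before squaring keeps the
quadratic well conditioned). Defaults: β₀ = 3, β_u = −9, γ₁ = γ₂ = 0,
δ₁ = −5, δ₂ = 2.5, τ = 0.8. These were chosen once to produce the
qualitative regime of interest: hit rates near ceiling (~0.93) at the
lowest σ in every condition; a σ-slope of about −2.7 at the lowest
density, steepening to −10.9 at the second-highest density and easing to
−8.5 at the highest (an interior-extremum parabola of slope against
density); a density-flat profile at σ = 0; and a between-subject
intercept SD typical of binary psychophysics (τ = 0.8, i.e. roughly
±13 percentage points around a 90% ceiling). Misses synthesise a click
uniformly over a random distractor footprint (observers click *some*
bordered object), rejected until it lies outside the target square, so
the stored hit flag, click and distance are mutually consistent. Hit
classification uses an inclusive boundary (|Δ| ≤ 16 px per axis).

**Mechanistic tracker.** An optional process model: each frame the
observer's estimate of the tracked object's position is corrupted by
isotropic Gaussian noise (SD `attention_noise` px) and re-associated to
the nearest object centre. Zero noise tracks perfectly; growing noise
loses the target more often, the more so at high density, and the
click-distance distribution becomes bimodal — the empirical rationale
for binarising distance into hit/miss.

Passing tests on these generators show that the *analysis machinery* is
correct and calibrated under the stated statistical structure; they do
not show anything about human observers, whose lapses, learning and
motor noise are deliberately not modelled.

## The mixed model

`glmm_core` implements the binomial logit GLMM with one Gaussian random
intercept per subject from first principles. The marginal likelihood is
a product over subjects of one-dimensional integrals; each is evaluated
by adaptive Gauss–Hermite quadrature centred at the conditional mode
u*ᵢ with scale 1/√Hᵢ from the inner curvature. Order 1 *is* the Laplace
approximation and the default (the common software default for binary
mixed models); order 25 agrees with dense brute-force integration to
1e-6 relative error in tests. The inner mode is found by damped Newton
on a log-concave objective, solved to |grad| < 1e-11 so that the outer
objective is smooth to finite differences.

Fitting maximises over (β, log τ) with L-BFGS-B (objective tolerance
1e-11), log τ bounded in [−10, 3]; a τ̂ at the lower bound (≈ 4.5e-5) is
the boundary estimate of a zero variance component, and the likelihood
code switches to the exact logistic likelihood there. Restart policy:
on non-convergence, restart L-BFGS-B once from the incumbent, then (for
small models) try Nelder-Mead from the logistic start; a fit that still
fails is returned flagged `converged=False` with a warning and BIC
refuses to evaluate it. Starting values come from a short IRLS logistic
fit. `fix_tau` pins τ (e.g. to 0) for reduction checks. Separation is
flagged when the fitted linear predictor exceeds ±30 or the response is
constant; the bootstrap refuses separated fits.

Model formulas use a small dialect (`log(x)`, `factor(x)`,
`poly(x, 2)`, `*`, `:`, `(1|subject)`); `poly` uses orthonormal coding
by default (QR of the centred Vandermonde) — likelihoods, BICs and LRTs
are coding-invariant, and raw coding is available when coefficient
values need to be read directly. BIC uses n = number of Bernoulli
observations and counts the variance component in k. LRTs use ML fits;
nesting is verified numerically (reduced design columns must lie in the
span of the full design). Boundary-τ p-values are not halved — only
fixed effects are tested here.

The parametric bootstrap redraws subject intercepts from N(0, τ̂²) and
Bernoulli responses from the fitted probabilities, refits (warm-started
at the estimate), and reports percentile intervals; non-converged
replicates are dropped and counted.

## Analysis pipeline

The six-model ladder (M1 factors + quadratic σ; M2 linear
log-items × area × σ; M3 = M2 without the three-way; M4 quadratic
density × σ; M5 linear density × σ; M6 = M4 without the interaction) is
fitted on one shared row set and compared by BIC. The three targeted
LRTs have design-determined df: 8 (2 σ-contrasts × 2 item contrasts ×
2 area contrasts), 1 (linear three-way) and 2 (the two density × σ
terms). "Area" as a linear covariate means side length in pixels by
default (`area_covariate="squared"` switches to side²); log(items) uses
the natural log.

Figure-style descriptives are deliberately *fixed-effect* logistic fits
(the GLMM stays the inferential engine): per-condition slopes of hit on
σ pooled over subjects, plus per-subject slopes for one-sample t-tests
(df = subjects − 1 = 23 at the default design). Cells or subjects at
ceiling separate; these are flagged and their slope replaced by a
lightly ridge-penalised fit (α = 0.05 on the slope) so every subject
still contributes a finite slope. The slope-vs-density quadratic is OLS
on the nine cell slopes (inverse-variance weighting optional). The
lowest-σ test filters to the minimum σ (1/7 of a balanced design) and
LRTs quadratic-density against intercept-only (df = 2). Within-subject
CIs use the Cousineau normalisation (subtract subject mean, add grand
mean — which preserves the grand mean exactly) with the Morey inflation
√(C/(C−1)) over the C = 63 cells and t-based intervals.

## Problem sizes and numerical choices in the tests

The test-suite simulations are scaled to what the properties need: the
bootstrap-coverage study uses 100 outer runs × 200 bootstrap replicates
on a 12-subject, 4-σ-level design with a two-coefficient model; the
null-LRT calibration uses 300 replicates of a 12-subject single-replicate
design; model-selection recovery uses the full 24-subject design with
two replicates. Monte-Carlo assertions use 3–3.5 SE bands; the coverage
assertion accepts 0.87–1.00 for a nominal 0.95 at 100 runs.

## Known limitations

- One random intercept only: no random slopes, crossed effects or
  non-logit links.
- The original laboratory experiment with human observers cannot be
  reproduced here; all quantitative statements concern the synthetic
  generators.
- The mechanistic observer is a minimal nearest-neighbour tracker, not a
  model of human attention (no capacity limit, no eye movements).
- Finite-difference outer derivatives make very large fixed-effect
  models (≫30 columns) slow; the ladder's largest model (27 columns)
  fits in a few seconds at 3000 rows.
- Trajectory export is CSV/JSON only.
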