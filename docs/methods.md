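# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Detection model

Point-transect distance sampling treats the distances of detected
groups as draws from `f(r) = g(r) · (2r/w²) / p`, where `g` is the
detection key, `2r/w²` the density of detection opportunities on a
circle of radius `w = 100` m, and `p = ∫₀ʷ g(r) 2r/w² dr` the average
detectability over the circle. The key is a gamma kernel normalised at
its apex,

    g(r) = h(r)/h(r*),  h(r) = r^(κ−1) e^(−r/σ),  r* = (κ−1)σ,

which allows detectability to peak away from the observer (κ > 1 forces
g(0) = 0; birds immediately underfoot flush before being recorded).
The shape κ is shared across observations; the scale takes a log link
in observation covariates (flock size, emergent vegetation,
trees-and-bushes cover), so one extra parameter per covariate.

Choices:

- **Conditional likelihood.** Only the distance distribution is
  modelled (one row per detected group); counts carry no information
  about the key under this formulation. The normalising apex constant
  cancels in `f(r)`, which makes the conditional density a truncated
  gamma in disguise — and explains an identifiability caveat below.
- **Closed-form circle integral.** `p` reduces to regularised
  incomplete-gamma expressions; no quadrature error enters the
  likelihood, and fits cost milliseconds.
- **Optimisation.** BFGS on `(log(κ−1), β)` — the log transform
  enforces κ > 1 — with 5 random restarts by default. Standard errors
  come from the inverse numerical Hessian.
- **Truncation.** Distances beyond `w` are discarded with a logged
  count. Detections at exactly r = 0 are clipped to 1 mm (zero density
  under the key).

**Identifiability caveat.** Under 100 m truncation with unknown shape,
κ̂ and σ̂ are strongly anti-correlated (r ≈ −0.97): the apex r* is well
determined but its factorisation into shape and scale is not. At
n = 5000 distances the sampling SD of σ̂ is ≈ 7% even though the
estimator is essentially unbiased. Recovery tests therefore assert
tolerances on medians over replicates, not on single realisations.

A second structural fact worth knowing: the average detectability `p`
increases with σ only while the apex `(κ−1)σ` lies inside the circle;
once the apex passes `w` the normalisation point leaves the surveyed
area and `p` falls again. Tests cover both regimes.

## Occurrence model

Presence/absence at each point count is modelled as a binomial logit
GLMM with a site random intercept and the logit of the predicted
detectability (flock size fixed at 1, so only habitat drives it) as an
offset. This is an odds-scale correction for detectability, not a
formal occupancy–detection decomposition; it follows the two-step
design the package implements. Detectability predictions are clipped to
[1e−6, 1 − 1e−6] before the logit.

- **Hypothesis set.** Exactly ten fixed-effect structures: a null model
  (date + offset only); habitat (four continuous covers as
  second-order terms plus a river indicator); habitat plus each of four
  moderators (residence time, CWD, MTCM, climate-suitability score)
  additively; and habitat crossed with each moderator, where
  interactions pair both habitat polynomial orders (and the river
  indicator) with both moderator orders. Every model keeps the date
  term and the offset.
- **Design matrices.** Continuous predictors are standardised and
  expanded to orthogonal polynomials (QR of the raw power basis, map
  stored for prediction). Predictions are invariant to this choice; it
  exists for conditioning and so linear and quadratic columns are
  uncorrelated. Full column rank is checked, with offending columns
  named.
- **Estimation.** Maximum likelihood (not REML — AIC comparison across
  fixed-effect structures requires ML). The site intercept is
  integrated out with 25-node adaptive Gauss–Hermite quadrature: per
  site, Newton iterations find the posterior mode and curvature, and
  the Hermite rule is shifted/scaled there. The outer optimiser is
  L-BFGS-B on `(β, log σ_site)` with an analytic score obtained via
  Fisher's identity (posterior-expected complete-data score under the
  same quadrature rule), relative tolerance 1e−8, a 500-iteration cap,
  memory `maxcor = 40` (the 32-parameter interaction models converge
  slowly with the default memory), and up to 3 jittered restarts.
  `σ_site` is bounded in `[e⁻⁶, e³]`; pinning both bounds at the floor
  gives the exact plain-logistic-regression limit used as an oracle in
  tests.
- **Parameter counting.** `n_params` = fixed effects + 1 variance
  component, so the ten models count 3, 12, 14 (×4) and 32 (×4)
  parameters; `AIC = 2k − 2ℓ`.
- **Marginal R².** `var(Xβ) / (var(Xβ) + σ²_site + π²/3)` — the
  logit-link latent-scale variant. The date term is part of the fixed
  variance; the offset is excluded.
- **Inference extras.** Likelihood-ratio tests for nested pairs
  (nesting checked by term names); prediction curves along one focal
  variable with all else at observed means, Wald intervals on the link
  scale from the numerical-Hessian covariance, optionally at several
  moderator values to visualise interactions; and a binned Moran's-I
  style correlogram of Pearson residuals with a seeded
  999-permutation envelope as a residual spatial-autocorrelation
  check.

## Resource selection

Availability at a focal-watch location is the cover of each habitat in
each 30 m sub-square weighted by a detection curve evaluated at the
sub-square centre's distance to the central transect, pooled over
locations and normalised. The weight function is injectable: any
uniform rescaling cancels, and a flat curve reproduces raw cover
proportions. The package does not claim any particular field protocol's
exact weighting beyond this centre-distance construction.

Jacobs' index is computed on *proportions* (observed proportional use
vs expected proportional use): the formula is scale-consistent only on
proportions, although field write-ups often phrase O and E as counts.
Significance uses simultaneous Bonferroni normal-approximation
intervals on observed use proportions at joint level 1 − α (per-habitat
level `1 − α/2k`); a habitat is flagged when its expected proportion
falls outside. Records whose microhabitat could not be attributed
(ground-feeding, bare ground) never enter the counts but are tallied so
the bookkeeping `Σ N + excluded = total` stays auditable.

## Climate

Cumulative water deficit runs the monthly recursion
`D_t = min(0, P_t − E_t + D_{t−1})` cyclically (December feeds January)
until the 12-month vector is stable, then reports `min_t D_t ≤ 0`.
Surplus months clamp the running deficit at zero — surplus does not
bank; without this clamp the quantity would be unbounded below for any
net-deficit climate. A year in permanent deficit (no surplus month)
never stabilises; after 10 cycles the capped value is returned with a
warning. MTCM and the climate-suitability score are supplied covariates
(no raster handling); climate joins point counts per site by default,
though per-point values on the input table are respected.

## Synthetic surveys

The generator emulates the emulated study's design: 41 sites in four
residence-time strata (8/10/10/13; residence time continuous within
stratum bounds, strata used only for allocation and reporting), five to
twelve point counts per site nudged to a 349 total, ≥ 200 m spacing by
rejection sampling inside a 10 km site square, habitat recorded on a
7×7 grid of 30 m-spaced nodes (so covers are multiples of 1/49,
discretised from per-point Dirichlet draws), a binary river indicator,
three seasonal survey rounds balanced within strata, 68 scan-sample
locations with 6×6 grids of 30 m sub-squares, and per-site monthly
climate whose summer deficit is driven by a latent correlated with
residence time (ρ = 0.33 for CWD, 0.55 for MTCM, 0.72 for the
suitability score — the design's confounding structure).

Presence is simulated from the same model family the analysis fits
(logit link, site intercept SD 1, true-detectability offset); distances
of detected groups are proposed from `2r/w²` and thinned through the
true gamma key (shape 3, scale intercept log 30, flock +0.05/bird,
trees −0.8), which is exactly the sampling model the detection step
assumes. Flock sizes are zero-truncated Poisson(3) — the distribution
is not specified by any field protocol, so a minimal count model was
chosen. Occupancy coefficients were fixed once so that (i) mean
prevalence sits near the design's 37% of point counts, and (ii) the
additive and interaction models' marginal R² land at the magnitudes the
emulated study design targets (≈ 0.31 additive, ≈ 0.5–0.6 with
interactions): humped responses to emergent vegetation, forbs and rough
grass, avoidance of trees, a positive river effect, a residence-time
effect saturating after ~20 years, and interactions that flatten the
emergent-vegetation hump, fade the river effect and trade forbs for
rough grass as residence time grows.

What the generator does **not** emulate — and hence what passing tests
cannot show about field data: spatial autocorrelation of habitat within
sites (covers are i.i.d. across points), observer effects and
mis-identification, overdispersion beyond the site intercept,
non-random placement of accessible point counts, real geography (site
centres are uniform in an abstract 200 km domain), and any multi-year
population dynamics behind the space-for-time substitution.

Fixed fixtures (`table1_fixture`, `table2_fixture`) carry the printed
survey margins of the emulated design (130/349 presences by stratum ×
land-cover class; 86 + 10 feeding and 96 + 2 shelter observations with
their Jacobs indices) for report plumbing and accounting tests.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make their statistical
assertions sharp at interactive cost: 5,000 distances (×5–11
replicates) for detection recovery, 1e4 points for law-of-large-numbers
and distance-distribution checks, 100 replicates for CI coverage, 200
for LRT type-I calibration, and 50 full surveys at the design scale
(349 points, 41 sites, all ten occurrence models refitted per
replicate) for AIC selection power. The brute-force likelihood oracle
uses 1e5 trapezoid panels on a 3-site toy dataset.

## Known limitations

- The detectability offset corrects odds, not probabilities; points
  with very low detectability lean on the clipped logit.
- ML variance estimates at the boundary (σ̂_site = 0 about half the
  time when the truth is 0) make σ̂-based assertions realisation-
  dependent; the package exposes `sigma_bounds` to study limits
  cleanly.
- Moderator availability is assumed complete; models with a missing
  moderator column fail fast rather than being silently dropped.
- The selection table assumes use observations and availability grids
  share habitat vocabularies; unknown habitats are an error, not a
  fuzzy match.
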