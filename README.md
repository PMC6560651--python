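# rangehab

Detectability-corrected habitat-association analysis for a
range-expanding bird, built around point-count surveys stratified by
*residence time* — the number of years since each site was colonised.
The scientific question the toolchain addresses: do a coloniser's
habitat associations change as populations mature, do they change with
climate, or are they stationary — and which of these best explains
spatial variation in occurrence?

The package is written for field ecologists analysing point-count and
focal-watch data: it implements the full two-step workflow (detection
modelling, then detection-corrected occurrence modelling), the
resource-selection summary used to pick habitat covariates, the
drought-stress climate covariate, and a synthetic survey generator with
known ground truth so that every step can be validated by
parameter-recovery and power simulations.

## The model

**Step 1 — detection.** Distances `r` of detected bird groups within a
`w = 100` m point-count radius follow a point-transect distance-sampling
model with a gamma key

```
g(r) = h(r) / h(r*),   h(r) = r^(κ−1) exp(−r/σ),   r* = (κ−1)σ,
```

with shared shape `κ > 1` and log-linear scale
`log σ = β₀ + β·x` in observation covariates (flock size, emergent
vegetation, trees-and-bushes cover). The conditional likelihood of the
distances uses the circle-geometry opportunity density `2r/w²`; all
2³ covariate subsets are ranked by AIC. The winning fit predicts each
point's average detectability `p̂` with flock size fixed at 1.

**Step 2 — occurrence.** Presence/absence `y_ij` of point `j` in site
`i` follows a binomial logit GLMM

```
logit P(y_ij = 1) = logit(p̂_ij) + x_ij'β + u_i,   u_i ~ N(0, σ²_site)
```

where `logit(p̂)` enters as an offset, `x` holds a survey-date term,
second-order orthogonal polynomials of four habitat covers plus a river
indicator, and optionally a moderator (residence time, cumulative water
deficit CWD, coldest-month temperature MTCM, or a precomputed
climate-suitability score) additively or interacting with every habitat
term. The fixed ten-model hypothesis set is fitted by maximum
likelihood with 25-node adaptive Gauss–Hermite quadrature and compared
by AIC; explanatory power is summarised by the latent-scale marginal
R² = var(Xβ) / (var(Xβ) + σ²_site + π²/3).

**Supporting statistics.** Habitat selection from scan samples uses
Jacobs' index `J = (O − E)/(O + E − 2OE)` with availability
detectability-weighted by the fitted key, and simultaneous Bonferroni
confidence intervals on use proportions. Drought stress is the
cumulative water deficit `D_t = min(0, P_t − E_t + D_{t−1})` run
cyclically over the 12 monthly water balances, `CWD = min_t D_t ≤ 0`.

## Worked example

Run the full pipeline on a synthetic survey with the default study
design (41 sites in four residence-time strata 8/10/10/13, 349 point
counts, three seasonal rounds, 68 scan-sample locations):

```
rangehab all --seed 11 --output-dir out
```

`out/model_comparison.csv` then contains (abridged):

```
model                     loglik    n_params  delta_aic  marginal_r2
habitat x residence_time  -168.112  32         0.000     0.567
habitat + residence_time  -198.957  14        25.690     0.314
habitat x climate_sdm     -183.508  32        30.791     0.470
habitat + climate_sdm     -202.584  14        32.944     0.287
habitat                   -206.208  12        36.192     0.257
...
null (date only)          -232.240   3        70.256     0.018
```

Read this as: the generating truth for the synthetic survey makes
habitat effects vary with residence time, and the AIC comparison
recovers exactly that — the habitat-by-residence-time interaction model
wins decisively (ΔAIC ≈ 26 over the additive model) and roughly doubles
the fixed-effect explanatory power (marginal R² 0.57 vs 0.31), while
the covariate-free null model is overwhelmingly rejected. The other
outputs are the detection-model ranking (`detection_ranking.csv`),
per-point detectability (`detectability.csv`), the Jacobs-index
selection table with Bonferroni flags (`selection_table.csv`), CWD
covariates and design correlations, per-model coefficients, prediction
curves for the winning model, and a `manifest.yaml` whose SHA-256
checksums are bit-identical across reruns with the same seed.

The library surface mirrors the pipeline:
`generate_survey`, `fit_detection_mle` / `rank_detection_models` /
`predict_point_detectability`, `selection_table`, `compute_cwd`,
`build_hypothesis_set` / `fit_glmm` / `compare_models` /
`predict_curves`, each usable on its own DataFrames.

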