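# Methods

## Model and estimators

For region *i* = 1…R and age group *j* = 1…J the observed data are event
counts `y[i,j]` with person-years `n[i,j]` (population × observation
years). The likelihood is `y_ij ~ Poisson(n_ij·θ_ij)` with a conjugate
gamma prior on the rate, in the rate parameterization
(`mean = shape/rate`):

    θ_ij ~ Gamma(α_ij = t_ij·m_j,  β_ij = m_j)

so the prior mean equals the smoothing target `t_ij` exactly and the prior
acts as `m_j` person-years of pseudo-exposure observed at the target rate.
The posterior is `Gamma(y_ij + α_ij, n_ij + β_ij)`; its mean is a convex
combination of the crude rate `y/n` and `t`, with data weight
`n/(n+m)` — the property the whole tool rests on, and the identity the test
suite checks to 1e-12.

**Smoothing targets.** Nonspatial: the pooled domain rate per age group,
`r_j = Σ_i y_ij / Σ_i n_ij`. Spatial: the pooled crude rate of the focal
region's contiguity neighbors, focal region excluded. Fallbacks, applied in
order, keep the target strictly positive (a gamma prior cannot have mean
zero): a region with no neighbors, or whose neighbors have zero pooled
events in an age group, takes the global rate `r_j`; an age group with zero
events in the entire domain takes the half-event continuity correction
`0.5 / Σ_i n_ij`.

**Prior strength `m_j`** is predetermined, not estimated from marginal
likelihood or moments. Default: the median over regions of `n[i,j]`, i.e.
the prior counts as much as one typical region's exposure, scaled per age
group so that smoothing strength tracks each group's denominators. It is a
deliberate, documented convention — exposed as `prior_weight` everywhere —
and the calibration consequences are discussed under Limitations.

**Age standardization.** `R_i = Σ_j w_j θ_ij` with weights `w_j ≥ 0`,
`Σ w_j = 1` from a standard population. Uncertainty is propagated by Monte
Carlo: θ draws are taken independently per age group (the posteriors
factorize by construction), the weighted sums form the standardized
posterior, and the summary is the draw mean (matching the closed form
`Σ_j w_j a_j/b_j` up to MC error, which the tests verify at 3 MC standard
errors) and the empirical 2.5/97.5 percentiles. Defaults: 10,000 draws,
seed 42; both settable. The point estimate is the mean, not the median,
to agree with the conjugate posterior-mean convention and the closed-form
check.

**Screens.** Reliability: unreliable iff CI width > point estimate (strict
inequality; an estimate of exactly zero with any positive width is
unreliable). Alerts combine the two methods' flags into
`none / unreliable_nonspatial / unreliable_spatial / unreliable_both`.
Significance: a region is `higher` (`lower`) than the reference iff its
interval lies strictly above (below) it; intervals touching the reference
are `not_different`. The reference is the domain's crude age-standardized
rate `Σ_j w_j r_j` — a fixed value, treated without sampling error; a
population-weighted mean of region estimates would be a defensible
alternative, but the pooled crude rate is reproducible from the inputs
alone and independent of the smoothing method. Both screens are
scale-invariant, so the display scale (default per 100,000 person-years)
never changes a classification.

## Adjacency

Queen contiguity (any shared boundary point) is the default; rook (shared
edge of positive length) is a flag. Queen is the safer default for census
geographies where four-corner point contacts occur. Two boundaries are
considered touching when their distance is ≤ 1e-9 in layer coordinate
units, absorbing coordinate rounding in exported layers; the rook test
requires the polygon intersection to have length > 1e-9. Geometry input is
GeoJSON (region id from a property field, default `GEOID`); the derived
dictionary is persisted as flat JSON (`{region_id: [sorted neighbors],
"_rule": ...}`) and re-validated on load — symmetry violations and
self-loops are rejected by name. Regions present in the count data but
missing from the dictionary are an error at smoothing time, never silently
treated as islands.

## Synthetic simulation study

The study scores three estimators of the age-standardized rate —
unsmoothed (crude), nonspatially smoothed, spatially smoothed — against a
known truth, by per-region rMSE over replicates and by pooled coverage of
the 95% intervals over region × replicate pairs (per-region coverage is
also retained for diagnostics).

Default scenario (all values are package conventions, chosen once):

- **Grid**: 10×10 unit squares, queen adjacency; 100 Poisson replicates.
- **Age structure**: six brackets 35–44 … 85+, base rates
  (1e-4, 4e-4, 1.2e-3, 3.5e-3, 9e-3, 2e-2) events per person-year —
  chronic-disease-mortality-like magnitudes rising two orders of magnitude
  with age.
- **Spatial structure**: a multiplicative region effect
  `exp(g·(u−½) + ε)` shared across age groups, with `u ∈ [0,1]` along the
  grid diagonal, `g = 0.3` (±15% smooth trend — signal for the spatial
  smoother) and `ε ~ N(0, 0.05²)` unstructured heterogeneity. Sharing the
  effect across ages keeps every region's rates monotone in age.
- **Exposures**: log-uniform in [500, 50,000] person-years per cell,
  independently — two orders of magnitude of denominator heterogeneity, so
  the study contains both data-rich and genuinely small-area cells.
- **Standard weights**: the US 2000 standard million for the six adult
  brackets (162613, 134834, 87247, 66037, 44842, 15508, normalized).

Streams of randomness are separated through `SeedSequence` keys
(scenario, per-replicate counts, per-replicate MC draws), so a master seed
reproduces the entire study bit-for-bit and replicates are independent.

What the generator does **not** emulate: realistic irregular geographies
and population spatial autocorrelation, age-structure correlation within
regions, secular time trends, covariates, or data suppression. Passing
tests therefore demonstrate the estimator's statistical behavior under a
clean Poisson truth with smooth spatial structure — not robustness to
misspecification, survey weighting, or suppressed public-use tables.

Problem sizes in the test suite are scaled to the method, not the data:
the replicate study runs at 10×10 × 100 replicates × 10,000 draws (about a
minute single-threaded); unit tests use 3×3–5×5 grids and 1,000–2,000
draws.

## Numerical choices

- All rates are events per person-year internally; the display scale
  multiplies only at output.
- Gamma quantiles come from `scipy.stats.gamma.ppf`; the test suite checks
  them against independent bisection inversion of the CDF at 1e-8.
- Counts are validated as integers; person-years strictly positive;
  duplicate population rows are an error rather than summed.
- MC standardized draws accumulate age group by age group, keeping memory
  at O(draws × regions).
- CSV output prints rates at 4 significant figures; columns of a method
  not run are empty strings.

## Limitations

- **Interval conservatism at sparse exposures.** The credible interval
  width reflects posterior variance `(y+α)/(n+β)²`, which exceeds the
  frequentist sampling variance of the estimate by the prior's
  pseudo-events `α/(n+β)²`. Wherever `m·t` is material relative to `n·λ`
  the intervals are wider than the estimator's true error, and pooled
  frequentist coverage of a *fixed* truth runs above the nominal 0.95 —
  about 0.98 on the default scenario, in which many cells hold only
  hundreds of person-years. The effect shrinks as cells become data-rich
  (county-scale, multi-year exposures) and vanishes in the limit; it is a
  property of any predetermined-strength conjugate prior, essentially
  independent of the chosen `m` (measured coverage changed by < 0.01
  between `m` = median and `m` = 10th-percentile exposure), and it errs on
  the conservative side. Under the model's own assumptions (truth drawn
  from the prior) the intervals are exactly calibrated, which the
  calibration test verifies.
- The empirical-Bayes construction ignores uncertainty in the smoothing
  target itself; a fully Bayesian spatial model (e.g. a conditional
  autoregressive prior fitted by MCMC) would propagate it at substantial
  computational cost, and is out of scope.
- Record-level input only; aggregate tables with suppressed small counts
  are not handled.
- Shapefile reading is not included; convert boundary layers to GeoJSON,
  or supply a precomputed adjacency JSON.
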