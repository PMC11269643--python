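# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `climenv`, in the order the pipeline runs them.

## Synthetic world

The generator emulates a reanalysis-like monthly product over a regular
lat/lon grid (cell-centre registration, half-cell offset from the extent
edge).  Monthly mean temperature is

    tmean = base + g·(lat − lat_min) + A·cos(2π(m − m_peak)/12) + τ·(t − t0)/10 + ε,

with defaults base 8.5 °C, meridional gradient g = −0.6 °C per degree
latitude, seasonal half-amplitude A = 8 °C peaking in July (a
Northern-Hemisphere temperate setting), warming trend τ = 0.3 °C/decade
(typical of recent European land warming), and monthly noise ε ~ N(0,
0.5 °C).  `tmax`/`tmin` are `tmean` ± independent half-ranges |N(4, 1)| °C
(floored at 0.1), so `tmin ≤ tmean ≤ tmax` holds by construction.
Precipitation is a seasonal mean (65 mm/month, ±40 % winter-peaked
modulation) plus N(0, 15 mm) noise truncated at zero; the truncated
fraction is logged.  Truncated-Gaussian rather than log-normal noise keeps
the moments analytically checkable.

Occurrence is Bernoulli with `logit p = logit(p_peak) − c·(x − μ)²` per
variable; multi-variable species combine per-variable probabilities by
product (configurable to minimum — the marginal fitting downstream makes
this a test convenience, and most tests use single-variable responses).
Ensemble runs are re-generated climate (per-run child seed, so the
unbiased twin is exactly reproducible) with an additive temperature offset
and multiplicative precipitation factor injected, plus a linear-trend GMST
series.  All randomness flows from one root seed through
`numpy.random.SeedSequence.spawn`, so sub-streams are independently
reproducible.

What the generator does *not* emulate: spatial autocorrelation of weather
beyond the smooth gradient, precipitation–temperature covariance, extreme
value tails heavier than Gaussian, land/sea contrast, or observation error
in occurrence data.  Tests passing on this world therefore demonstrate the
*correctness of the computations*, not the realism of any particular
ecological conclusion.

## Bioclim conventions

Quarters are all twelve wrap-around windows of three consecutive calendar
months; the wettest/driest (total precipitation) and warmest/coldest (mean
temperature) windows are selected with ties broken by the earliest starting
month — the convention of the dominant bioclim implementation lineage.
Standard deviations (BIO4, BIO15) use the sample (n−1) convention.  BIO15
is the conventional coefficient of variation, `100·sd/(mean + 1 mm)`; the
+1 mm guards arid cells, at the cost of exact scale-invariance (the scaling
property tests carry the guard's analytic correction).  BIO2 is the mean of
monthly `(tmax − tmin)`, i.e. the monthly-extreme range, since the four
monthly aggregates are the only retained inputs.  BIO3 with a zero annual
range is reported as NaN with an explicit flag, never silently propagated.
IDW interpolation uses great-circle (haversine) distances in km — degree
distances distort with latitude over continental domains — with exact
pass-through for targets within 1 m of a sample.

## Ordination

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on the dissimilarities with Guttman-transform
updates; an update that would raise stress is halved toward the current
configuration (up to 8 times), so stress is non-increasing within a
restart.  Initialisation is classical (Torgerson) scaling, jittered with
N(0, 0.1·rms) for restarts 2..n (default 20); convergence at relative
stress change < 1e-6; the best restart is returned and non-convergence is
flagged, not raised.  Species can be ordinated directly (the default,
entities = species over grid-cell sites) which matches the species-level
reading of the analysis.  Variable vectors are least-squares fits of each
standardized variable on the centred scores; ranking by the L1 loading norm
mirrors the total score's weighting.  No permutation significance tests are
attached to the loadings.

## Envelopes

"Unimodal response" is realized as the quadratic-logit binomial GLM — the
minimal GLM with a unimodal probability response and interpretable
coefficients with p-values.  Envelope bounds are the analytic roots of the
logit quadratic at `logit(cutoff)` (no numeric root finding); the cutoff
(default 0.1) applies to the fitted probability, not observed frequency
bins.  Open bounds distinguish three causes: non-unimodal fit (β₂ ≥ 0),
peak below cutoff (complex roots), and roots outside the fitted data
range.  Physical floors of 0 apply to the precipitation amounts and the two
seasonality indices (BIO4, BIO15); temperature variables have none.
Separation in the GLM (perfect classification) is reported as an error with
the offending coefficient magnitude; in the batch fitter per-pair failures
degrade to both-open envelopes with diagnostics instead of aborting.

## Warming levels

A window "matches" a level when its 30-year mean anomaly is within ±0.1 °C
of the level (configurable); the anomaly baseline is 1850–1900, with an
optional proxy baseline (first k years, flagged) for runs that start later.
Years, not windows, are pooled — deduplicated within a run — because
duplicate counting of overlapping windows would bias the exceedance
frequencies.  Each run-year counts once: no scenario or model weighting.
The 1.2 °C level is labelled "(ref)" in outputs.

## Bias adjustment

Quantile maps pair empirical quantiles on an equally spaced probability
grid (100 points, 0.005–0.995 — a resolution/stability compromise at
30-year monthly reference sample sizes) with monotone linear interpolation
between them.  Tails extrapolate as a constant offset (additive mode,
temperature) or constant ratio with a 0.1 mm wet-threshold floor (ratio
mode, precipitation).  Trend preservation removes the long-term signal, maps
the detrended values re-centred on the model's reference mean, and re-adds
the signal.  The signal estimator is a 31-year local-linear
(Savitzky–Golay, degree 1) smoother rather than an edge-padded running
mean: the two agree in the series interior, but the local-linear fit is
exactly unbiased for linear trends at the series edges, where an
edge-padded mean acquires O(trend·window/4) bias — and the reference period
typically sits at a series edge.  Adjustment is applied to the monthly
series before bioclim derivation (a switch allows plain mapping without
trend handling); variables are adjusted independently, with no multivariate
consistency constraint.

## Exceedance scoring

Intensity bins are left-open right-closed, default edges
(0,5], (5,10], (10,15], (15,25], (25,30], (30,∞); a five-bin preset merging
(15,30] is also shipped, since both schemes are in circulation for this
statistic.  When exactly one bound is open, the intensity denominator falls
back to the span between the finite bound and the opposite extreme of the
historical fitting range (flagged), so exceedance of the finite bound can
still be graded; both-open pairs are skipped with a logged reason.  A year
contributes at most one exceedance per variable, and the sign/bin splits
sum exactly to the total frequency.  Total-score weights
(|load₁|+|load₂|) are normalized to sum to one over the scored variables so
scores are comparable across variable subsets; only the *ranking* of
species scores should be interpreted, not their absolute magnitude.

## Problem sizes and determinism

The bundled end-to-end configurations use a 16×10-cell half-degree world
over 26 years with a 1×2-run ensemble (1850–2100 at the case cell), and the
flagship two-species study an 80×40-cell quarter-degree stationary world
over 30 years — sizes chosen so every example and the full test suite run
comfortably on a single CPU while keeping GLM fits well conditioned
(thousands of sites).  Envelope-recovery checks use 10,000 sites, where the
fitted bounds sit within ±0.1 units of the closed-form truth.  All
stochastic stages take explicit seeds; identical configuration and seed
reproduce every output bit for bit.

## Known limitations

Envelopes are marginal per variable: no interactions, no spatial
autocorrelation correction, no joint multivariate exceedance.  The
exceedance statistic is a stress proxy, not a mortality model.  The IDW
step is a near-identity when inputs are already gridded at the target
resolution.  NMDS loadings from very few entities (two-species studies) are
rank-deficient and should be read as weights, not directions.
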