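# Methods

## Model

Daily death counts `Y_t` in a population stratum are modelled by
quasi-Poisson regression with a log link:

    log E[Y_t] = α + cb(temp)_t + Σ_k β_k 1[dow_t = k] + γ·holiday_t
                 + δ·PM10(ma lag0–2)_t + ns(RH(ma lag0–2)_t, 3 df)
                 + ns(time, 10 df/year) + cb(temp)_t × s_t

`cb(temp)` is a distributed-lag non-linear (DLNM) crossbasis: the tensor
product of a natural cubic spline in temperature (one interior knot at the
75th percentile of the observed series, boundary knots at the observed
minimum/maximum, no intercept → 2 basis functions) and a natural cubic
spline in lag (three knots equally spaced on the log-lag scale between
lag 1 and lag 21, i.e. ≈ 2.14, 4.58, 9.81 days; boundary knots 0 and 21;
with intercept → 5 basis functions).  Lags are the integer days 0–21, so
the crossbasis has 2 × 5 = 10 columns; rows whose 22-day temperature
window is incomplete are dropped from the likelihood rather than
zero-filled.

The final term is the time-varying extension: `s_t` is calendar time in
years, centred at the series midpoint and interacted linearly with every
crossbasis column.  The exposure-lag-response surface at a centring date
`c` is then recovered from the single fit as

    β(c) = β_main + s_c β_int,
    V(c) = V_mm + s_c² V_ii + s_c (V_mi + V_mi′),

which is algebraically identical to refitting the model with time
re-centred at `c` (verified to 1e-6 in the tests).  Annual surfaces are
taken at 1 July of each year — the midpoint of the calendar year, so the
slice summarises that year's average surface under the linearity
assumption.  Centring `s_t` is purely a conditioning device; the Wald
statistic and all predictions are invariant to this affine choice (tested
to 1e-8).

Confounder details: day-of-week enters as six indicators against a Monday
reference; holidays as one indicator read from a plain date-list (the
synthetic generator uses the fixed-date national/state holidays); PM10 and
RH enter as the mean of lags 0–2 (a three-day window — the "lag 0–2"
subscript is read as the lag span), PM10 linearly and RH as a 3-df natural
spline with knots at the terciles of the observed moving average.  The
long-term time spline has `round(10 × years)` total df with equally spaced
interior knots over the observation period; it absorbs both secular trends
and seasonality, so no separate harmonic terms are used.

## Spline construction

Natural cubic splines are built from the cubic B-spline design matrix on
the knot sequence, projected onto the null space of the second-derivative
constraints at the two boundary knots; outside the boundary knots the
basis is continued linearly using the boundary value and slope, so the
natural constraint holds exactly under extrapolation.  B-splines keep the
design well conditioned even for the ~190-column time spline of a 19-year
fit, where a truncated-power parameterization would be numerically
unusable.  The no-intercept variant additionally removes the constant
direction from the span.  Any basis of the same function space gives the
same fitted surfaces; the tests verify this parameterization invariance
directly, using an independent truncated-power construction as the
alternate parameterization.

Percentile-based knots use the linear-interpolation percentile rule (the
scientific-Python default).  Degenerate lag-knot geometries (a knot
coinciding with a boundary, e.g. max lag 1) fall back to a linear lag
basis.

## Fitting

The quasi-Poisson fit is iteratively reweighted least squares on the
log-link Poisson likelihood, stopping when the relative deviance change
falls below 1e-9 (max 100 iterations) and then taking one extra polishing
iteration so coefficient-level identities hold well beyond the deviance
tolerance.  The dispersion φ̂ is the Pearson statistic over residual
degrees of freedom; the coefficient covariance is φ̂ (XᵀWX)⁻¹.  Rank
deficiency raises an error naming the collinear columns (diagnosed by
pivoted QR).  There is no population offset: counts are modelled raw, and
the time spline absorbs slow denominator drift.

Model comparison uses qAIC = −2ℓ/φ̂ + 2p.  `qaic(fit)` defaults to the
fit's own dispersion, but the sensitivity harness ranks candidates using a
common dispersion taken from the most complex candidate, and fits all
candidates on the subset of rows usable by every one of them.  Both
choices matter: with per-model dispersions a misspecified model inflates
its own φ̂ and thereby *deflates* its qAIC (which can invert a lag-window
comparison entirely), and with different lag windows the models would
otherwise be scored on different data.

## Adaptation indicators

The lag-cumulated relative risk of temperature `x` versus reference `r`
is `exp((w(x) − w(r))ᵀ β)` with `w(x)` the overall-cumulative prediction
vector `w_(i,j)(x) = R_i(x) Σ_l C_j(l)`; its variance is the quadratic
form of `w(x) − w(r)` in the slice covariance, and 95% intervals are
normal-theory on the log scale.

The minimum mortality temperature (MMT) is the argmin of the cumulated
log-RR on a 0.1 °C grid restricted to the 1st–99th percentiles of the
exposure distribution (percentile-constricted, avoiding the unstable curve
tails).  The grid is aligned to absolute multiples of the step so nested
constraint windows search nested grids.  Uncertainty comes from a
parametric bootstrap: `n_boot` (default 1000) coefficient vectors drawn
from N(β, V) via the symmetric eigendecomposition square root, each
re-minimised on the grid; the eCI is the empirical 2.5/97.5 percentile
interval and the SE the standard deviation of the draws.  If more than
half the draws land on a constraint boundary the estimate is flagged
boundary-dominated; if the point estimate falls outside its own eCI
(possible for strongly skewed bootstrap distributions) that is flagged
too.  A flat curve (range < 1e-12) is an error: the MMT is undefined.

Annual indicators take the 1 July slice, the MMT constrained to that
year's exposure distribution, and cRRs at the year's 1st/10th/90th/99th
percentiles re-centred at the year's MMT (percentiles from the calendar
year by default; a config switch uses the full-period distribution
instead).  Trends of annual indicators on year use weighted least squares
with weights 1/se² (variance-correcting; equal weights reduce exactly to
OLS), reporting slope, R², Snedecor F, p, and the unweighted Pearson
correlation; cRR trends are fitted on the log scale.  Coupling regressions
(MMT on AMT; log extreme-heat cRR on the annual P99; log extreme-cold cRR
on the annual P1) use the same estimator with the indicator as regressor.
The missingness bias check is a plain Pearson χ² on a
missing-vs-present contingency table, with no continuity correction.

## Synthetic data generator

The generator emulates the statistical structure of a subtropical
Southern-hemisphere megacity over 19 years:

- **Temperature**: a sinusoid peaking on 1 January (mean 19.8 °C,
  amplitude 4.0 °C) plus AR(1) noise (φ = 0.7, stationary sd 1.4 °C) and
  cool-season cold fronts arriving at 0.03/day with depths U(2, 7) °C and
  3-day exponential decay.  The fronts reproduce the negatively skewed
  winter tail of observed series — a pure Gaussian AR(1) cannot reach a
  ~7 °C minimum without overstating the hot tail.  Defaults give overall
  mean ≈ 19.5–19.7 °C and range ≈ 5–30 °C across seeds.
- **RH / PM10**: seasonal AR(1) processes (drier, more polluted winters),
  clipped to physical ranges.
- **Risk surface**: separable truth `f(x, l; t) = g(x; t) h(l)` with
  `g` a split quadratic around a drifting minimum
  `MMT(t) = 20.5 + 0.09 t` °C (cold curvature 0.0041, heat curvature
  0.0047 per °C²) and `h(l) ∝ exp(−l/5)` normalised to sum to one over
  lags 0–21.  The implied cumulated log-RR at constant exposure is `g`
  itself, giving closed-form truth for every MMT/cRR computation.  The
  curvatures and drift are anchored to the first-year magnitudes of the
  motivating analysis (cRR ≈ 1.33 at the 1st percentile, ≈ 1.14 at the
  99th, MMT rising ≈ 1.7 °C over 19 years).  Both tails are anchored at
  the same year because the surface drifts rigidly: mixing first-year and
  last-year anchors would fold the real data's curve *steepening* into a
  sharp curvature kink at the MMT, which the 2-df exposure spline smooths
  over with a systematic cold-ward displacement of the fitted minimum.
- **Counts**: Poisson–gamma with per-day frailty variance (ω−1)/λ so the
  variance/mean ratio is exactly ω (default 1.3) — a generative law whose
  quasi-Poisson dispersion is constant by construction.  Baseline ~600
  deaths/day at the MMT with a slow secular trend (+0.8%/year), winter
  mortality peak (amplitude 0.08 on the log scale), small day-of-week,
  holiday, RH and PM10 effects.

What the generator does *not* emulate: spatially heterogeneous exposure,
influenza co-circulation, El Niño/La Niña modulation, demographic shifts
within strata, and any change of the risk curve's *shape* over time (only
its location drifts).  Passing recovery tests therefore demonstrate that
the pipeline estimates what this class of surface implies — not that the
real data's surface belongs to that class.  The fitted model is *not*
constrained to the generator's separable form, so recovery tests include
honest approximation error and are asserted as coverage bands rather than
exact matches.

## Tunable parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| exposure_knot_percentiles | (75,) | interior knot(s) of the temperature spline |
| max_lag | 21 | days of delayed effect |
| n_lag_knots | 3 | log-spaced interior lag knots |
| time_df_per_year | 10 | seasonality/trend control df |
| rh_df | 3 | humidity spline df |
| ma_max_lag | 2 | PM10/RH moving-average span (lags 0..2) |
| centre_month/day | 7 / 1 | annual slice date |
| n_boot | 1000 | bootstrap draws for the MMT |
| mmt_grid_step | 0.1 °C | MMT search resolution (below reported precision) |
| mmt_constraint | (1, 99) | percentile constriction of the MMT search |
| annual_percentile_basis | "year" | anchors from the year or the full period |

## Numerical choices and edge cases

- Missing daily values are never imputed; any row with a missing required
  regressor (including lagged windows) is dropped at design assembly with
  a logged count.  Assembly refuses to fit with fewer than 5 complete rows
  per parameter.
- Hourly-to-daily aggregation excludes stations below 75% overall valid
  data, requires ≥ 18 of 24 hourly values for a station-day mean, and
  averages retained stations unweighted.
- Near-singular interaction covariance (condition number ≥ 1e10) falls
  back to a pseudo-inverse Wald statistic with a logged warning — small
  strata produce unstable covariances.
- Sensitivity-grid ties in qAIC break by fewest parameters, then
  declaration order.
- All randomness descends from one root seed (per-stratum streams derived
  by hashing the stratum label into a SeedSequence), so identical seeds
  give byte-identical pipeline outputs; no output file contains a
  timestamp.

## Problem sizes used by the test suite

The calibration and recovery properties are checked at sizes chosen to
make the Monte Carlo bands sharp while keeping the suite quick: the null
calibration of the interaction Wald test uses 300 replicates of a 5-year
city at ~100 deaths/day; parameter recovery uses 100 replicates of the
19-year, ~600 deaths/day scenario with drift 0.10 °C/year and 200
bootstrap draws; lag-window selection consistency uses 100 replicates of a
10-year city at ~600 deaths/day.

## Known limitations

- The annual slice summarises a year by its midpoint under the linear
  interaction assumption; strongly non-linear temporal change would be
  aliased.
- qAIC with the same-model dispersion is reported per fit but is not a
  safe ranking criterion (see Fitting); the harness's common-dispersion
  ranking is the supported comparison.
- The percentile-constricted MMT is clamped to its search window; for
  monotone curves the reported MMT is a boundary value and is flagged
  rather than suppressed.
- Education-style strata with high missingness are supported mechanically
  (exclusion plus χ² bias check) but the generator injects missingness
  completely at random, so the bias check's power against structured
  missingness is not exercised.
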