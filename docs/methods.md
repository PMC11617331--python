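# Methods

## Scope and data model

`heatdlnm` analyses daily surveillance series: one row per calendar day
with a case count, daily mean temperature (°C) and relative humidity (%).
All stages operate on the `DailySeries` container; calendar covariates
(day of year, day of week, running time index) are derived from the date
index. Days are the unit of analysis throughout; no spatial structure is
modelled.

## Threshold detection

The exposure-response for acute heat illness is J-shaped, so the
threshold is estimated as the join point of a two-segment linear fit to
the count-versus-temperature curve.

* **Input curve.** Daily counts are binned by temperature (default 1 °C
  bins aligned to whole degrees) and each bin contributes its mean daily
  count, weighted by the number of days in the bin. Fitting binned means
  rather than raw days makes the fitted object the visible scatter-plot
  curve and gives every temperature region comparable leverage; the bin
  width is configurable.
* **Parameterization.** The default `continuous` mode fits
  y = a + b₁x + b₂(x−τ)₊, which forces the segments to meet at τ; that
  matches a J-curve with a kink. `free` mode fits two unrelated lines on
  either side of τ (never a larger SSR than continuous at the same τ,
  but it can leave a jump).
* **Grid.** Candidates run from the 5th to the 95th percentile of
  observed temperature in 0.5 °C steps by default. Candidates leaving
  fewer than two points in a segment are skipped; SSR ties break toward
  the smallest τ.
* **Model comparison.** Gaussian AIC, n·log(SSR/n) + 2k, with the
  breakpoint counted as a parameter (k = 4 continuous, 5 free, 2 for the
  single line). SSRs below the numerical floor n·(10⁻¹⁰·rms(y))² are
  clamped to it so that two exact fits are separated by parameter count
  rather than rounding noise.

When the threshold stage runs inside the full pipeline on lagged count
data, the binned curve mixes each day's count with the previous week's
exposures, which can smear the detected join point about one grid step
above the generative kink. The direct (unlagged) recovery behaviour is
what the breakpoint test suite measures.

## The distributed-lag model

Daily counts follow a quasi-Poisson log-linear model:

    log mu_t = alpha + cb(T, lag 0..L) + gamma RH_t
               + NS(DOY, 4) + NS(t, 3) + eta DOW_t

* **Cross-basis.** Tensor product of a natural cubic spline in
  temperature (df 5) and a polynomial in lag (df 4), L = 7 days. Column
  (j, k) of the design block is Σ_l B_var_j(T_{t−l})·B_lag_k(l). Rows
  without a complete lag history (the first L days) are excluded from
  fitting, not imputed.
* **Temperature spline.** R-style natural cubic spline: df columns imply
  df−1 internal knots at equally spaced quantiles (20/40/60/80th for
  df 5), boundary knots at the observed min/max, zero second derivative
  at the boundaries, and *linear continuation beyond them*. The knots are
  frozen when the basis is built, so predictions and scenario rebuilds
  evaluate identical basis functions. The implementation reproduces R's
  `splines::ns` to machine precision (a frozen oracle matrix is kept in
  the test suite).
* **Lag basis.** Powers 0..3 of lag/7. The constant column is included
  deliberately: without it the lag-0 effect would be forced to zero,
  whereas heat effects on acute illness are concentrated at lags 0–1.
* **Confounders.** Humidity enters linearly (a single column); day-of-year
  (df 4) absorbs within-year seasonality not carried by temperature;
  a df-3 spline in the running day index absorbs long-term trend such as
  reporting drift; day-of-week is categorical with Monday as the fixed
  reference. Exactly collinear columns (e.g. a constant humidity series)
  are detected by sequential orthogonalization, excluded from the solve,
  and reported with zero coefficient and variance at their original
  positions so column bookkeeping is stable.
* **Estimation.** Poisson IRLS (statsmodels GLM) followed by a short
  Newton polish of the score equations, so every returned fit satisfies
  ‖Xᵀ(y−μ̂)‖ < 10⁻⁶. Dispersion is the Pearson statistic
  φ = Σ(y−μ̂)²/μ̂ / (n−p); the covariance is φ(XᵀWX)⁻¹; qAIC
  = −2·loglik/φ + 2p is reported so users can replicate basis-dimension
  selection. The defaults (lag 7, df 5/4/4/3) are fixed, not re-searched.
* **MMT.** The minimal morbidity temperature is the argmin of the
  cumulative RR curve on a 0.1 °C grid between the 1st and 99th
  percentile of the fitted temperatures, ties toward the lower
  temperature. The reference temperature is an explicit argument in every
  prediction and attribution entry point; nothing silently assumes the
  MMT.

## Attribution

For day t, β_x is the fitted cumulative log-RR contrast between the
day's own exposure history {T_t, …, T_{t−7}} and the reference held over
the whole window (backward perspective; a forward variant is not
provided). Then AF_t = 1 − exp(−β_x), AN = Σ n_t·AF_t over days with
same-day temperature above the threshold, and AF% divides by all cases
in the period — the whole-period denominator is what lets scenario AFs
approach 100% as hot days dominate. Intervals are empirical 2.5/97.5
percentiles over Monte Carlo redraws of the full coefficient vector from
N(β̂, V̂); non-PSD covariances are repaired by eigenvalue clipping with a
logged warning. All Monte Carlo paths are seeded and reproducible.

## Projection

A scenario contributes a uniform daily warming δ (mean shift only — no
variance or seasonality change), with a 95% interval read as
δ ± 1.96·sd. Projected burden uses *model-expected* daily counts on the
shifted series, not observed counts: the null scenario (δ = 0) then
reproduces the model-expected baseline attribution exactly, and scenario
AN can exceed the observed historical total because hotter series imply
more expected cases under the fitted curve (population structure is held
fixed). Temperatures shifted past the fitted range follow the natural
spline's linear continuation; the number of extrapolated days is logged
per row. Interval widths for day counts arise only from δ sampling, as
coefficient uncertainty does not move the temperature mask. The baseline
decade is the last ten full calendar years of the input series.

## Synthetic data generator

The generator is the package's testbed and defines its standard study
conditions:

* **Weather.** Temperature = 23.2 + 6·sin(2π(doy−phase)/365.25) + AR(1)
  noise (innovation sd 1.5 °C, autocorrelation 0.6), phase set so the
  peak falls near day 200; overall SD ≈ √(6²/2 + 1.5²/(1−0.6²)) ≈ 4.6 °C,
  matching a subtropical surveillance setting (observed mean 23.2 °C,
  SD 4.9 °C). Humidity is i.i.d. truncated normal, mean 78.9%, sd 5.6.
* **Counts.** log mean = log(baseline 2.0/day) + Σ_l surface(T_{t−l}, l)
  + log(day-of-week factor). The true surface is a hockey stick: zero at
  or below 27 °C, cumulative slope ln(1.71) per °C above, distributed
  over lags 0..7 with front-loaded weights (0.50, 0.25, 0.10, 0.06,
  0.04, 0.02, 0.02, 0.01). Overdispersion (default φ = 1.5) is generated
  as negative binomial with p = 1/φ, r = μ/(φ−1), matching mean μ and
  variance φμ — quasi-Poisson is a fitting device, not a generative law,
  and NB is its standard simulable surrogate. The first 7 days are drawn
  at baseline so the series stays aligned; the fitting stage owns the
  exclusion rule.
* **What it does not emulate.** Station-level spatial structure, typhoon
  extremes, humidity-temperature dependence, demographic structure, or
  case-crossover referent sampling. Passing tests therefore demonstrate
  statistical correctness of the machinery under the stated generative
  model, not robustness to those real-data features.

## Known limitations

* **Smooth-basis bias at a slope discontinuity.** The generator's truth
  has a corner at 27 °C, but every function in the cross-basis span is
  C². The fitted cumulative curve therefore rounds the corner, and the
  one-degree contrast straddling it (threshold → threshold+1) is
  systematically attenuated: projecting the true log-risk surface onto
  the cross-basis column space — a bound no estimator in this model class
  can beat — already loses 20–35% of that contrast for every knot
  placement we examined, including knots at the kink. The parameter-
  recovery and attribution-coverage checks in the acceptance suite
  quantify the consequence (mean cumulative-RR estimates near 1.55
  against a generative 1.71, attributable numbers a few percent high
  with intervals too narrow to absorb the offset). Contrasts evaluated
  well inside the linear region, and within-model-class simulations
  (see the regression test suite), are recovered correctly — the bias is
  a property of approximating a kink with a smooth basis, not of the
  estimator.
* **Threshold stage on lagged data.** See above: join points detected on
  binned lagged counts sit slightly above the generative kink.
* **Projection assumes stationarity** of everything except the mean
  temperature: no adaptation (fixed MMT), no demographic change, no
  humidity scenarios.
* **No inference on τ** (no Davies test or bootstrap), single breakpoint
  only, and no penalized/GAM alternatives to the fixed-df bases.
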