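# heatdlnm

Temperature-attributable acute heat illness, end to end: threshold
detection, distributed-lag nonlinear modelling, attributable burden, and
climate-scenario projection for daily surveillance count series.

## The problem

Emergency-department surveillance systems in hot climates record daily
counts of acute heat illness (heat stroke, heat syncope, heat cramps,
heat exhaustion). The relationship between daily mean temperature and
these counts is J-shaped — essentially flat below some *nonoptimal
temperature threshold* and rising steeply above it — and the effect of a
hot day is spread over the following week. Public-health planning needs
three numbers from such data: the threshold itself, the burden of cases
attributable to heat today, and the burden expected under future warming
scenarios. `heatdlnm` implements that full chain for epidemiologists
working with daily count/weather series, and ships a synthetic-data
generator with known ground truth so every stage can be validated by
parameter recovery.

## The model

**Threshold.** The count-versus-temperature curve (daily counts binned by
1 °C of temperature, weighted by days per bin) is fitted with a
two-segment linear model over a grid of candidate breakpoints τ,

  min_τ Σᵢ wᵢ (yᵢ − a − b₁xᵢ − b₂(xᵢ − τ)₊)²,

keeping the τ with the smallest weighted SSR; the segmented model is
compared with a single line by Gaussian AIC (the breakpoint counts as a
parameter). A `free` mode fits two unconnected lines instead.

**Distributed-lag nonlinear model (DLNM).** Daily counts are
quasi-Poisson with log link:

  log μ_t = α + cb(T; lag 0..7) + γ·RH_t + NS(DOY, 4) + NS(t, 3) + η·DOW_t

where the cross-basis `cb` is the tensor product of a natural cubic
spline in temperature (df 5, knots at the 20/40/60/80th percentiles) and
a polynomial in lag (df 4, powers 0..3 of lag/7), RH is relative
humidity, NS(DOY, 4) absorbs within-year seasonality, NS(t, 3) absorbs
long-term trend, and DOW is day-of-week (Monday reference). Estimation is
Poisson IRLS with the covariance scaled by the Pearson dispersion φ.
Fitted coefficients are summarised as the cumulative exposure-response
curve RR(x) against a reference temperature, the lag-response profile,
and the full temperature × lag surface. The *minimal morbidity
temperature* (MMT) is the argmin of the cumulative RR curve.

**Attribution.** With β_x the backward-perspective cumulative log-RR of
day t's own exposure history versus a constant reference (the MMT),

  AF_t = 1 − exp(−β_x),  AN = Σ_t n_t · AF_t,

summed over days whose temperature exceeds the threshold, with the
fraction expressed against all cases in the period. Confidence intervals
come from Monte Carlo resampling of the coefficient vector from
N(β̂, V̂).

**Projection.** A scenario is a mean warming δ (with 95% interval) for a
target decade. The baseline decade's temperatures are shifted by δ, the
fitted model recomputes expected daily cases on the shifted series, and
the attribution machinery yields days above threshold, AN and AF;
intervals propagate coefficient and (optionally) δ uncertainty. Beyond
the fitted temperature range the natural spline continues linearly.

## Worked example

```python
import numpy as np
from heatdlnm import *
from heatdlnm.threshold import default_grid

config = SimConfig(seed=42)                  # a synthetic decade, ~12k cases
truth = TrueSurface()                        # threshold 27 °C, RR 1.71 per +1 °C
series = simulate_counts(simulate_weather(config), truth, config)

x, y, w = aggregate_by_temperature(series, bin_width=1.0)
seg = fit_segmented(x, y, w, default_grid(series.tmean))

cb = build_crossbasis(series.tmean)
fit = fit_quasipoisson(build_design(series, cb), cb)
mmt = find_mmt(fit)
rr = predict_cumulative(fit, cb, [seg.tau + 1.0], reference=seg.tau)
attr = attribute_period(fit, series, reference=mmt, threshold=seg.tau,
                        n_sim=500, seed=1)
```

printing the pieces gives:

```
join point: 28.0 C  (segmented preferred: True)
dispersion: 1.528   MMT: 14.4 C
RR per +1 C above 28 C: 1.56 (95% CI 1.51-1.60)
AN above 28 C: 4,753 (95% CI 4,356-5,034) of 12,149 cases  AF 39.1%
SSP5-8.5 (+5.8 C): days>thr 2,017 AF 97.5% (95.9-98.5)
```

The detected join point (28 °C) sits one grid step above the generator's
27 °C: the binned count curve mixes each day's count with the previous
week's exposures, which smears the kink slightly upward. The cumulative
RR per +1 °C (1.56) is below the generative 1.71 because a smooth spline
basis necessarily rounds off a slope discontinuity — see
`docs/methods.md` for the quantitative discussion. The attribution row
says 39% of the decade's cases are attributable to temperatures above the
threshold, and under a +5.8 °C scenario nearly every summer day exceeds
it.

The same chain is available from the shell:

```
heatdlnm simulate --n-years 10 --seed 42 --out data.csv
heatdlnm threshold --input data.csv --out thr.json
heatdlnm fit --input data.csv --out model.json
heatdlnm attribute --model model.json --input data.csv --threshold 28 --out attr.csv
heatdlnm project --model model.json --baseline data.csv \
    --scenario "SSP5-8.5=5.8:5.3,6.3" --threshold 28 --out proj.csv
heatdlnm run --config examples/pipeline.yaml --outdir out/
```

`heatdlnm run` executes all stages and writes a manifest with per-stage
seeds and output checksums; two runs of the same config are bit-identical.

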