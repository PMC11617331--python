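"""Synthetic daily surveillance data with a known exposure-lag-response truth.

The generator emulates a subtropical surveillance setting: a seasonal
temperature cycle around an annual mean near 23 °C, humidity near 79%, and
overdispersed daily counts whose log mean follows a J-shaped ("hockey
stick") exposure-response — zero excess risk below a threshold near 27 °C
and a log-linear rise above it — distributed over lags 0..lag_max with a
front-loaded lag profile. Because the true threshold, cumulative log
relative risk and lag weights are known exactly, every downstream stage
(threshold detection, cross-basis regression, attribution, projection) can
be validated by parameter recovery rather than against an external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientHistoryError, InvalidConfigError
from .series import DailySeries

__all__ = [
    "TrueSurface",
    "SimConfig",
    "simulate_weather",
    "simulate_counts",
    "shift_scenario",
]

#: Seasonal phase (days) placing the sinusoid peak near day 200 of the year,
#: the centre of the observed summer case season.
DEFAULT_PHASE = 200.0 - 365.25 / 4.0


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth exposure-lag-response surface.

    The surface is piecewise-linear in temperature: zero at or below
    ``threshold`` and rising with slope ``log_rr_per_degree`` (cumulated
    over lags) above it. ``lag_weights[l]`` is the share of the cumulative
    effect acting at lag ``l``; the weights are nonnegative and sum to 1.
    """

    threshold: float = 27.0
    log_rr_per_degree: float = float(np.log(1.71))
    lag_weights: tuple[float, ...] = (0.50, 0.25, 0.10, 0.06, 0.04, 0.02, 0.02, 0.01)

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if w.size == 0 or (w < 0).any():
            raise InvalidConfigError("lag_weights must be nonnegative and nonempty")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidConfigError(f"lag_weights must sum to 1, got {w.sum()!r}")

    @property
    def lag_max(self) -> int:
        return len(self.lag_weights) - 1

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.lag_weights, dtype=float)

    def value(self, temp, lag: int) -> np.ndarray:
        """Log relative-risk contribution of exposure ``temp`` at lag ``lag``."""
        excess = np.maximum(np.asarray(temp, dtype=float) - self.threshold, 0.0)
        return self.weights[lag] * self.log_rr_per_degree * excess

    def cumulative(self, temp) -> np.ndarray:
        """Cumulative (lag-summed) log relative risk at constant exposure ``temp``."""
        excess = np.maximum(np.asarray(temp, dtype=float) - self.threshold, 0.0)
        return self.log_rr_per_degree * excess


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the weather and count generators.

    Defaults target the descriptive moments of the motivating surveillance
    setting: annual mean temperature 23.2 °C with overall SD near 4.9 °C
    (seasonal amplitude 6 °C plus AR(1) day-to-day noise), humidity
    78.9% (SD 5.6), and a few expected cases per day at reference
    conditions with moderate overdispersion.
    """

    n_years: int = 10
    temp_mean: float = 23.2
    temp_amplitude: float = 6.0
    temp_noise_sd: float = 1.5
    temp_ar: float = 0.6
    temp_phase: float = DEFAULT_PHASE
    rh_mean: float = 78.9
    rh_sd: float = 5.6
    baseline_rate: float = 2.0
    dispersion: float = 1.5
    dow_effects: tuple[float, ...] = (1.0,) * 7
    start_year: int = 2010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise InvalidConfigError("n_years must be >= 1")
        if self.baseline_rate <= 0:
            raise InvalidConfigError("baseline_rate must be positive")
        if self.dispersion < 1:
            raise InvalidConfigError("dispersion must be >= 1")
        if not (0 <= self.temp_ar < 1):
            raise InvalidConfigError("temp_ar must lie in [0, 1)")
        if len(self.dow_effects) != 7 or any(e <= 0 for e in self.dow_effects):
            raise InvalidConfigError("dow_effects must be 7 positive factors")


def simulate_weather(config: SimConfig) -> DailySeries:
    """Simulate daily temperature and humidity over whole calendar years.

    Temperature is a sinusoidal annual cycle plus stationary AR(1) noise:
    ``T_t = mean + amplitude * sin(2*pi*(doy - phase)/365.25) + e_t`` with
    ``e_t = ar * e_{t-1} + N(0, noise_sd^2)`` started from its stationary
    distribution. Humidity is i.i.d. normal truncated to [0, 100].
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.n_years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()

    seasonal = config.temp_mean + config.temp_amplitude * np.sin(
        2.0 * np.pi * (doy - config.temp_phase) / 365.25
    )
    innov = rng.normal(0.0, config.temp_noise_sd, size=n)
    noise = np.empty(n)
    if config.temp_noise_sd == 0.0:
        noise[:] = 0.0
    else:
        stationary_sd = config.temp_noise_sd / np.sqrt(1.0 - config.temp_ar**2)
        noise[0] = rng.normal(0.0, stationary_sd)
        for t in range(1, n):
            noise[t] = config.temp_ar * noise[t - 1] + innov[t]
    tmean = seasonal + noise

    if config.rh_sd == 0.0:
        rh = np.full(n, float(np.clip(config.rh_mean, 0, 100)))
    else:
        a = (0.0 - config.rh_mean) / config.rh_sd
        b = (100.0 - config.rh_mean) / config.rh_sd
        rh = stats.truncnorm.rvs(
            a, b, loc=config.rh_mean, scale=config.rh_sd, size=n, random_state=rng
        )
    return DailySeries(dates, tmean, rh)


def _lagged_log_excess(tmean: np.ndarray, surface: TrueSurface) -> np.ndarray:
    """Sum over lags of the surface applied to each day's exposure history."""
    excess = np.maximum(tmean - surface.threshold, 0.0) * surface.log_rr_per_degree
    L = surface.lag_max
    out = np.zeros_like(tmean)
    for lag, w in enumerate(surface.weights):
        if w == 0.0:
            continue
        out[lag:] += w * excess[: len(tmean) - lag]
    # days 0..L-1 have incomplete history; the caller overwrites them
    out[:L] = 0.0
    return out


def simulate_counts(
    weather: DailySeries, surface: TrueSurface, config: SimConfig
) -> DailySeries:
    """Draw daily counts from the generative twin of the fitted model.

    For each day t with full lag history, the log mean is
    ``log(baseline_rate) + sum_l surface(T_{t-l}, l) + log(dow_effect)``.
    Counts are Poisson when ``dispersion == 1`` and negative binomial with
    variance ``dispersion * mean`` otherwise. The leading ``lag_max`` days
    are drawn at baseline so the series stays aligned; the fitting stage
    owns the exclusion rule.
    """
    L = surface.lag_max
    if len(weather) <= L:
        raise InsufficientHistoryError(
            f"series of length {len(weather)} cannot cover lag window {L}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dow_effect = np.asarray(config.dow_effects, dtype=float)[weather.dow]
    log_mu = np.log(config.baseline_rate) + np.log(dow_effect)
    log_mu = log_mu + _lagged_log_excess(weather.tmean, surface)
    mu = np.exp(log_mu)
    if config.dispersion == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB with p = 1/phi, r = mu/(phi-1): mean mu, variance phi*mu
        r = mu / (config.dispersion - 1.0)
        counts = rng.negative_binomial(r, 1.0 / config.dispersion)
    return weather.with_cases(counts)


def shift_scenario(weather: DailySeries, delta: float) -> DailySeries:
    """Return a copy with every temperature incremented by ``delta`` °C."""
    if not np.isfinite(delta):
        raise InvalidConfigError("scenario delta must be finite")
    return weather.with_tmean(weather.tmean + float(delta))
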