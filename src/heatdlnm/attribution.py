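"""Attributable fraction and number of cases due to nonoptimal temperature.

For each day t the model gives a backward-perspective log relative risk
``beta_x`` comparing the day's own exposure history {T_t, ..., T_{t-L}}
against a constant reference temperature (the minimal morbidity
temperature by default). The attributable fraction and number follow the
standard attributable-risk identities

    AF_t = 1 - exp(-beta_x),        AN = sum_t  n_t * AF_t,

with the sum restricted to days whose same-day temperature exceeds the
heat threshold and the fraction expressed against all cases in the
period. Uncertainty comes from Monte Carlo resampling of the coefficient
vector from its multivariate-normal sampling distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .basis import CrossBasis
from .errors import EmptyPeriodError
from .regression import FittedDLNM
from .series import DailySeries

__all__ = ["DailyAF", "AttributionResult", "daily_af", "aggregate", "mc_interval",
           "attribute_period"]

logger = logging.getLogger(__name__)


@dataclass
class DailyAF:
    """Per-day attributable fractions (NaN where lag history is incomplete)."""

    af: np.ndarray
    beta_x: np.ndarray
    valid: np.ndarray
    n_excluded: int
    reference: float


@dataclass
class AttributionResult:
    """One period's attributable burden (one row of a burden table)."""

    an: float
    af_pct: float
    an_ci: tuple[float, float]
    af_ci: tuple[float, float]
    n_total: float
    days_exceeding: int
    reference: float
    threshold: float
    period: str
    n_sim: int = 0
    seed: int | None = None


def _contrast_rows(
    fit: FittedDLNM, series: DailySeries, reference: float
) -> tuple[np.ndarray, np.ndarray]:
    """Backward contrast matrix Z (valid days × cb columns) and valid index."""
    cb = fit.crossbasis
    M = cb.rebuild(series.tmean)
    valid = np.arange(cb.valid_from, len(series))
    Z = M[valid] - cb.cum_vector(reference)
    return Z, valid


def daily_af(fit: FittedDLNM, series: DailySeries, reference: float) -> DailyAF:
    """Attributable fraction of each day's cases, backward perspective.

    ``beta_x`` for day t is the fitted cumulative log-RR contrast of the
    day's own lagged exposure history versus holding the reference
    temperature over the whole lag window; days with history entirely at
    the reference get AF exactly 0. Days without complete history are
    excluded and counted.
    """
    sl = fit.column_map["crossbasis"]
    Z, valid = _contrast_rows(fit, series, reference)
    beta_x = np.full(len(series), np.nan)
    beta_x[valid] = Z @ fit.coef[sl]
    af = 1.0 - np.exp(-beta_x)
    mask = np.zeros(len(series), dtype=bool)
    mask[valid] = True
    return DailyAF(
        af=af,
        beta_x=beta_x,
        valid=mask,
        n_excluded=int(len(series) - valid.size),
        reference=float(reference),
    )


def aggregate(
    daf: DailyAF,
    series: DailySeries,
    threshold: float,
    period: str = "",
    counts: np.ndarray | None = None,
) -> AttributionResult:
    """Aggregate daily AF into AN / AF% over days exceeding the threshold.

    AN sums ``count * AF`` over valid days whose same-day temperature
    exceeds ``threshold``; AF% divides by all cases on valid days of the
    period, matching a whole-period denominator.
    """
    if counts is None:
        counts = series.cases
    counts = np.asarray(counts, dtype=float)
    valid = daf.valid & np.isfinite(counts)
    if not valid.any():
        raise EmptyPeriodError("no usable days in period")
    hot = valid & (series.tmean > threshold)
    an = float(np.sum(counts[hot] * daf.af[hot])) if hot.any() else 0.0
    n_total = float(np.sum(counts[valid]))
    af_pct = 100.0 * an / n_total if n_total > 0 else 0.0
    return AttributionResult(
        an=an,
        af_pct=af_pct,
        an_ci=(an, an),
        af_ci=(af_pct, af_pct),
        n_total=n_total,
        days_exceeding=int(hot.sum()),
        reference=daf.reference,
        threshold=float(threshold),
        period=period,
    )


def _coef_draws(
    coef: np.ndarray, vcov: np.ndarray, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """MVN coefficient draws; non-PSD covariances repaired by eigenvalue clipping."""
    vals, vecs = np.linalg.eigh((vcov + vcov.T) / 2.0)
    if vals.min() < -1e-10 * max(vals.max(), 1.0):
        logger.warning("covariance not PSD (min eigenvalue %.3g); clipping", vals.min())
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    z = rng.standard_normal((n_sim, coef.size))
    return coef + z @ root.T


def mc_interval(
    fit: FittedDLNM,
    series: DailySeries,
    reference: float,
    threshold: float,
    n_sim: int = 1000,
    seed: int = 0,
    counts: np.ndarray | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% Monte Carlo intervals for (AN, AF%) by coefficient resampling."""
    sl = fit.column_map["crossbasis"]
    Z, valid_idx = _contrast_rows(fit, series, reference)
    if counts is None:
        counts = series.cases
    counts = np.asarray(counts, dtype=float)[valid_idx]
    temps = series.tmean[valid_idx]
    hot = temps > threshold

    rng = np.random.default_rng(seed)
    draws = _coef_draws(fit.coef, fit.vcov, n_sim, rng)[:, sl]
    af_draws = 1.0 - np.exp(-(Z[hot] @ draws.T))  # (hot days, n_sim)
    an_s = counts[hot] @ af_draws if hot.any() else np.zeros(n_sim)
    n_total = counts.sum()
    af_s = 100.0 * an_s / n_total if n_total > 0 else np.zeros(n_sim)
    an_ci = tuple(np.percentile(an_s, [2.5, 97.5]))
    af_ci = tuple(np.percentile(af_s, [2.5, 97.5]))
    return an_ci, af_ci


def attribute_period(
    fit: FittedDLNM,
    series: DailySeries,
    reference: float,
    threshold: float,
    period: str = "",
    n_sim: int = 1000,
    seed: int = 0,
    counts: np.ndarray | None = None,
) -> AttributionResult:
    """Point estimates plus Monte Carlo intervals in one call."""
    daf = daily_af(fit, series, reference)
    result = aggregate(daf, series, threshold, period=period, counts=counts)
    if n_sim > 0:
        an_ci, af_ci = mc_interval(
            fit, series, reference, threshold, n_sim=n_sim, seed=seed, counts=counts
        )
        result.an_ci = (float(an_ci[0]), float(an_ci[1]))
        result.af_ci = (float(af_ci[0]), float(af_ci[1]))
        result.n_sim = n_sim
        result.seed = seed
    return result
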