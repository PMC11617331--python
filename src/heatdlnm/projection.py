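"""Projection of heat-illness burden under climate-scenario warming.

Each scenario supplies a mean-temperature increase (with an uncertainty
interval) for a future decade. The baseline decade's weather is shifted by
that delta, the fitted model recomputes the expected daily case counts on
the shifted series (population and baseline structure held fixed), and the
attribution machinery turns those into attributable number/fraction and
days exceeding the heat threshold. Monte Carlo intervals propagate both
coefficient uncertainty and (optionally) the scenario delta uncertainty;
interval widths for day counts arise only from delta sampling.

Temperatures pushed beyond the fitted range are handled by the natural
spline's linear continuation beyond its boundary knots; the number of
extrapolated days is logged on each row.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import _coef_draws, _contrast_rows, daily_af
from .errors import DuplicateKeyError, EmptyInputError, InvalidConfigError
from .regression import FittedDLNM, design_for
from .series import DailySeries
from .synthetic import shift_scenario

__all__ = ["Scenario", "ProjectionRow", "SSP_SCENARIOS", "project_burden",
           "scenario_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """A shared-socioeconomic-pathway temperature shift for a target decade."""

    name: str
    delta_mean: float
    delta_ci: tuple[float, float] = (None, None)  # type: ignore[assignment]
    period: str = "2090-2099"

    def __post_init__(self) -> None:
        lo, hi = self.delta_ci
        if lo is None or hi is None:
            object.__setattr__(self, "delta_ci", (self.delta_mean, self.delta_mean))
            return
        if not (lo <= self.delta_mean <= hi):
            raise InvalidConfigError(
                f"delta_ci {self.delta_ci} must bracket delta_mean {self.delta_mean}"
            )

    @property
    def delta_sd(self) -> float:
        """Normal SD implied by treating delta_ci as a 95% interval."""
        lo, hi = self.delta_ci
        return (hi - lo) / (2.0 * 1.959963984540054)


#: End-of-century mean warming for Taiwan under the four SSP scenarios
#: (delta in °C with 95% interval), used as the shipped example set.
SSP_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("SSP1-2.6", 1.4, (0.9, 1.9)),
    Scenario("SSP2-4.5", 2.5, (2.1, 3.0)),
    Scenario("SSP3-7.0", 4.3, (3.8, 4.8)),
    Scenario("SSP5-8.5", 5.8, (5.3, 6.3)),
)


@dataclass
class ProjectionRow:
    """Burden of one scenario in one decade (one cell-row of the report)."""

    scenario: str
    period: str
    delta: float
    days_exceeding: float
    days_ci: tuple[float, float]
    an: float
    an_ci: tuple[float, float]
    af_pct: float
    af_ci: tuple[float, float]
    expected_cases: float
    n_extrapolated_days: int = 0


def _burden_on(
    fit: FittedDLNM,
    series: DailySeries,
    threshold: float,
    reference: float,
    coef: np.ndarray | None = None,
) -> tuple[float, float, int, float]:
    """(AN, AF%, days exceeding, total expected cases) on one shifted series."""
    beta = fit.coef if coef is None else coef
    X, valid = design_for(fit, series)
    mu = np.exp(X @ beta)
    sl = fit.column_map["crossbasis"]
    Z, _ = _contrast_rows(fit, series, reference)
    af = 1.0 - np.exp(-(Z @ beta[sl]))
    hot = series.tmean[valid] > threshold
    an = float(mu[hot] @ af[hot]) if hot.any() else 0.0
    total = float(mu.sum())
    af_pct = 100.0 * an / total if total > 0 else 0.0
    return an, af_pct, int(hot.sum()), total


def project_burden(
    fit: FittedDLNM,
    baseline: DailySeries,
    scenario: Scenario,
    threshold: float,
    reference: float,
    n_sim: int = 1000,
    seed: int = 0,
    sample_delta: bool = True,
) -> ProjectionRow:
    """Burden of one scenario on the shifted baseline decade.

    Expected daily cases come from the fitted model evaluated on the
    shifted series (not observed counts), so a zero-delta scenario
    reproduces the model-expected baseline burden exactly. Monte Carlo
    intervals redraw the coefficient vector each iteration and, when
    ``sample_delta`` is on, a scenario delta from N(delta_mean, delta_sd).
    """
    if len(baseline) < 3650:
        logger.warning("baseline of %d days is shorter than a decade", len(baseline))
    shifted = shift_scenario(baseline, scenario.delta_mean)
    an, af_pct, days, total = _burden_on(fit, shifted, threshold, reference)

    b0, b1 = fit.crossbasis.var_spline.boundary
    n_extrap = int(((shifted.tmean < b0) | (shifted.tmean > b1)).sum())
    if n_extrap:
        logger.info(
            "%s: %d days beyond the fitted temperature range (linear continuation)",
            scenario.name, n_extrap,
        )

    if n_sim <= 0:
        return ProjectionRow(
            scenario=scenario.name, period=scenario.period, delta=scenario.delta_mean,
            days_exceeding=days, days_ci=(days, days), an=an, an_ci=(an, an),
            af_pct=af_pct, af_ci=(af_pct, af_pct), expected_cases=total,
            n_extrapolated_days=n_extrap,
        )

    rng = np.random.default_rng(seed)
    draws = _coef_draws(fit.coef, fit.vcov, n_sim, rng)
    sd = scenario.delta_sd if sample_delta else 0.0
    deltas = rng.normal(scenario.delta_mean, sd, size=n_sim) if sd > 0 else None

    an_s = np.empty(n_sim)
    af_s = np.empty(n_sim)
    days_s = np.empty(n_sim)
    if deltas is None:
        # fixed design: vectorize over coefficient draws
        X, valid = design_for(fit, shifted)
        sl = fit.column_map["crossbasis"]
        Z, _ = _contrast_rows(fit, shifted, reference)
        hot = shifted.tmean[valid] > threshold
        mu_all = np.exp(X @ draws.T)  # (n_valid, n_sim)
        af_all = 1.0 - np.exp(-(Z @ draws[:, sl].T))
        an_s = np.einsum("ts,ts->s", mu_all[hot], af_all[hot]) if hot.any() else np.zeros(n_sim)
        totals = mu_all.sum(axis=0)
        af_s = np.where(totals > 0, 100.0 * an_s / totals, 0.0)
        days_s[:] = float(hot.sum())
    else:
        for s in range(n_sim):
            shifted_s = shift_scenario(baseline, float(deltas[s]))
            an_i, af_i, d_i, _ = _burden_on(
                fit, shifted_s, threshold, reference, coef=draws[s]
            )
            an_s[s], af_s[s], days_s[s] = an_i, af_i, d_i

    return ProjectionRow(
        scenario=scenario.name,
        period=scenario.period,
        delta=scenario.delta_mean,
        days_exceeding=days,
        days_ci=tuple(np.percentile(days_s, [2.5, 97.5])),
        an=an,
        an_ci=tuple(np.percentile(an_s, [2.5, 97.5])),
        af_pct=af_pct,
        af_ci=tuple(np.percentile(af_s, [2.5, 97.5])),
        expected_cases=total,
        n_extrapolated_days=n_extrap,
    )


def scenario_table(rows: list[ProjectionRow]) -> pd.DataFrame:
    """Wide burden table: scenario × period × {days, AN, AF} with CIs.

    One input row per (scenario, period); duplicates are an error. The
    frame is tidy (one row per scenario-period) and carries both numeric
    columns and a preformatted ``"value (lo-hi)"`` text column per metric.
    """
    if not rows:
        raise EmptyInputError("scenario table needs at least one row")
    seen = set()
    records = []
    for r in rows:
        key = (r.scenario, r.period)
        if key in seen:
            raise DuplicateKeyError(f"duplicate scenario/period {key}")
        seen.add(key)
        for ci in (r.days_ci, r.an_ci, r.af_ci):
            if ci is None or any(c is None or not np.isfinite(c) for c in ci):
                raise InvalidConfigError(f"row {key} has missing interval fields")
        records.append(
            {
                "scenario": r.scenario,
                "period": r.period,
                "delta_c": r.delta,
                "days_exceeding": r.days_exceeding,
                "days_low": r.days_ci[0],
                "days_high": r.days_ci[1],
                "an": r.an,
                "an_low": r.an_ci[0],
                "an_high": r.an_ci[1],
                "af_pct": r.af_pct,
                "af_low": r.af_ci[0],
                "af_high": r.af_ci[1],
                "days_text": _fmt(r.days_exceeding, r.days_ci, 0),
                "an_text": _fmt(r.an, r.an_ci, 0),
                "af_text": _fmt(r.af_pct, r.af_ci, 1),
            }
        )
    return pd.DataFrame.from_records(records)


def _fmt(value: float, ci: tuple[float, float], digits: int) -> str:
    def f(v: float) -> str:
        return f"{v:,.{digits}f}"

    return f"{f(value)} ({f(ci[0])}-{f(ci[1])})"


def format_table(table: pd.DataFrame) -> str:
    """Human-readable text rendering of a scenario table."""
    buf = io.StringIO()
    cols = ["scenario", "period", "days_text", "an_text", "af_text"]
    headers = ["Scenario", "Period", "Days > threshold", "AN (95% CI)", "AF % (95% CI)"]
    sub = table[cols].astype(str)
    widths = [max(len(h), int(sub[c].str.len().max())) for h, c in zip(headers, cols)]
    buf.write("  ".join(h.ljust(w) for h, w in zip(headers, widths)) + "\n")
    for _, row in sub.iterrows():
        buf.write("  ".join(str(row[c]).ljust(w) for c, w in zip(cols, widths)) + "\n")
    return buf.getvalue()
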