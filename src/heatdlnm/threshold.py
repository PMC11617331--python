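"""Nonoptimal-temperature threshold by two-segment least squares.

The count-versus-temperature curve for heat illness is J-shaped: flat near
zero below some temperature and rising steeply above it. The join point of
that curve is found by fitting a two-segment linear model over a grid of
candidate breakpoints and keeping the breakpoint with the smallest
(weighted) sum of squared residuals, then comparing the segmented model
against a single straight line by AIC.

Two parameterizations are supported. ``continuous`` (the default) fits
``y = a + b1*x + b2*(x - tau)_+`` so the two segments meet at the
breakpoint. ``free`` fits two unrelated lines on either side of the
candidate, which can only lower the SSR but may leave a jump at tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, InvalidConfigError, NoValidBreakpointError
from .series import DailySeries

__all__ = [
    "SegmentedFit",
    "aggregate_by_temperature",
    "default_grid",
    "fit_segmented",
    "join_point_report",
]

logger = logging.getLogger(__name__)


@dataclass
class SegmentedFit:
    """Result of the breakpoint grid search.

    ``(alpha1, beta1)`` describe the segment with x <= tau and
    ``(alpha2, beta2)`` the segment with x > tau, both as intercept/slope
    of a plain line so the two parameterizations report comparable
    coefficients. AIC uses the Gaussian-residual form
    ``n*log(SSR/n) + 2k`` with the breakpoint counted as a parameter.
    """

    tau: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    ssr: float
    aic_segmented: float
    aic_linear: float
    n1: int
    n: int
    grid: np.ndarray
    continuity_mode: str
    linear_coef: tuple[float, float] = (0.0, 0.0)
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    w: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, x) -> np.ndarray:
        """Fitted values of the segmented model."""
        x = np.asarray(x, dtype=float)
        left = self.alpha1 + self.beta1 * x
        right = self.alpha2 + self.beta2 * x
        return np.where(x <= self.tau, left, right)

    def predict_linear(self, x) -> np.ndarray:
        a, b = self.linear_coef
        return a + b * np.asarray(x, dtype=float)


def aggregate_by_temperature(
    series: DailySeries, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin days by temperature; return bin centres, mean counts, day weights.

    Bin edges are aligned to multiples of ``bin_width`` (a day at 20.1 °C
    with 1 °C bins falls in [20, 21), centre 20.5). Bins containing no days
    are omitted, so ``sum(w)`` equals the number of days and
    ``sum(w * y)`` equals the total count.
    """
    if bin_width <= 0:
        raise InvalidConfigError("bin_width must be positive")
    if series.cases is None or len(series) == 0:
        raise EmptyInputError("series with counts required")
    idx = np.floor(series.tmean / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    uniq, start = np.unique(idx[order], return_index=True)
    counts = np.asarray(series.cases, dtype=float)[order]
    w = np.diff(np.r_[start, len(idx)]).astype(float)
    sums = np.add.reduceat(counts, start)
    x = (uniq + 0.5) * bin_width
    return x, sums / w, w


def default_grid(
    temps: np.ndarray, step: float = 0.5, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> np.ndarray:
    """Candidate breakpoints between temperature percentiles, fixed step."""
    lo, hi = np.percentile(temps, [lo_pct, hi_pct])
    lo = np.ceil(lo / step) * step
    return np.arange(lo, hi + 1e-9, step)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    return coef, float(np.sum(w * resid**2))


def _aic(ssr: float, n: int, k: int, floor: float = 1e-300) -> float:
    # Gaussian-likelihood AIC up to an additive constant shared by models.
    # SSRs at numerical zero are floored so that two exact fits are compared
    # on parameter count alone rather than on rounding noise.
    return n * np.log(max(ssr, floor) / n) + 2 * k


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    continuity_mode: str = "continuous",
) -> SegmentedFit:
    """Grid-search the breakpoint minimizing the weighted SSR.

    Candidates that leave fewer than two points in either segment are
    skipped with a log record. Ties in SSR break toward the smallest tau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if continuity_mode not in ("continuous", "free"):
        raise InvalidConfigError(f"unknown continuity mode {continuity_mode!r}")
    if x.size < 4:
        raise EmptyInputError("segmented regression needs at least 4 points")
    if grid is None:
        grid = default_grid(x)
    grid = np.asarray(grid, dtype=float)

    n = x.size
    ones = np.ones_like(x)
    best: tuple[float, float, np.ndarray, int] | None = None  # (ssr, tau, coef, n1)
    for tau in grid:
        left = x <= tau
        n1 = int(left.sum())
        if n1 < 2 or n - n1 < 2:
            logger.debug("skipping breakpoint %.3f: segment sizes %d/%d", tau, n1, n - n1)
            continue
        if continuity_mode == "continuous":
            X = np.column_stack([ones, x, np.maximum(x - tau, 0.0)])
            coef, ssr = _wls(X, y, w)
        else:
            cl, sl = _wls(np.column_stack([ones[left], x[left]]), y[left], w[left])
            cr, sr = _wls(np.column_stack([ones[~left], x[~left]]), y[~left], w[~left])
            coef, ssr = np.r_[cl, cr], sl + sr
        if best is None or ssr < best[0] - 0.0:
            best = (ssr, float(tau), coef, n1)
    if best is None:
        raise NoValidBreakpointError("no grid candidate leaves >= 2 points per segment")

    ssr, tau, coef, n1 = best
    if continuity_mode == "continuous":
        a, b1, b2 = coef
        alpha1, beta1 = float(a), float(b1)
        alpha2, beta2 = float(a - b2 * tau), float(b1 + b2)
        k_seg = 4  # a, b1, b2 and the breakpoint
    else:
        alpha1, beta1, alpha2, beta2 = map(float, coef)
        k_seg = 5

    lin_coef, lin_ssr = _wls(np.column_stack([ones, x]), y, w)
    rms = float(np.sqrt(np.mean(y**2)))
    floor = n * (1e-10 * max(1.0, rms)) ** 2
    return SegmentedFit(
        tau=tau,
        alpha1=alpha1,
        beta1=beta1,
        alpha2=alpha2,
        beta2=beta2,
        ssr=ssr,
        aic_segmented=_aic(ssr, n, k_seg, floor),
        aic_linear=_aic(lin_ssr, n, 2, floor),
        n1=n1,
        n=n,
        grid=grid,
        continuity_mode=continuity_mode,
        linear_coef=(float(lin_coef[0]), float(lin_coef[1])),
        x=x,
        y=y,
        w=w,
    )


def join_point_report(fit: SegmentedFit) -> dict:
    """Structured summary of the join-point analysis.

    Includes the coefficients of both segments, the AIC comparison with a
    single line, and a plot-ready table of fitted values for both models.
    """
    fitted_seg = fit.predict(fit.x)
    fitted_lin = fit.predict_linear(fit.x)
    table = {
        "x": fit.x.tolist(),
        "y": fit.y.tolist(),
        "w": fit.w.tolist(),
        "fitted_segmented": fitted_seg.tolist(),
        "fitted_linear": fitted_lin.tolist(),
    }
    return {
        "tau": fit.tau,
        "coefficients": {
            "alpha1": fit.alpha1,
            "beta1": fit.beta1,
            "alpha2": fit.alpha2,
            "beta2": fit.beta2,
        },
        "linear_coefficients": {"alpha": fit.linear_coef[0], "beta": fit.linear_coef[1]},
        "ssr": fit.ssr,
        "aic_segmented": fit.aic_segmented,
        "aic_linear": fit.aic_linear,
        "segmented_preferred": bool(fit.aic_segmented < fit.aic_linear),
        "n1": fit.n1,
        "n": fit.n,
        "continuity_mode": fit.continuity_mode,
        "fitted_table": table,
    }
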