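"""Quasi-Poisson fitting of the full daily-count model.

The linear predictor combines the exposure-lag cross-basis with the
standard time-series confounder set:

    log mu_t = intercept + crossbasis(T, lag) + RH_t
               + NS(day-of-year, 4) + NS(time, 3) + day-of-week

Relative humidity enters as a single linear column; the day-of-year spline
absorbs within-year seasonality not carried by temperature; the long-term
time spline absorbs trends (e.g. reporting drift); day-of-week is a
categorical with Monday as the reference level. Estimation is log-link
Poisson IRLS with Pearson-dispersion scaling of the covariance
(quasi-Poisson): point estimates are the Poisson MLE, standard errors are
inflated by sqrt(phi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .basis import CrossBasis, NaturalSpline, predict_cumulative
from .errors import AlignmentError, ConvergenceError, DegenerateFitError
from .series import DailySeries

__all__ = ["Design", "FittedDLNM", "build_design", "fit_quasipoisson", "find_mmt",
           "expected_counts", "design_for"]

logger = logging.getLogger(__name__)

DOW_REFERENCE = 0  # Monday


@dataclass
class Design:
    """Assembled regression design for the quasi-Poisson fit."""

    X: np.ndarray
    y: np.ndarray
    column_map: dict[str, slice]
    valid_index: np.ndarray
    doy_spline: NaturalSpline
    time_spline: NaturalSpline
    collinear: list[int]
    column_names: list[str]


@dataclass
class FittedDLNM:
    """Fitted model: coefficients, scaled covariance, and fit context.

    ``coef``/``vcov`` are indexed by the full design columns; columns
    dropped for collinearity carry zero coefficient and zero variance.
    The cross-basis and confounder splines are stored with frozen knots so
    the model can be evaluated on new (e.g. scenario-shifted) series.
    """

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    column_map: dict[str, slice]
    n_used: int
    qaic: float
    crossbasis: CrossBasis
    doy_spline: NaturalSpline
    time_spline: NaturalSpline
    dropped: list[int] = field(default_factory=list)
    mmt: float | None = None


def _doy_design(spline: NaturalSpline, doy: np.ndarray) -> np.ndarray:
    return spline.design(doy.astype(float))


def build_design(
    series: DailySeries,
    cb: CrossBasis,
    df_doy: int = 4,
    df_time: int = 3,
) -> Design:
    """Assemble intercept | cross-basis | RH | NS(doy) | NS(time) | DOW.

    Rows before ``cb.valid_from`` (incomplete lag history) are removed.
    Columns that are exactly collinear with earlier columns are flagged in
    ``collinear`` but kept in place so downstream indexing is stable.
    """
    if series.cases is None:
        raise AlignmentError("series must carry daily counts")
    if cb.matrix.shape[0] != len(series):
        raise AlignmentError(
            f"cross-basis has {cb.matrix.shape[0]} rows, series {len(series)} days"
        )
    valid = np.arange(cb.valid_from, len(series))
    doy = series.doy[valid]
    tindex = series.time_index[valid]
    doy_spline = NaturalSpline.from_data(doy.astype(float), df_doy)
    time_spline = NaturalSpline.from_data(tindex, df_time)

    blocks: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones((valid.size, 1))),
        ("crossbasis", cb.matrix[valid]),
        ("rh", series.rh[valid, None]),
        ("ns_doy", doy_spline.design(doy.astype(float))),
        ("ns_time", time_spline.design(tindex)),
        ("dow", _dow_dummies(series.dow[valid])),
    ]
    column_map: dict[str, slice] = {}
    names: list[str] = []
    start = 0
    for name, block in blocks:
        column_map[name] = slice(start, start + block.shape[1])
        names.extend(f"{name}[{i}]" for i in range(block.shape[1]))
        start += block.shape[1]
    X = np.hstack([b for _, b in blocks])
    collinear = _flag_collinear(X)
    if collinear:
        logger.warning("collinear design columns flagged: %s",
                       [names[i] for i in collinear])
    return Design(
        X=X,
        y=np.asarray(series.cases[valid], dtype=float),
        column_map=column_map,
        valid_index=valid,
        doy_spline=doy_spline,
        time_spline=time_spline,
        collinear=collinear,
        column_names=names,
    )


def _gammaln1p(y: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(y + 1.0)


def _newton_polish(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, tol: float = 1e-9, max_steps: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Drive the Poisson score equations to tight convergence.

    Returns the polished coefficients and the Fisher information X'WX at
    the solution.
    """
    info = None
    for _ in range(max_steps):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        info = (X * mu[:, None]).T @ X
        if np.linalg.norm(score) < max(1e-7, tol * np.linalg.norm(X.T @ y) * 1e-3):
            break
        beta = beta + np.linalg.solve(info, score)
    else:
        mu = np.exp(X @ beta)
        info = (X * mu[:, None]).T @ X
    return beta, info


def _dow_dummies(dow: np.ndarray) -> np.ndarray:
    """Six indicator columns, Monday (0) as the reference level."""
    levels = [d for d in range(7) if d != DOW_REFERENCE]
    return np.column_stack([(dow == d).astype(float) for d in levels])


def _flag_collinear(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Flag columns (in order) that add no rank to the preceding ones."""
    n, p = X.shape
    Q = np.empty((n, p))
    k = 0
    flagged: list[int] = []
    for j in range(p):
        col = X[:, j].astype(float)
        scale = np.linalg.norm(col)
        if scale == 0:
            flagged.append(j)
            continue
        v = col / scale
        if k:
            v = v - Q[:, :k] @ (Q[:, :k].T @ v)
            # second pass for numerical safety
            v = v - Q[:, :k] @ (Q[:, :k].T @ v)
        nrm = np.linalg.norm(v)
        if nrm < tol:
            flagged.append(j)
        else:
            Q[:, k] = v / nrm
            k += 1
    return flagged


def fit_quasipoisson(design: Design, cb: CrossBasis) -> FittedDLNM:
    """Fit by IRLS; covariance scaled by the Pearson dispersion.

    Collinear-flagged columns are excluded from the solve and reported with
    zero coefficient/variance at their original positions. Reports
    qAIC = -2 loglik / phi + 2p.
    """
    y = design.y
    if np.ptp(y) == 0:
        raise DegenerateFitError("response has zero variance")
    keep = np.setdiff1d(np.arange(design.X.shape[1]), design.collinear)
    Xf = design.X[:, keep]
    model = sm.GLM(y, Xf, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-9, scale="X2")
    if not getattr(res, "converged", True):
        raise ConvergenceError("IRLS did not converge within 100 iterations")
    beta, info = _newton_polish(Xf, y, np.asarray(res.params))
    p = Xf.shape[1]
    n = y.size
    mu = np.exp(Xf @ beta)
    phi = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    coef = np.zeros(design.X.shape[1])
    vcov = np.zeros((design.X.shape[1], design.X.shape[1]))
    coef[keep] = beta
    vcov[np.ix_(keep, keep)] = phi * np.linalg.inv(info)
    llf = float(np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu - _gammaln1p(y)))
    qaic = float(-2.0 * llf / phi + 2 * p)
    return FittedDLNM(
        coef=coef,
        vcov=vcov,
        dispersion=phi,
        column_map=design.column_map,
        n_used=len(y),
        qaic=qaic,
        crossbasis=cb,
        doy_spline=design.doy_spline,
        time_spline=design.time_spline,
        dropped=list(design.collinear),
    )


def design_for(fit: FittedDLNM, series: DailySeries) -> tuple[np.ndarray, np.ndarray]:
    """Design rows for a new series using the fit's frozen bases.

    Returns ``(X, valid_index)``. The series must have the same length and
    calendar as the fitted one (projection shifts temperature only).
    """
    cbm = fit.crossbasis.rebuild(series.tmean)
    valid = np.arange(fit.crossbasis.valid_from, len(series))
    doy = series.doy[valid].astype(float)
    tindex = series.time_index[valid]
    X = np.hstack(
        [
            np.ones((valid.size, 1)),
            cbm[valid],
            series.rh[valid, None],
            fit.doy_spline.design(doy),
            fit.time_spline.design(tindex),
            _dow_dummies(series.dow[valid]),
        ]
    )
    return X, valid


def expected_counts(fit: FittedDLNM, series: DailySeries,
                    coef: np.ndarray | None = None) -> np.ndarray:
    """Model-expected daily counts on (possibly shifted) ``series``.

    Length matches the series; days without full lag history are NaN.
    """
    X, valid = design_for(fit, series)
    beta = fit.coef if coef is None else coef
    mu = np.full(len(series), np.nan)
    mu[valid] = np.exp(X @ beta)
    return mu


def find_mmt(
    fit: FittedDLNM,
    search_range: tuple[float, float] | None = None,
    step: float = 0.1,
) -> float:
    """Minimal morbidity temperature: argmin of the cumulative RR curve.

    Searched on a fixed-step grid over ``search_range`` (default the
    1st-99th percentile of the temperatures the model was built on); ties
    break toward the lower temperature. The result is stored on the fit.
    """
    cb = fit.crossbasis
    if search_range is None:
        lo, hi = np.percentile(cb.temps, [1.0, 99.0])
    else:
        lo, hi = search_range
    grid = np.arange(lo, hi + step / 2, step)
    curve = predict_cumulative(fit, cb, grid, reference=float(grid[0]))
    mmt = float(grid[int(np.argmin(curve.log_rr))])
    fit.mmt = mmt
    return mmt
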