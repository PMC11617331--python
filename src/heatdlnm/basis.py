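"""Exposure-lag cross-basis: natural cubic spline × lag polynomial.

A distributed-lag nonlinear model represents the effect of temperature on
day-t counts as a bilinear expansion over an exposure basis (natural cubic
spline in temperature, dimension ``df_var``) and a lag basis (polynomial in
lag 0..lag_max, dimension ``df_lag``). The realized design block has one
column per (exposure, lag) basis pair:

    CB[t, j*df_lag + k] = sum_l  B_var_j(T_{t-l}) * B_lag_k(l)

Fitted coefficients on this block are turned back into interpretable
quantities by the prediction helpers: the cumulative exposure-response
curve (lag-summed log relative risk against a reference temperature), the
lag-response profile at a fixed temperature, and the full
temperature × lag surface.

The natural spline follows the standard regression-spline construction:
cubic B-splines on the augmented knot sequence, projected onto the
subspace with zero second derivative at the boundary knots, intercept
column removed. With ``df`` basis columns there are ``df - 1`` internal
knots, placed at equally spaced quantiles of the data when not supplied.
Beyond the boundary knots every basis function continues linearly (value
and first derivative matched at the boundary), which is what makes
projection under large warming scenarios well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import qr

from .errors import InsufficientHistoryError, InvalidConfigError, InvalidKnotsError

__all__ = [
    "NaturalSpline",
    "ns_basis",
    "poly_basis",
    "CrossBasisSpec",
    "CrossBasis",
    "build_crossbasis",
    "ExposureResponseCurve",
    "LagResponse",
    "predict_cumulative",
    "predict_lag_response",
    "predict_surface",
]


class NaturalSpline:
    """Natural cubic spline basis with frozen knots, linear beyond boundary."""

    def __init__(self, internal_knots, boundary) -> None:
        internal = np.asarray(internal_knots, dtype=float)
        b0, b1 = float(boundary[0]), float(boundary[1])
        if b0 >= b1:
            raise InvalidKnotsError("boundary knots must be increasing")
        allk = np.r_[b0, np.sort(internal), b1]
        if np.unique(allk).size != allk.size:
            raise InvalidKnotsError(f"duplicate knots in {allk}")
        if internal.size and (internal.min() <= b0 or internal.max() >= b1):
            raise InvalidKnotsError("internal knots must lie strictly inside the boundary")
        self.internal = np.sort(internal)
        self.boundary = (b0, b1)
        self._t = np.r_[[b0] * 4, self.internal, [b1] * 4]
        nb = self.internal.size + 4

        # second-derivative values of each B-spline at the two boundaries
        d2 = np.empty((2, nb))
        for i in range(nb):
            c = np.zeros(nb)
            c[i] = 1.0
            d2[:, i] = BSpline(self._t, c, 3).derivative(2)(np.array([b0, b1]))
        d2 = d2[:, 1:]  # drop the intercept-carrying first B-spline
        Q, _ = qr(d2.T)
        self._transform = Q[:, 2:]  # (nb-1, nb-3)
        self.df = nb - 3

        bpts = np.array([b0, b1])
        self._edge_val = self._eval_inner(bpts)  # (2, df)
        self._edge_deriv = np.empty((2, self.df))
        for j in range(self.df):
            c = np.r_[0.0, self._transform[:, j]]
            self._edge_deriv[:, j] = BSpline(self._t, c, 3).derivative(1)(bpts)

    @classmethod
    def from_data(
        cls, x, df: int, knots=None, boundary=None
    ) -> "NaturalSpline":
        """Knots at equally spaced quantiles of ``x``; boundary at min/max."""
        x = np.asarray(x, dtype=float)
        if df < 2:
            raise InvalidConfigError("natural spline needs df >= 2")
        if boundary is None:
            boundary = (float(x.min()), float(x.max()))
        if knots is None:
            nk = df - 1
            probs = np.arange(1, nk + 1) / (nk + 1)
            knots = np.quantile(x, probs)
        return cls(knots, boundary)

    def _eval_inner(self, x: np.ndarray) -> np.ndarray:
        B = BSpline.design_matrix(x, self._t, 3).toarray()
        return B[:, 1:] @ self._transform

    def design(self, x) -> np.ndarray:
        """Evaluate the df basis columns at ``x``, extrapolating linearly."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.isfinite(x).all():
            raise InvalidConfigError("spline input must be finite")
        b0, b1 = self.boundary
        out = np.empty((x.size, self.df))
        inside = (x >= b0) & (x <= b1)
        if inside.any():
            out[inside] = self._eval_inner(x[inside])
        below = x < b0
        if below.any():
            out[below] = self._edge_val[0] + np.outer(x[below] - b0, self._edge_deriv[0])
        above = x > b1
        if above.any():
            out[above] = self._edge_val[1] + np.outer(x[above] - b1, self._edge_deriv[1])
        return out

    __call__ = design


def ns_basis(x, df: int, knots=None, boundary=None) -> np.ndarray:
    """Natural cubic spline design matrix (no intercept column)."""
    return NaturalSpline.from_data(x, df, knots=knots, boundary=boundary).design(x)


def poly_basis(lags, df: int, lag_max: int | None = None) -> np.ndarray:
    """Polynomial lag basis: powers 0..df-1 of lag rescaled to [0, 1].

    The constant column lets the lag profile carry an immediate (lag-0)
    effect. Raises if ``df`` exceeds the number of distinct lags.
    """
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if lag_max is None:
        lag_max = int(lags.max()) if lags.size else 0
    if df < 1:
        raise InvalidConfigError("lag basis needs df >= 1")
    if df > lag_max + 1:
        raise InvalidConfigError(
            f"lag polynomial df={df} exceeds the {lag_max + 1} available lags"
        )
    scaled = lags / max(lag_max, 1)
    return np.column_stack([scaled**p for p in range(df)])


@dataclass(frozen=True)
class CrossBasisSpec:
    """Dimensions and knot placement of the exposure-lag cross-basis."""

    lag_max: int = 7
    df_var: int = 5
    df_lag: int = 4
    var_knots: tuple[float, ...] | None = None
    var_boundary: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.df_var < 2 or self.df_lag < 1 or self.lag_max < 0:
            raise InvalidConfigError("need df_var >= 2, df_lag >= 1, lag_max >= 0")
        if self.df_lag > self.lag_max + 1:
            raise InvalidConfigError("df_lag cannot exceed lag_max + 1")
        if self.var_knots is not None and len(self.var_knots) != self.df_var - 1:
            raise InvalidConfigError(
                f"df_var={self.df_var} requires {self.df_var - 1} internal knots"
            )

    @property
    def n_columns(self) -> int:
        return self.df_var * self.df_lag


@dataclass
class CrossBasis:
    """Realized cross-basis: design block plus the frozen basis functions.

    Rows before ``valid_from`` lack a complete lag history and are filled
    with NaN; the fitting stage drops them. The exposure spline is frozen
    from the series it was built on, so predictions and rebuilds on new
    (e.g. scenario-shifted) series use identical knots.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    valid_from: int
    var_spline: NaturalSpline
    lag_matrix: np.ndarray  # (lag_max+1, df_lag)
    temps: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def rebuild(self, temps) -> np.ndarray:
        """Cross-basis rows for a new temperature series, frozen knots."""
        return _cb_matrix(np.asarray(temps, dtype=float), self.var_spline,
                          self.lag_matrix, self.spec.lag_max)

    def cum_vector(self, temps) -> np.ndarray:
        """Coefficient-contrast vector for constant exposure held over all lags.

        ``cum_vector(x) @ beta`` is the cumulative log-RR of sitting at
        temperature x for the whole lag window (relative to the basis
        origin; differences of these vectors give reference contrasts).
        """
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        Bv = self.var_spline.design(temps)  # (m, df_var)
        lag_sum = self.lag_matrix.sum(axis=0)  # (df_lag,)
        return np.einsum("mj,k->mjk", Bv, lag_sum).reshape(temps.size, -1)

    def lag_vector(self, temp: float, lags) -> np.ndarray:
        """Contrast rows for exposure ``temp`` acting at each requested lag."""
        lags = np.atleast_1d(np.asarray(lags, dtype=float))
        Bv = self.var_spline.design([float(temp)])[0]  # (df_var,)
        Bl = poly_basis(lags, self.spec.df_lag, lag_max=self.spec.lag_max)
        return np.einsum("j,mk->mjk", Bv, Bl).reshape(lags.size, -1)


def _cb_matrix(
    temps: np.ndarray, spline: NaturalSpline, lag_matrix: np.ndarray, lag_max: int
) -> np.ndarray:
    n = temps.size
    Bv = spline.design(temps)  # (n, df_var)
    df_var, df_lag = Bv.shape[1], lag_matrix.shape[1]
    out = np.full((n, df_var * df_lag), np.nan)
    # lagged exposure-basis stack: Q[t, l, :] = Bv at temp_{t-l}
    valid = np.arange(lag_max, n)
    acc = np.zeros((valid.size, df_var, df_lag))
    for l in range(lag_max + 1):
        acc += np.einsum("tj,k->tjk", Bv[valid - l], lag_matrix[l])
    out[valid] = acc.reshape(valid.size, -1)
    return out


def build_crossbasis(temps, spec: CrossBasisSpec | None = None) -> CrossBasis:
    """Construct the cross-basis for a temperature series.

    Exposure-spline knots come from the series quantiles (or from the spec
    when given) and are frozen on the returned object.
    """
    spec = spec or CrossBasisSpec()
    temps = np.asarray(temps, dtype=float)
    if temps.size <= spec.lag_max:
        raise InsufficientHistoryError(
            f"series of length {temps.size} cannot cover lag window {spec.lag_max}"
        )
    spline = NaturalSpline.from_data(
        temps, spec.df_var, knots=spec.var_knots, boundary=spec.var_boundary
    )
    lag_matrix = poly_basis(np.arange(spec.lag_max + 1), spec.df_lag, lag_max=spec.lag_max)
    matrix = _cb_matrix(temps, spline, lag_matrix, spec.lag_max)
    frozen = CrossBasisSpec(
        lag_max=spec.lag_max,
        df_var=spec.df_var,
        df_lag=spec.df_lag,
        var_knots=tuple(spline.internal.tolist()),
        var_boundary=spline.boundary,
    )
    return CrossBasis(
        matrix=matrix,
        spec=frozen,
        valid_from=spec.lag_max,
        var_spline=spline,
        lag_matrix=lag_matrix,
        temps=temps,
    )


@dataclass
class ExposureResponseCurve:
    """Cumulative log relative risk against a reference temperature."""

    temps: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def rr_ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return np.exp(self.log_rr - z * self.se), np.exp(self.log_rr + z * self.se)

    def to_frame(self):
        import pandas as pd

        lo, hi = self.rr_ci()
        return pd.DataFrame(
            {
                "temp": self.temps,
                "log_rr": self.log_rr,
                "se": self.se,
                "rr": self.rr,
                "rr_low": lo,
                "rr_high": hi,
            }
        )


@dataclass
class LagResponse:
    """Per-lag log relative risk for one temperature contrast."""

    lags: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    at_temp: float
    reference: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag": self.lags, "log_rr": self.log_rr, "se": self.se,
             "rr": np.exp(self.log_rr)}
        )


def predict_cumulative(fit, cb: CrossBasis, temp_grid, reference: float) -> ExposureResponseCurve:
    """Lag-cumulated log-RR curve over ``temp_grid`` anchored at ``reference``."""
    sl = fit.column_map["crossbasis"]
    beta, V = fit.coef[sl], fit.vcov[sl, sl]
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    C = cb.cum_vector(temp_grid) - cb.cum_vector(reference)
    log_rr = C @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))
    return ExposureResponseCurve(temp_grid, log_rr, se, float(reference))


def predict_lag_response(fit, cb: CrossBasis, at_temp: float, reference: float) -> LagResponse:
    """Log-RR of exposure ``at_temp`` (vs reference) decomposed by lag."""
    sl = fit.column_map["crossbasis"]
    beta, V = fit.coef[sl], fit.vcov[sl, sl]
    lags = np.arange(cb.spec.lag_max + 1)
    C = cb.lag_vector(at_temp, lags) - cb.lag_vector(reference, lags)
    log_rr = C @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))
    return LagResponse(lags, log_rr, se, float(at_temp), float(reference))


def predict_surface(fit, cb: CrossBasis, temp_grid, lag_grid, reference: float) -> np.ndarray:
    """Log-RR surface over (temperature, lag); rows index temperature."""
    sl = fit.column_map["crossbasis"]
    beta = fit.coef[sl]
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    lag_grid = np.atleast_1d(np.asarray(lag_grid, dtype=float))
    out = np.empty((temp_grid.size, lag_grid.size))
    ref_rows = cb.lag_vector(reference, lag_grid)
    for i, x in enumerate(temp_grid):
        out[i] = (cb.lag_vector(float(x), lag_grid) - ref_rows) @ beta
    return out
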