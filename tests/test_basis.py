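"""Cross-basis construction and prediction against brute-force oracles."""

import numpy as np
import pytest

from heatdlnm import (
    CrossBasisSpec,
    build_crossbasis,
    ns_basis,
    poly_basis,
    predict_cumulative,
    predict_lag_response,
    predict_surface,
)
from heatdlnm.basis import NaturalSpline
from heatdlnm.errors import InsufficientHistoryError, InvalidConfigError, InvalidKnotsError

# splines::ns(x, knots=c(2,5,8), Boundary.knots=c(0,10)) computed with R 4.3.3
_R_NS_X = np.array([0.5, 1.7, 3.1, 4.9, 6.2, 7.8, 9.4, 10.0, 2.5])
_R_NS_EXPECTED = np.array([
    [0.001562500000000, -0.045930015718330, 0.160755055014156, -0.114825039295826],
    [0.061412500000000, -0.129986318770086, 0.454952115695301, -0.324965796925215],
    [0.326172222222222, -0.121715394770160, 0.458354576140004, -0.327396125814288],
    [0.623772222222222, 0.115642476961767, 0.188039525078260, -0.134313946484471],
    [0.483400000000000, 0.425142975443619, 0.120749585947333, -0.069792561390952],
    [0.132822222222222, 0.597493601211435, 0.211966840204423, 0.057661780806365],
    [0.002700000000000, 0.142833333333333, 0.379833333333333, 0.474633333333333],
    [0.000000000000000, -0.128205128205128, 0.448717948717949, 0.679487179487180],
    [0.190972222222222, -0.142744886671492, 0.502645297794667, -0.359032355567619],
])


class TestNaturalSpline:
    def test_matches_reference_implementation(self):
        """Frozen oracle: R splines::ns on fixed knots and points."""
        B = NaturalSpline([2.0, 5.0, 8.0], (0.0, 10.0)).design(_R_NS_X)
        assert np.allclose(B, _R_NS_EXPECTED, atol=1e-12)

    def test_linear_beyond_boundary(self, rng):
        ns = NaturalSpline.from_data(rng.uniform(0, 10, 200), 5)
        for pts in (np.array([-3.0, -2.0, -1.0]), np.array([11.0, 12.0, 13.0])):
            vals = ns.design(pts)
            second_diff = vals[0] - 2 * vals[1] + vals[2]
            assert np.allclose(second_diff, 0.0, atol=1e-10)

    def test_df2_reproduces_straight_lines(self, rng):
        x = rng.uniform(0, 1, 300)
        B = ns_basis(x, 2)
        assert B.shape == (300, 2)
        X = np.column_stack([np.ones_like(x), B])
        y = 3.0 - 2.0 * x
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-10

    def test_deterministic(self, rng):
        x = rng.uniform(0, 10, 50)
        assert np.array_equal(ns_basis(x, 4), ns_basis(x, 4))

    def test_quantile_knot_count(self, rng):
        x = rng.uniform(0, 10, 500)
        ns = NaturalSpline.from_data(x, 5)
        assert ns.df == 5
        assert len(ns.internal) == 4
        assert np.allclose(ns.internal, np.quantile(x, [0.2, 0.4, 0.6, 0.8]))

    def test_duplicate_knots_rejected(self):
        with pytest.raises(InvalidKnotsError):
            NaturalSpline([2.0, 2.0, 8.0], (0.0, 10.0))


class TestPolyBasis:
    def test_df1_is_constant_column(self):
        B = poly_basis(np.arange(8), 1, lag_max=7)
        assert np.array_equal(B, np.ones((8, 1)))

    def test_full_rank(self):
        B = poly_basis(np.arange(8), 4, lag_max=7)
        assert B.shape == (8, 4)
        assert np.linalg.matrix_rank(B) == 4

    def test_lag_zero_row(self):
        B = poly_basis(np.arange(8), 4, lag_max=7)
        assert np.array_equal(B[0], [1.0, 0.0, 0.0, 0.0])

    def test_df_exceeding_lags_rejected(self):
        with pytest.raises(InvalidConfigError):
            poly_basis(np.arange(3), 4, lag_max=2)


def _oracle_cb_entry(temps, spline, lag_mat, lag_max, t, j, k):
    total = 0.0
    for l in range(lag_max + 1):
        total += spline.design([temps[t - l]])[0, j] * lag_mat[l, k]
    return total


class TestCrossBasis:
    def test_matches_double_loop_oracle(self, rng):
        temps = rng.uniform(10, 32, 50)
        spec = CrossBasisSpec(lag_max=4, df_var=3, df_lag=3)
        cb = build_crossbasis(temps, spec)
        for t in range(4, 50, 7):
            for j in range(3):
                for k in range(3):
                    want = _oracle_cb_entry(temps, cb.var_spline, cb.lag_matrix, 4, t, j, k)
                    assert cb.matrix[t, j * 3 + k] == pytest.approx(want, abs=1e-10)

    def test_constant_series_rows_identical(self):
        temps = np.full(30, 24.0)
        cb = build_crossbasis(temps, CrossBasisSpec(var_knots=(22.0, 23.0, 25.0, 26.0),
                                                    var_boundary=(20.0, 30.0)))
        valid = cb.matrix[cb.valid_from:]
        assert np.allclose(valid, valid[0], atol=1e-12)

    def test_invalid_rows_flagged(self, rng):
        cb = build_crossbasis(rng.uniform(10, 30, 40), CrossBasisSpec())
        assert np.isnan(cb.matrix[: cb.valid_from]).all()
        assert np.isfinite(cb.matrix[cb.valid_from:]).all()

    def test_lag_max_zero_collapses(self, rng):
        temps = rng.uniform(10, 30, 20)
        spec = CrossBasisSpec(lag_max=0, df_var=3, df_lag=1)
        cb = build_crossbasis(temps, spec)
        expected = cb.var_spline.design(temps)  # lag basis row at 0 is [1]
        assert np.allclose(cb.matrix, expected, atol=1e-12)

    def test_column_count(self, crossbasis):
        assert crossbasis.n_columns == 5 * 4

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientHistoryError):
            build_crossbasis(np.arange(5.0), CrossBasisSpec(lag_max=7))


class _NullFit:
    """Minimal fit carrying only a cross-basis coefficient block."""

    def __init__(self, ncols, coef=None, vcov=None):
        self.column_map = {"crossbasis": slice(0, ncols)}
        self.coef = np.zeros(ncols) if coef is None else coef
        self.vcov = np.zeros((ncols, ncols)) if vcov is None else vcov


@pytest.fixture(scope="module")
def cb():
    rng = np.random.default_rng(5)
    return build_crossbasis(rng.uniform(12, 32, 60), CrossBasisSpec())


@pytest.fixture(scope="module")
def fit(cb):
    rng = np.random.default_rng(6)
    n = cb.n_columns
    A = rng.normal(0, 0.05, (n, n))
    return _NullFit(n, coef=rng.normal(0, 0.1, n), vcov=A @ A.T)


class TestPredictions:
    def test_null_coefficients_flat_curve(self, cb):
        fit = _NullFit(cb.n_columns)
        curve = predict_cumulative(fit, cb, np.linspace(15, 30, 10), reference=20.0)
        assert np.all(curve.log_rr == 0.0)
        assert np.all(np.exp(curve.log_rr) == 1.0)

    def test_reference_point_anchored_at_zero(self, fit, cb):
        curve = predict_cumulative(fit, cb, [20.0, 25.0], reference=20.0)
        assert curve.log_rr[0] == 0.0
        assert curve.se[0] == 0.0

    def test_lag_sum_equals_cumulative(self, fit, cb):
        for temp in (18.0, 25.0, 30.0):
            lr = predict_lag_response(fit, cb, temp, reference=20.0)
            cum = predict_cumulative(fit, cb, [temp], reference=20.0)
            assert abs(lr.log_rr.sum() - cum.log_rr[0]) < 1e-10

    def test_lag_response_at_reference_is_zero(self, fit, cb):
        lr = predict_lag_response(fit, cb, 22.0, reference=22.0)
        assert np.all(lr.log_rr == 0.0)

    def test_surface_consistent_with_lag_slices(self, fit, cb):
        temps = np.array([18.0, 25.0, 30.0])
        lags = np.arange(cb.spec.lag_max + 1)
        surf = predict_surface(fit, cb, temps, lags, reference=20.0)
        for i, temp in enumerate(temps):
            lr = predict_lag_response(fit, cb, float(temp), reference=20.0)
            assert np.allclose(surf[i], lr.log_rr, atol=1e-10)

    def test_surface_zero_at_reference_temperature(self, fit, cb):
        surf = predict_surface(fit, cb, [20.0], np.arange(8), reference=20.0)
        assert np.allclose(surf, 0.0, atol=1e-14)

    def test_reference_invariance_of_curve_shape(self, fit, cb):
        grid = np.linspace(15, 30, 16)
        a = predict_cumulative(fit, cb, grid, reference=18.0).log_rr
        b = predict_cumulative(fit, cb, grid, reference=26.0).log_rr
        diff = a - b
        assert np.allclose(diff, diff[0], atol=1e-10)

    def test_cumulative_matches_loop_oracle(self, fit, cb):
        """Cumulative prediction equals an explicit sum over lags and columns."""
        beta = fit.coef
        for x in (16.0, 24.5, 31.0):
            total = 0.0
            for l in range(cb.spec.lag_max + 1):
                row_x = cb.lag_vector(x, [l])[0]
                row_r = cb.lag_vector(21.0, [l])[0]
                total += float((row_x - row_r) @ beta)
            got = predict_cumulative(fit, cb, [x], reference=21.0).log_rr[0]
            assert got == pytest.approx(total, abs=1e-10)
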