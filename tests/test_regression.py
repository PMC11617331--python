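"""Design assembly, quasi-Poisson estimation and MMT location."""

import numpy as np
import pandas as pd
import pytest

from heatdlnm import (
    DailySeries,
    SimConfig,
    build_crossbasis,
    build_design,
    expected_counts,
    find_mmt,
    fit_quasipoisson,
    predict_cumulative,
    simulate_weather,
)
from heatdlnm.errors import DegenerateFitError
from heatdlnm.regression import Design


class TestBuildDesign:
    def test_row_and_column_bookkeeping(self, series, crossbasis):
        d = build_design(series, crossbasis)
        assert d.X.shape[0] == len(series) - 7
        # intercept + 20 crossbasis + RH + NS(doy,4) + NS(time,3) + 6 DOW
        assert d.X.shape[1] == 1 + 20 + 1 + 4 + 3 + 6 == 35
        spans = sorted((s.start, s.stop) for s in d.column_map.values())
        assert spans[0][0] == 0 and spans[-1][1] == d.X.shape[1]
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_constant_humidity_flagged_collinear(self, crossbasis, series):
        s = DailySeries(series.dates, series.tmean, np.full(len(series), 75.0), series.cases)
        d = build_design(s, crossbasis)
        assert d.column_map["rh"].start in d.collinear

    def test_n_used_accounting(self, series, fitted):
        assert fitted.n_used + 7 == len(series)


class TestFitQuasipoisson:
    def test_intercept_only_closed_form(self):
        d = Design(
            X=np.ones((3, 1)), y=np.array([2.0, 4.0, 6.0]),
            column_map={"intercept": slice(0, 1)}, valid_index=np.arange(3),
            doy_spline=None, time_spline=None, collinear=[], column_names=["intercept"],
        )
        fit = fit_quasipoisson(d, None)
        assert fit.coef[0] == pytest.approx(np.log(4.0), abs=1e-9)

    def test_score_equations_satisfied(self, series, crossbasis, fitted):
        d = build_design(series, crossbasis)
        mu = np.exp(d.X @ fitted.coef)
        grad = d.X.T @ (d.y - mu)
        assert np.linalg.norm(grad) < 1e-6

    def test_vcov_symmetric_psd(self, fitted):
        v = fitted.vcov
        assert np.allclose(v, v.T, atol=1e-8)
        eigs = np.linalg.eigvalsh((v + v.T) / 2)
        assert eigs.min() > -1e-8 * max(eigs.max(), 1.0)

    def test_dispersion_positive_and_plausible(self, fitted, sim_config):
        assert fitted.dispersion > 0
        # generator uses dispersion 1.5; Pearson phi should land nearby
        assert 1.2 < fitted.dispersion < 1.9

    def test_zero_variance_response_rejected(self):
        d = Design(
            X=np.ones((4, 1)), y=np.full(4, 3.0),
            column_map={"intercept": slice(0, 1)}, valid_index=np.arange(4),
            doy_spline=None, time_spline=None, collinear=[], column_names=["intercept"],
        )
        with pytest.raises(DegenerateFitError):
            fit_quasipoisson(d, None)

    def test_time_shift_equivariance(self, surface):
        """Adding a constant to the time index leaves cross-basis coefficients alone."""
        from dataclasses import replace

        from heatdlnm import simulate_counts
        from heatdlnm.basis import NaturalSpline

        cfg = SimConfig(n_years=4, seed=77)
        s = simulate_counts(simulate_weather(cfg), surface, cfg)
        cb = build_crossbasis(s.tmean)
        d1 = build_design(s, cb)
        # rebuild the long-term spline block on a shifted time index
        tindex = s.time_index[d1.valid_index] + 1000.0
        shifted_spline = NaturalSpline.from_data(tindex, 3)
        X2 = d1.X.copy()
        X2[:, d1.column_map["ns_time"]] = shifted_spline.design(tindex)
        d2 = replace(d1, X=X2, time_spline=shifted_spline)
        f1 = fit_quasipoisson(d1, cb)
        f2 = fit_quasipoisson(d2, cb)
        sl = f1.column_map["crossbasis"]
        assert np.allclose(f1.coef[sl], f2.coef[sl], atol=1e-6)

    def test_within_model_class_recovery(self):
        """Estimator is consistent when the truth lies in the basis span.

        Counts are generated from a log mean built with the cross-basis
        itself, so the Poisson fit targets exactly the generating
        coefficients; the fitted cumulative contrast must cover the true
        contrast within its CI most of the time.
        """
        rng = np.random.default_rng(123)
        cfg = SimConfig(n_years=10, seed=321)
        w = simulate_weather(cfg)
        cb = build_crossbasis(w.tmean)
        ncb = cb.n_columns
        beta_true = rng.normal(0.0, 0.01, ncb)
        valid = np.arange(7, len(w))
        eta = np.log(2.0) + cb.matrix[valid] @ beta_true
        eta = eta - eta.mean() + np.log(3.0)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            counts = np.zeros(len(w))
            counts[valid] = np.random.default_rng(rep).poisson(np.exp(eta))
            s = DailySeries(w.dates, w.tmean, w.rh, counts)
            fit = fit_quasipoisson(build_design(s, cb), cb)
            c_hat = predict_cumulative(fit, cb, [28.0], reference=24.0)
            truth = float((cb.cum_vector([28.0]) - cb.cum_vector(24.0))[0] @ beta_true)
            if abs(c_hat.log_rr[0] - truth) <= 1.96 * c_hat.se[0]:
                hits += 1
        assert hits >= 16  # ~95% nominal, binomial slack at 20 reps


class TestFindMMT:
    def test_null_fit_ties_to_lower_bound(self, crossbasis):
        from heatdlnm.regression import FittedDLNM

        n = crossbasis.n_columns
        fit = FittedDLNM(
            coef=np.zeros(n), vcov=np.zeros((n, n)), dispersion=1.0,
            column_map={"crossbasis": slice(0, n)}, n_used=0, qaic=0.0,
            crossbasis=crossbasis, doy_spline=None, time_spline=None,
        )
        mmt = find_mmt(fit, search_range=(15.0, 25.0))
        assert mmt == 15.0

    def test_mmt_is_grid_argmin(self, fitted):
        mmt = find_mmt(fitted)
        lo, hi = np.percentile(fitted.crossbasis.temps, [1.0, 99.0])
        grid = np.arange(lo, hi + 0.05, 0.1)
        curve = predict_cumulative(fitted, fitted.crossbasis, grid, reference=float(grid[0]))
        at_mmt = predict_cumulative(fitted, fitted.crossbasis, [mmt], reference=float(grid[0]))
        assert at_mmt.log_rr[0] <= curve.log_rr.min() + 1e-12

    def test_mmt_below_threshold_on_hockey_stick_data(self, fitted, surface):
        # risk is flat below the true threshold, so the minimum should sit there
        assert fitted.mmt <= surface.threshold


class TestExpectedCounts:
    def test_matches_design_prediction(self, series, fitted):
        mu = expected_counts(fitted, series)
        assert np.isnan(mu[:7]).all()
        assert np.all(mu[7:] > 0)
        # total expected close to total observed (fit includes intercept)
        assert np.sum(mu[7:]) == pytest.approx(series.cases[7:].sum(), rel=0.01)
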