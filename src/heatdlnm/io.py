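"""Reading/writing daily series CSVs and serialized fitted models."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import CrossBasis, CrossBasisSpec, NaturalSpline, build_crossbasis, poly_basis
from .errors import SchemaError
from .regression import FittedDLNM
from .series import DailySeries

__all__ = ["read_daily_csv", "write_daily_csv", "model_to_json", "model_from_json"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("date", "cases", "tmean_c", "rh_pct")


def read_daily_csv(
    path, *, max_gap_days: int | None = None, return_report: bool = False
):
    """Load a daily surveillance CSV (date, cases, tmean_c, rh_pct).

    Dates are parsed ISO-8601 and sorted; duplicated dates are an error;
    calendar gaps are reported (and rejected beyond ``max_gap_days`` when
    set). Humidity outside [0, 100] is reported but not altered.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    try:
        dates = pd.to_datetime(frame["date"], format="%Y-%m-%d")
    except (ValueError, TypeError):
        bad = pd.to_datetime(frame["date"], format="%Y-%m-%d", errors="coerce")
        lines = (np.flatnonzero(bad.isna()) + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"{path}: unparseable date(s) at line(s) {lines[:10]}")
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated date {dup.date()}")
    order = np.argsort(dates.to_numpy(), kind="stable")
    frame = frame.iloc[order].reset_index(drop=True)
    dates = pd.DatetimeIndex(dates.iloc[order])

    gaps = []
    diffs = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
    for i in np.flatnonzero(diffs > 1):
        gaps.append({"after": str(dates[i].date()), "missing_days": int(diffs[i] - 1)})
    if max_gap_days is not None and any(g["missing_days"] > max_gap_days for g in gaps):
        raise SchemaError(f"{path}: calendar gap exceeds {max_gap_days} days: {gaps}")

    rh = frame["rh_pct"].to_numpy(float)
    rh_violations = int(((rh < 0) | (rh > 100)).sum())
    if rh_violations:
        logger.warning("%s: %d humidity values outside [0, 100]", path, rh_violations)
    cases_col = frame["cases"]
    cases = None if cases_col.isna().all() else cases_col.to_numpy()
    series = DailySeries(dates, frame["tmean_c"].to_numpy(float), rh, cases)
    report = {"n_days": len(series), "gaps": gaps, "rh_violations": rh_violations}
    if gaps:
        logger.info("%s: %d calendar gap(s): %s", path, len(gaps), gaps[:5])
    if return_report:
        return series, report
    return series


def write_daily_csv(series: DailySeries, path) -> None:
    frame = series.to_frame()
    if series.cases is not None:
        frame["cases"] = frame["cases"].astype(int)
    # %.17g keeps IEEE doubles bit-exact through the round trip
    frame.to_csv(path, index=False, float_format="%.17g")


def _spline_state(sp: NaturalSpline) -> dict:
    return {"internal": sp.internal.tolist(), "boundary": list(sp.boundary)}


def model_to_json(fit: FittedDLNM, path=None) -> str:
    """Serialize a fitted model (coefficients, covariance, frozen bases)."""
    cb = fit.crossbasis
    payload = {
        "coef": fit.coef.tolist(),
        "vcov": fit.vcov.tolist(),
        "dispersion": fit.dispersion,
        "column_map": {k: [v.start, v.stop] for k, v in fit.column_map.items()},
        "n_used": fit.n_used,
        "qaic": fit.qaic,
        "mmt": fit.mmt,
        "dropped": fit.dropped,
        "crossbasis": {
            "lag_max": cb.spec.lag_max,
            "df_var": cb.spec.df_var,
            "df_lag": cb.spec.df_lag,
            "var_spline": _spline_state(cb.var_spline),
            "temps": cb.temps.tolist(),
        },
        "doy_spline": _spline_state(fit.doy_spline),
        "time_spline": _spline_state(fit.time_spline),
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source) -> FittedDLNM:
    """Inverse of :func:`model_to_json`; accepts a path or a JSON string."""
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    d = json.loads(text)
    cbd = d["crossbasis"]
    spline = NaturalSpline(cbd["var_spline"]["internal"], cbd["var_spline"]["boundary"])
    spec = CrossBasisSpec(
        lag_max=cbd["lag_max"],
        df_var=cbd["df_var"],
        df_lag=cbd["df_lag"],
        var_knots=tuple(spline.internal.tolist()),
        var_boundary=spline.boundary,
    )
    temps = np.asarray(cbd["temps"], dtype=float)
    lag_matrix = poly_basis(np.arange(spec.lag_max + 1), spec.df_lag, lag_max=spec.lag_max)
    from .basis import _cb_matrix

    cb = CrossBasis(
        matrix=_cb_matrix(temps, spline, lag_matrix, spec.lag_max),
        spec=spec,
        valid_from=spec.lag_max,
        var_spline=spline,
        lag_matrix=lag_matrix,
        temps=temps,
    )
    return FittedDLNM(
        coef=np.asarray(d["coef"], dtype=float),
        vcov=np.asarray(d["vcov"], dtype=float),
        dispersion=d["dispersion"],
        column_map={k: slice(a, b) for k, (a, b) in d["column_map"].items()},
        n_used=d["n_used"],
        qaic=d["qaic"],
        crossbasis=cb,
        doy_spline=NaturalSpline(d["doy_spline"]["internal"], d["doy_spline"]["boundary"]),
        time_spline=NaturalSpline(d["time_spline"]["internal"], d["time_spline"]["boundary"]),
        dropped=list(d["dropped"]),
        mmt=d["mmt"],
    )
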