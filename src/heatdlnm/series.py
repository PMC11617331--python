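"""Daily surveillance series: aligned counts, temperature and humidity.

The whole pipeline operates on :class:`DailySeries` — one row per calendar
day, with daily mean temperature (°C), relative humidity (%) and, once
simulated or observed, the daily case count. Calendar covariates
(day-of-year, day-of-week, running time index) are derived from the date
index on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError

__all__ = ["DailySeries"]


@dataclass
class DailySeries:
    """Aligned daily vectors with calendar metadata.

    Parameters
    ----------
    dates
        Strictly increasing, gap-free or gappy daily ``DatetimeIndex``.
    tmean
        Daily mean temperature in °C.
    rh
        Daily mean relative humidity in percent.
    cases
        Daily case counts; ``None`` until simulated or loaded.
    """

    dates: pd.DatetimeIndex
    tmean: np.ndarray
    rh: np.ndarray
    cases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.rh = np.asarray(self.rh, dtype=float)
        if self.cases is not None:
            self.cases = np.asarray(self.cases)
        n = len(self.dates)
        if n == 0:
            raise EmptyInputError("daily series must contain at least one day")
        if len(self.tmean) != n or len(self.rh) != n:
            raise AlignmentError(
                f"length mismatch: {n} dates, {len(self.tmean)} temperatures, "
                f"{len(self.rh)} humidity values"
            )
        if self.cases is not None and len(self.cases) != n:
            raise AlignmentError(
                f"length mismatch: {n} dates, {len(self.cases)} counts"
            )
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise AlignmentError("dates must be strictly increasing and unique")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def doy(self) -> np.ndarray:
        """Day of year, 1..366."""
        return self.dates.dayofyear.to_numpy()

    @property
    def dow(self) -> np.ndarray:
        """Day of week, 0 = Monday .. 6 = Sunday."""
        return self.dates.dayofweek.to_numpy()

    @property
    def time_index(self) -> np.ndarray:
        """Running day index 0..n-1 (long-term trend covariate)."""
        return np.arange(len(self), dtype=float)

    def with_cases(self, cases: np.ndarray) -> "DailySeries":
        return DailySeries(self.dates, self.tmean.copy(), self.rh.copy(), np.asarray(cases))

    def with_tmean(self, tmean: np.ndarray) -> "DailySeries":
        cases = None if self.cases is None else self.cases.copy()
        return DailySeries(self.dates, np.asarray(tmean, dtype=float), self.rh.copy(), cases)

    def between(self, start, end) -> "DailySeries":
        """Subset to dates in [start, end] inclusive."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise EmptyInputError(f"no days between {start} and {end}")
        cases = None if self.cases is None else self.cases[mask]
        return DailySeries(self.dates[mask], self.tmean[mask], self.rh[mask], cases)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with the canonical column names used on disk."""
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "cases": self.cases if self.cases is not None else np.full(len(self), np.nan),
                "tmean_c": self.tmean,
                "rh_pct": self.rh,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailySeries":
        dates = pd.DatetimeIndex(pd.to_datetime(frame["date"]))
        cases = None
        if "cases" in frame and not frame["cases"].isna().all():
            cases = frame["cases"].to_numpy()
        return cls(dates, frame["tmean_c"].to_numpy(float), frame["rh_pct"].to_numpy(float), cases)
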