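"""Environmental and individual covariates.

Two environmental regressors drive the analyses:

* the **winter temperature anomaly** — the mean temperature over the winter
  window (1 December through 28 February, Feb 29 always excluded) minus the
  long-term mean of that same window over a fixed climatological baseline
  (default winters 1981–2010).  Winters colder than the baseline get negative
  anomalies.  A winter is labelled by the calendar year of its December, so
  the first winter experienced by a cohort hatched in year *Y* is winter *Y*
  (Dec *Y* – Feb *Y*+1).

* the **prey abundance index** — small-mammal snap-trapping captures per 100
  trap nights.

Plus ``standardize`` for z-scoring individual covariates (fledging body
mass) over the exact sample entering a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "WinterRecord",
    "PreyRecord",
    "ClimateSeries",
    "winter_mean",
    "winter_anomaly",
    "prey_index",
    "standardize",
    "CoverageError",
]

_WINTER_MONTHS = (12, 1, 2)
_MONTH_WEIGHTS = {12: 31, 1: 31, 2: 28}  # Feb 29 excluded by definition
_WINTER_DAYS = sum(_MONTH_WEIGHTS.values())  # 90


class CoverageError(ValueError):
    """Raised when the climate series does not cover a requested window."""


@dataclass(frozen=True)
class WinterRecord:
    """One winter's mean temperature and its anomaly against the baseline."""

    winter_year: int  # calendar year of the December opening the winter
    mean_temp_c: float
    anomaly_c: float


@dataclass(frozen=True)
class PreyRecord:
    """One autumn's snap-trapping outcome and derived abundance index."""

    year: int
    captures: int
    trap_nights: int
    index: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", prey_index(self.captures, self.trap_nights))


class ClimateSeries:
    """A station temperature series at daily or monthly resolution.

    Parameters
    ----------
    records : DataFrame
        Columns ``date`` (parseable to datetime) and ``temp_c``.  Daily data
        carry one row per day; monthly data one row per month (any day-of-month
        stamp, conventionally the 1st).
    baseline_start, baseline_end : int
        First and last winter label of the climatological baseline.
    resolution : {"auto", "daily", "monthly"}
        "auto" infers monthly when no calendar month contains more than one
        observation.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        baseline_start: int = 1981,
        baseline_end: int = 2010,
        resolution: Literal["auto", "daily", "monthly"] = "auto",
    ):
        df = records.copy()
        if not {"date", "temp_c"} <= set(df.columns):
            raise ValueError("climate table needs columns 'date' and 'temp_c'")
        df["date"] = pd.to_datetime(df["date"])
        df = df.sort_values("date").reset_index(drop=True)
        if df["date"].duplicated().any():
            raise ValueError("duplicate dates in climate series")
        if resolution == "auto":
            per_month = df.groupby([df["date"].dt.year, df["date"].dt.month]).size()
            resolution = "monthly" if (per_month <= 1).all() else "daily"
        self.records = df
        self.resolution = resolution
        self.baseline_start = int(baseline_start)
        self.baseline_end = int(baseline_end)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ClimateSeries":
        return cls(pd.read_csv(path), **kwargs)

    # internal -------------------------------------------------------------
    def _winter_frame(self, winter_year: int) -> pd.DataFrame:
        d = self.records["date"]
        in_dec = (d.dt.year == winter_year) & (d.dt.month == 12)
        in_jf = (d.dt.year == winter_year + 1) & d.dt.month.isin((1, 2))
        sel = self.records[in_dec | in_jf]
        # Feb 29 never belongs to the window
        return sel[~((sel["date"].dt.month == 2) & (sel["date"].dt.day == 29))]

    def winter_mean(self, winter_year: int, max_missing_days: int = 0) -> float:
        """Mean temperature over Dec 1 (winter_year) – Feb 28 (winter_year+1)."""
        win = self._winter_frame(winter_year)
        if self.resolution == "daily":
            n = len(win)
            if n < _WINTER_DAYS - max_missing_days:
                missing = _WINTER_DAYS - n
                raise CoverageError(
                    f"winter {winter_year}: {missing} of {_WINTER_DAYS} days "
                    "missing from the daily climate series"
                )
            return float(win["temp_c"].mean())
        # monthly: require all three months, weight by month length
        months = dict(zip(win["date"].dt.month, win["temp_c"]))
        missing = [m for m in _WINTER_MONTHS if m not in months]
        if missing:
            raise CoverageError(
                f"winter {winter_year}: monthly series lacks month(s) {missing}"
            )
        num = sum(_MONTH_WEIGHTS[m] * months[m] for m in _WINTER_MONTHS)
        return float(num / _WINTER_DAYS)

    def baseline_mean(self, max_missing_days: int = 0) -> float:
        """Mean of winter means over the baseline winters."""
        means = [
            self.winter_mean(y, max_missing_days=max_missing_days)
            for y in range(self.baseline_start, self.baseline_end + 1)
        ]
        return float(np.mean(means))

    def winter_anomaly(self, winter_year: int, max_missing_days: int = 0) -> float:
        """Winter mean minus the baseline mean; negative = colder than average."""
        return self.winter_mean(winter_year, max_missing_days) - self.baseline_mean(
            max_missing_days
        )

    def winter_record(self, winter_year: int) -> WinterRecord:
        m = self.winter_mean(winter_year)
        return WinterRecord(winter_year, m, m - self.baseline_mean())

    def anomaly_table(self, years: list[int]) -> pd.DataFrame:
        """Covariate table with columns winter_year, mean_temp_c, anomaly_c."""
        base = self.baseline_mean()
        rows = []
        for y in years:
            m = self.winter_mean(y)
            rows.append({"winter_year": y, "mean_temp_c": m, "anomaly_c": m - base})
        return pd.DataFrame(rows)


def winter_mean(series: ClimateSeries, winter_year: int, **kwargs) -> float:
    """Functional alias for :meth:`ClimateSeries.winter_mean`."""
    return series.winter_mean(winter_year, **kwargs)


def winter_anomaly(series: ClimateSeries, winter_year: int, **kwargs) -> float:
    """Functional alias for :meth:`ClimateSeries.winter_anomaly`."""
    return series.winter_anomaly(winter_year, **kwargs)


def prey_index(captures: int, trap_nights: int) -> float:
    """Captures per 100 trap nights."""
    if trap_nights <= 0:
        raise ValueError(f"trap_nights must be positive (got {trap_nights})")
    if captures < 0:
        raise ValueError(f"captures must be non-negative (got {captures})")
    return 100.0 * captures / trap_nights


def standardize(values) -> np.ndarray:
    """Z-score a vector to zero mean and unit *sample* standard deviation.

    Standardization is always computed over the analysis sample actually
    entering a model, not over a larger parent table.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize needs a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
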