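"""Station temperature variability from high-frequency logger records.

A 15-min logger series is decomposed into diurnal anomalies — each reading
minus the mean of its calendar day — and the anomalies are aggregated into
a per-station, per-window variability statistic.  Mean temperature and its
variability are the two predictors that carry the calcification analysis;
the variability statistic is a proxy for the co-varying short-term
fluctuations of salinity, oxygen, pH and aragonite saturation in the fjord.

The canonical metric is the mean over qualifying days of the within-day
(population) standard deviation of the anomalies.  Two alternatives are
selectable: the mean daily range (max - min per day) and the pooled SD of
all anomalies in the window.  For a pure 24-h sinusoid of amplitude A the
closed forms are A/sqrt(2) (within-day SD) and 2A (daily range).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "VariabilityStat",
    "SeasonCalendar",
    "DEFAULT_SEASONS",
    "diurnal_anomalies",
    "variability_metric",
    "window_summaries",
    "METRICS",
]

#: expected samples per day at the nominal 15-min logging interval
SAMPLES_PER_DAY = 96

#: minimum fraction of expected samples for a day to qualify
DAY_COVERAGE_THRESHOLD = 0.8

METRICS = ("mean_daily_sd", "daily_range", "pooled_sd")


@dataclass
class TemperatureSeries:
    """One station's logger record: strictly increasing timestamps, degC values.

    Timestamps are interpreted as local time; an optional ``utc_offset_hours``
    shifts UTC-stamped input into local time before calendar days are formed
    (diurnal means a local solar day).
    """

    station_id: str
    depth: float
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if len(self.timestamps) == 0:
            raise ValueError("empty temperature series")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if np.nanmin(self.values) <= -2.0 or np.nanmax(self.values) >= 40.0:
            raise ValueError("temperatures outside (-2, 40) degC")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temp_C": self.values}, index=self.timestamps)


@dataclass(frozen=True)
class VariabilityStat:
    """Mean temperature and variability of one station over one window."""

    station_id: str
    window: str
    mean_temperature: float
    variability: float
    metric_name: str
    n_days: int

    def __post_init__(self) -> None:
        if self.variability < 0:
            raise ValueError("variability must be >= 0")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")


@dataclass(frozen=True)
class SeasonCalendar:
    """Named windows with [start, end) date boundaries."""

    windows: tuple[tuple[str, str, str], ...]  # (label, start, end) ISO dates

    def bounds(self, label: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        for name, start, end in self.windows:
            if name == label:
                return pd.Timestamp(start), pd.Timestamp(end)
        raise KeyError(f"unknown window {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.windows)


#: growth periods of the field year: austral summer (Sep-Jan), autumn
#: (Jan-May) and winter (May-Aug), bounded by the seasonal sampling campaigns
DEFAULT_SEASONS = SeasonCalendar(
    windows=(
        ("summer", "2016-09-15", "2017-01-15"),
        ("autumn", "2017-01-15", "2017-05-15"),
        ("winter", "2017-05-15", "2017-08-15"),
    )
)


def _qualifying_days(frame: pd.DataFrame, min_coverage: float) -> pd.Series:
    counts = frame.groupby(frame.index.normalize()).size()
    return counts[counts >= min_coverage * SAMPLES_PER_DAY].index


def diurnal_anomalies(
    series: TemperatureSeries,
    utc_offset_hours: float = 0.0,
    min_coverage: float = DAY_COVERAGE_THRESHOLD,
) -> pd.Series:
    """Anomalies a(t) = T(t) - daily mean, on qualifying calendar days.

    Days with fewer than ``min_coverage`` of the expected 96 samples are
    dropped.  For a complete day the anomalies average to zero.
    """
    frame = series.to_frame()
    if utc_offset_hours:
        frame.index = frame.index + pd.Timedelta(hours=utc_offset_hours)
    days = frame.index.normalize()
    keep = days.isin(_qualifying_days(frame, min_coverage))
    frame = frame[keep]
    if frame.empty:
        raise ValueError(f"station {series.station_id}: no qualifying days")
    daily_mean = frame.groupby(frame.index.normalize())["temp_C"].transform("mean")
    anom = frame["temp_C"] - daily_mean
    anom.name = "anomaly_C"
    return anom


def variability_metric(
    anomalies: pd.Series,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    metric: str = "mean_daily_sd",
    station_id: str = "",
    window_label: str = "annual",
    temperatures: pd.Series | None = None,
) -> VariabilityStat:
    """Aggregate diurnal anomalies into one variability number for a window.

    ``metric`` selects the statistic: ``mean_daily_sd`` (canonical),
    ``daily_range`` or ``pooled_sd``.  ``temperatures`` (raw series aligned
    like the anomalies) supplies the window mean temperature; if omitted the
    mean temperature is reported as NaN.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    a = anomalies
    if window is not None:
        start, end = window
        a = a[(a.index >= start) & (a.index < end)]
    if a.empty:
        raise ValueError(f"no qualifying days in window {window_label!r}")
    by_day = a.groupby(a.index.normalize())
    if metric == "mean_daily_sd":
        value = float(by_day.apply(lambda x: float(np.std(x, ddof=0))).mean())
    elif metric == "daily_range":
        value = float((by_day.max() - by_day.min()).mean())
    else:  # pooled_sd
        value = float(np.std(a.to_numpy(), ddof=0))
    mean_t = float("nan")
    if temperatures is not None:
        t = temperatures
        if window is not None:
            t = t[(t.index >= window[0]) & (t.index < window[1])]
        mean_t = float(t.mean())
    return VariabilityStat(
        station_id=station_id,
        window=window_label,
        mean_temperature=mean_t,
        variability=value,
        metric_name=metric,
        n_days=int(by_day.ngroups),
    )


def window_summaries(
    series: TemperatureSeries,
    calendar: SeasonCalendar = DEFAULT_SEASONS,
    utc_offset_hours: float = 0.0,
    min_coverage: float = DAY_COVERAGE_THRESHOLD,
) -> pd.DataFrame:
    """Per-window mean, SD, maximum and maximum daily range of temperature.

    Returns one row per calendar window plus an ``annual`` row spanning the
    whole record.  Windows that do not intersect the series yield a row of
    NaNs with ``n_days = 0``.
    """
    frame = series.to_frame()
    if utc_offset_hours:
        frame.index = frame.index + pd.Timedelta(hours=utc_offset_hours)
    keep = frame.index.normalize().isin(_qualifying_days(frame, min_coverage))
    frame = frame[keep]

    rows = []
    spans = list(calendar.windows) + [
        ("annual", str(frame.index.min().date()), str((frame.index.max() + pd.Timedelta(days=1)).date()))
    ]
    for label, start, end in spans:
        sel = frame[(frame.index >= pd.Timestamp(start)) & (frame.index < pd.Timestamp(end))]
        if sel.empty:
            rows.append(
                {
                    "station_id": series.station_id,
                    "window": label,
                    "mean_C": np.nan,
                    "sd_C": np.nan,
                    "max_C": np.nan,
                    "max_daily_range_C": np.nan,
                    "n_days": 0,
                }
            )
            continue
        by_day = sel.groupby(sel.index.normalize())["temp_C"]
        rows.append(
            {
                "station_id": series.station_id,
                "window": label,
                "mean_C": float(sel["temp_C"].mean()),
                "sd_C": float(sel["temp_C"].std(ddof=0)),
                "max_C": float(sel["temp_C"].max()),
                "max_daily_range_C": float((by_day.max() - by_day.min()).max()),
                "n_days": int(by_day.ngroups),
            }
        )
    return pd.DataFrame(rows)
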