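"""Hourly feature engineering from minute-level and nightly wearable streams.

Waking-hour streams (heart rate, steps) are aggregated into clock-aligned,
half-open one-hour steps ``[h:00, h+1:00)``. Sleep-period streams (SpO2, HRV,
breathing rate, sleep quality) are aggregated per night and broadcast onto
every hour of the *previous* calendar day, so that a night's physiology can be
related to that day's substance use. Missing hours keep NaN markers; nothing
is imputed here.

The dominant frequency of a windowed signal is the DFT index
``k in 1..floor(N/2)`` with the largest magnitude ``|sum_n x(n) e^{-i2πkn/N}|``
— an integer number of cycles per window, capturing its strongest periodic
component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "dominant_frequency",
    "aggregate_hr_hourly",
    "aggregate_steps_hourly",
    "spo2_daily_features",
    "sleep_daily_features",
    "assemble_feature_matrix",
]

#: Canonical column order of the assembled feature matrix.
FEATURE_COLUMNS = [
    "hr_mean", "hr_sd", "hr_max", "hr_domfreq",
    "steps_avg", "steps_max", "active_minutes",
    "spo2_mean", "spo2_domfreq", "spo2_minutes_below90", "hypoxemia_flag",
    "br_deep", "br_rem", "br_light", "br_full",
    "sleep_efficiency", "sleep_total_minutes", "minutes_awake", "sleep_onset_minutes",
    "hrv_rmssd", "hrv_lf", "hrv_hf", "hrv_lh_ratio", "hrv_coverage",
]

_MAG_TOL = 1e-9


def dominant_frequency(x) -> float:
    """Dominant non-zero DFT index of a 1-D signal, in cycles per window.

    Ties break toward the smallest index; a flat signal (all non-zero-bin
    magnitudes below 1e-9) returns 0. Returns NaN for signals shorter than 2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return np.nan
    mags = np.abs(np.fft.rfft(x))[1 : n // 2 + 1]
    if mags.size == 0 or np.all(mags < _MAG_TOL):
        return 0.0
    return float(np.argmax(mags) + 1)


def _hour_groups(df: pd.DataFrame) -> "pd.core.groupby.DataFrameGroupBy":
    return df.groupby(df["timestamp"].dt.floor("h"))


def aggregate_hr_hourly(hr_minutes: pd.DataFrame) -> pd.DataFrame:
    """Mean, population SD, max and dominant frequency of heart rate per hour."""
    if hr_minutes.empty:
        return pd.DataFrame(columns=["hr_mean", "hr_sd", "hr_max", "hr_domfreq"])
    out = _hour_groups(hr_minutes)["bpm"].agg(
        hr_mean="mean",
        hr_sd=lambda v: float(np.std(v.to_numpy(), ddof=0)),
        hr_max="max",
        hr_domfreq=lambda v: dominant_frequency(v.to_numpy()),
    )
    out.index.name = "hour"
    return out


def aggregate_steps_hourly(step_minutes: pd.DataFrame) -> pd.DataFrame:
    """Mean and max step count plus active minutes (steps > 0) per hour."""
    if step_minutes.empty:
        return pd.DataFrame(columns=["steps_avg", "steps_max", "active_minutes"])
    out = _hour_groups(step_minutes)["steps"].agg(
        steps_avg="mean",
        steps_max="max",
        active_minutes=lambda v: int((v.to_numpy() > 0).sum()),
    )
    out.index.name = "hour"
    return out


def _night_key(timestamps: pd.Series) -> pd.Series:
    """Calendar date on which a sleep period ends.

    Shifting by 12 h groups pre-midnight minutes of a typical night
    (23:00-07:00) together with the following morning.
    """
    return (timestamps + pd.Timedelta(hours=12)).dt.normalize()


def spo2_daily_features(spo2_minutes: pd.DataFrame) -> pd.DataFrame:
    """Per-night SpO2 aggregates, keyed by the date the sleep period ends.

    Columns: mean SpO2, dominant frequency over the night's minute sequence,
    minutes strictly below 90% (potential hypoxemia) and a night-level flag
    set when any such minute exists.
    """
    cols = ["spo2_mean", "spo2_domfreq", "spo2_minutes_below90", "hypoxemia_flag"]
    if spo2_minutes.empty:
        return pd.DataFrame(columns=cols)
    grouped = spo2_minutes.groupby(_night_key(spo2_minutes["timestamp"]))["spo2"]
    out = grouped.agg(
        spo2_mean="mean",
        spo2_domfreq=lambda v: dominant_frequency(v.to_numpy()),
        spo2_minutes_below90=lambda v: int((v.to_numpy() < 90.0).sum()),
    )
    out["hypoxemia_flag"] = (out["spo2_minutes_below90"] > 0).astype(float)
    out.index.name = "night_end_date"
    return out


def _onset_minutes(onset: pd.Timestamp) -> float:
    """Sleep onset as signed minutes relative to midnight, continuous across
    it: 23:30 maps to -30, 00:45 to +45."""
    m = onset.hour * 60 + onset.minute
    return float(m - 1440 if m > 720 else m)


def sleep_daily_features(sleep_records: pd.DataFrame, hrv_minutes: pd.DataFrame) -> pd.DataFrame:
    """Per-night sleep and HRV aggregates, keyed by the night's end date.

    Multiple sleep cycles ending on the same date are averaged. The LF/HF
    ratio is the ratio of the night's mean LF to mean HF power (NaN when the
    HF mean is zero).
    """
    cols = [
        "br_deep", "br_rem", "br_light", "br_full",
        "sleep_efficiency", "sleep_total_minutes", "minutes_awake", "sleep_onset_minutes",
        "hrv_rmssd", "hrv_lf", "hrv_hf", "hrv_lh_ratio", "hrv_coverage",
    ]
    if sleep_records.empty:
        return pd.DataFrame(columns=cols)
    sleep = sleep_records.copy()
    sleep["night_end_date"] = _night_key(sleep["end_time"])
    sleep["sleep_onset_minutes"] = sleep["onset_time"].map(_onset_minutes)
    daily = sleep.groupby("night_end_date").agg(
        br_deep=("br_deep", "mean"),
        br_rem=("br_rem", "mean"),
        br_light=("br_light", "mean"),
        br_full=("br_full", "mean"),
        sleep_efficiency=("efficiency", "mean"),
        sleep_total_minutes=("total_minutes", "mean"),
        minutes_awake=("minutes_awake", "mean"),
        sleep_onset_minutes=("sleep_onset_minutes", "mean"),
    )
    if not hrv_minutes.empty:
        hrv = hrv_minutes.groupby(_night_key(hrv_minutes["timestamp"])).agg(
            hrv_rmssd=("rmssd", "mean"),
            hrv_lf=("lf", "mean"),
            hrv_hf=("hf", "mean"),
            hrv_coverage=("coverage", "mean"),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            hrv["hrv_lh_ratio"] = np.where(
                hrv["hrv_hf"].to_numpy() == 0.0, np.nan,
                hrv["hrv_lf"].to_numpy() / hrv["hrv_hf"].to_numpy(),
            )
        daily = daily.join(hrv, how="left")
    else:
        for c in ("hrv_rmssd", "hrv_lf", "hrv_hf", "hrv_lh_ratio", "hrv_coverage"):
            daily[c] = np.nan
    return daily[cols]


def assemble_feature_matrix(
    hr_hourly: pd.DataFrame,
    steps_hourly: pd.DataFrame,
    spo2_daily: pd.DataFrame,
    sleep_daily: pd.DataFrame,
    start: pd.Timestamp | None = None,
    periods: int | None = None,
) -> pd.DataFrame:
    """Assemble one hourly grid of all engineered features.

    Night-level aggregates (sleep, SpO2, HRV, BR) are broadcast as constants
    onto all 24 hours of the calendar day *preceding* the night's end date.
    ``start``/``periods`` fix the grid explicitly; when omitted they are
    inferred as whole days spanning the hourly inputs. Hours without source
    records stay NaN.
    """
    hourly_parts = [p for p in (hr_hourly, steps_hourly) if not p.empty]
    if start is None or periods is None:
        if not hourly_parts:
            return pd.DataFrame(columns=FEATURE_COLUMNS)
        lo = min(p.index.min() for p in hourly_parts).normalize()
        hi = max(p.index.max() for p in hourly_parts).normalize() + pd.Timedelta(days=1)
        start = lo
        periods = int((hi - lo) / pd.Timedelta(hours=1))
    grid = pd.date_range(start, periods=periods, freq="h")
    matrix = pd.DataFrame(index=grid, columns=FEATURE_COLUMNS, dtype=float)
    matrix.index.name = "hour_index"

    for part in (hr_hourly, steps_hourly):
        for col in part.columns:
            matrix[col] = part[col].reindex(grid)

    day_of_hour = grid.normalize()
    for daily in (spo2_daily, sleep_daily):
        if daily.empty:
            continue
        # previous calendar day of the night's end date
        shifted = daily.copy()
        shifted.index = pd.DatetimeIndex(shifted.index) - pd.Timedelta(days=1)
        for col in shifted.columns:
            matrix[col] = shifted[col].reindex(day_of_hour).to_numpy()
    return matrix
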