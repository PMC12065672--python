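"""Synthetic wearable streams and EMA logs for one study cohort.

Emulates the data a consumer wrist-worn tracker plus a smartphone EMA app
produce during a multi-week substance-use monitoring study:

* minute-level heart rate with a circadian sinusoid plus AR(1) noise;
* minute-level step counts organised as daytime activity bouts;
* one sleep record per night (efficiency, duration, minutes awake, onset,
  breathing rate by stage);
* minute-level SpO2 and HRV (RMSSD, LF, HF, coverage) during sleep periods;
* a ground-truth point process of use events, an EMA log derived from it with
  recall noise, and use-coupled physiological perturbations of controllable
  magnitude (``effect_size``), so that downstream detectors can be calibrated
  against a known signal (or its absence at ``effect_size=0``);
* contiguous non-wear gaps reproducing realistic wear-time fractions.

Everything is driven by a single integer seed; identical configurations yield
byte-identical CSV fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .labels import DEFAULT_EFFECT_DURATIONS

logger = logging.getLogger(__name__)

__all__ = [
    "EPOCH",
    "CohortConfig",
    "RawStreams",
    "GroundTruth",
    "ConfigError",
    "generate_participant",
    "inject_use_effects",
    "apply_missingness",
    "write_fixtures",
    "read_fixtures",
]

#: All synthetic monitoring periods start at this midnight.
EPOCH = pd.Timestamp("2024-01-01 00:00:00")

# Circadian heart-rate baseline: mean 70 bpm, amplitude 10 bpm, 24 h period,
# peaking at 16:00. AR(1) noise phi=0.8 with innovation SD 3 bpm.
HR_MEAN = 70.0
HR_AMPLITUDE = 10.0
HR_PEAK_HOUR = 16.0
HR_AR_PHI = 0.8
HR_AR_SIGMA = 3.0

#: Shift in mean heart rate per unit of effect size, in bpm.
HR_SHIFT_PER_EFFECT = 10.0

#: Non-wear gaps are at least this long, emulating device removal for
#: showers/swimming rather than isolated dropped samples.
MIN_GAP_MINUTES = 30
MAX_GAP_MINUTES = 240

WAKING_START_HOUR = 8   # use events occur between 08:00 and midnight
SLEEP_ONSET_HOUR = 23.5
SLEEP_END_HOUR = 7.0


class ConfigError(ValueError):
    """Invalid cohort or generator configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generation settings.

    Defaults mirror a four-week wearable monitoring study with roughly two
    use events per day and a 90% device wear fraction.
    """

    n_participants: int = 9
    monitoring_days: int = 28
    wear_fraction: float = 0.9
    substances: tuple[str, ...] = ("cannabis",)
    daily_use_rate: float = 2.0
    effect_size: float = 1.0
    rng_seed: int = 0
    #: Half-width (minutes) of the uniform EMA recall error; 0 disables it.
    ema_recall_minutes: float = 30.0
    #: Restrict use events to waking hours (08:00-24:00). Default off: with a
    #: circadian heart-rate baseline, diurnally concentrated events make the
    #: labels predictable from clock time alone, so a detector appears
    #: skillful even at effect_size=0. Uniform event timing keeps the
    #: zero-effect cohort a true null for calibration studies.
    waking_hours_only: bool = False
    durations: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_DURATIONS))

    def __post_init__(self):
        errs = self.validate()
        if errs:
            raise ConfigError("; ".join(errs))

    def validate(self) -> list[str]:
        errs = []
        if self.n_participants < 1:
            errs.append("n_participants must be >= 1")
        if self.monitoring_days < 2:
            errs.append("monitoring_days must be >= 2 (sleep maps to the previous day)")
        if not (0.0 < self.wear_fraction <= 1.0):
            errs.append("wear_fraction must be in (0, 1]")
        if self.daily_use_rate < 0:
            errs.append("daily_use_rate must be >= 0")
        if self.effect_size < 0:
            errs.append("effect_size must be >= 0")
        if self.ema_recall_minutes < 0:
            errs.append("ema_recall_minutes must be >= 0")
        for s in self.substances:
            if s.strip().lower() not in {k.lower() for k in self.durations}:
                errs.append(f"substance {s!r} has no entry in the duration table")
        return errs


@dataclass
class RawStreams:
    """Per-participant sensor streams.

    ``hr``/``steps``/``spo2`` are minute-level frames with a ``timestamp``
    column; ``hrv`` additionally carries rmssd/lf/hf/coverage; ``sleep`` has
    one row per sleep period.
    """

    hr: pd.DataFrame        # timestamp, bpm
    steps: pd.DataFrame     # timestamp, steps
    sleep: pd.DataFrame     # onset_time, end_time, efficiency, total_minutes,
                            # minutes_awake, br_deep, br_rem, br_light, br_full
    spo2: pd.DataFrame      # timestamp, spo2
    hrv: pd.DataFrame       # timestamp, rmssd, lf, hf, coverage

    def copy(self) -> "RawStreams":
        return RawStreams(
            self.hr.copy(), self.steps.copy(), self.sleep.copy(),
            self.spo2.copy(), self.hrv.copy(),
        )

    def equals(self, other: "RawStreams") -> bool:
        return (
            self.hr.equals(other.hr)
            and self.steps.equals(other.steps)
            and self.sleep.equals(other.sleep)
            and self.spo2.equals(other.spo2)
            and self.hrv.equals(other.hrv)
        )


@dataclass
class GroundTruth:
    """True use-event times and substances, before EMA recall noise."""

    events: pd.DataFrame  # use_time, substance

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# stream construction
# ---------------------------------------------------------------------------

def _circadian_hr(minutes: pd.DatetimeIndex, rng: np.random.Generator) -> np.ndarray:
    hours = (minutes - minutes[0]).total_seconds() / 3600.0 + minutes[0].hour
    baseline = HR_MEAN + HR_AMPLITUDE * np.cos(2 * np.pi * (hours - HR_PEAK_HOUR) / 24.0)
    eps = rng.normal(0.0, HR_AR_SIGMA, size=len(minutes))
    noise = lfilter([1.0], [1.0, -HR_AR_PHI], eps)
    return np.clip(baseline + noise, 35.0, 210.0)


def _sleep_periods(
    days: int, rng: np.random.Generator
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """One sleep period per night, onset late on day d, ending morning of d+1."""
    periods = []
    for d in range(days - 1):
        onset = (
            EPOCH
            + pd.Timedelta(days=d, hours=SLEEP_ONSET_HOUR)
            + pd.Timedelta(minutes=int(rng.integers(-45, 46)))
        ).floor("min")
        end = (
            EPOCH
            + pd.Timedelta(days=d + 1, hours=SLEEP_END_HOUR)
            + pd.Timedelta(minutes=int(rng.integers(-30, 31)))
        ).floor("min")
        periods.append((onset, end))
    return periods


def _steps_stream(
    minutes: pd.DatetimeIndex,
    periods: list[tuple[pd.Timestamp, pd.Timestamp]],
    rng: np.random.Generator,
) -> np.ndarray:
    steps = np.zeros(len(minutes), dtype=int)
    # low-level ambling during the day
    hrs = minutes.hour.to_numpy()
    day_mask = (hrs >= 8) & (hrs < 22)
    amble = rng.random(len(minutes)) < 0.05
    steps[day_mask & amble] = rng.poisson(8, size=int((day_mask & amble).sum()))
    # walking bouts
    n_days = (minutes[-1] - minutes[0]).days + 1
    t0 = minutes[0]
    for d in range(n_days):
        for _ in range(rng.poisson(6)):
            start_min = d * 1440 + int(rng.integers(8 * 60, 22 * 60))
            length = int(rng.integers(5, 41))
            lo = max(0, start_min)
            hi = min(len(minutes), start_min + length)
            if hi > lo:
                steps[lo:hi] = rng.poisson(70, size=hi - lo)
    # no steps while asleep
    asleep = np.zeros(len(minutes), dtype=bool)
    for onset, end in periods:
        asleep |= (minutes >= onset) & (minutes < end)
    steps[asleep] = 0
    del t0
    return steps


def _sleep_frame(
    periods: list[tuple[pd.Timestamp, pd.Timestamp]], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for onset, end in periods:
        period_minutes = (end - onset).total_seconds() / 60.0
        efficiency = float(np.clip(rng.normal(0.90, 0.04), 0.5, 0.99))
        total = efficiency * period_minutes
        br_full = float(rng.normal(15.0, 1.0))
        rows.append(
            {
                "onset_time": onset,
                "end_time": end,
                "efficiency": round(efficiency, 4),
                "total_minutes": round(total, 1),
                "minutes_awake": round(period_minutes - total, 1),
                "br_deep": round(br_full - 1.0 + rng.normal(0, 0.3), 2),
                "br_rem": round(br_full + 0.5 + rng.normal(0, 0.3), 2),
                "br_light": round(br_full + rng.normal(0, 0.3), 2),
                "br_full": round(br_full, 2),
            }
        )
    return pd.DataFrame(rows)


def _sleep_minute_streams(
    periods: list[tuple[pd.Timestamp, pd.Timestamp]], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    spo2_parts, hrv_parts = [], []
    for onset, end in periods:
        idx = pd.date_range(onset, end - pd.Timedelta(minutes=1), freq="min")
        n = len(idx)
        spo2 = 96.5 + rng.normal(0, 0.8, n)
        dips = rng.random(n) < 0.01
        spo2[dips] -= rng.uniform(3.0, 9.0, size=int(dips.sum()))
        spo2 = np.clip(spo2, 50.0, 100.0)
        spo2_parts.append(pd.DataFrame({"timestamp": idx, "spo2": np.round(spo2, 2)}))
        rmssd = np.clip(rng.normal(45.0, 8.0, n), 5.0, 250.0)
        lf = rng.lognormal(np.log(500.0), 0.4, n)
        hf = rng.lognormal(np.log(300.0), 0.4, n)
        coverage = np.clip(rng.normal(0.95, 0.04, n), 0.0, 1.0)
        hrv_parts.append(
            pd.DataFrame(
                {
                    "timestamp": idx,
                    "rmssd": np.round(rmssd, 2),
                    "lf": np.round(lf, 2),
                    "hf": np.round(hf, 2),
                    "coverage": np.round(coverage, 3),
                }
            )
        )
    empty_spo2 = pd.DataFrame(columns=["timestamp", "spo2"])
    empty_hrv = pd.DataFrame(columns=["timestamp", "rmssd", "lf", "hf", "coverage"])
    spo2 = pd.concat(spo2_parts, ignore_index=True) if spo2_parts else empty_spo2
    hrv = pd.concat(hrv_parts, ignore_index=True) if hrv_parts else empty_hrv
    return spo2, hrv


def _draw_events(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Homogeneous Poisson process of daily use events.

    Uniform over the full day by default; restricted to waking hours
    08:00-24:00 when ``waking_hours_only`` is set (see CohortConfig)."""
    start_minute = WAKING_START_HOUR * 60 if config.waking_hours_only else 0
    rows = []
    for d in range(config.monitoring_days):
        for _ in range(rng.poisson(config.daily_use_rate)):
            minute = int(rng.integers(start_minute, 24 * 60))
            t = EPOCH + pd.Timedelta(days=d, minutes=minute)
            substance = str(rng.choice(list(config.substances)))
            rows.append({"use_time": t, "substance": substance})
    df = pd.DataFrame(rows, columns=["use_time", "substance"])
    return df.sort_values("use_time", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# use-coupled perturbations
# ---------------------------------------------------------------------------

def inject_use_effects(
    streams: RawStreams,
    truth: GroundTruth,
    effect_size: float,
    duration_table: dict[str, int],
) -> RawStreams:
    """Superimpose use-coupled physiological perturbations onto clean streams.

    During each event's effect window (the substance's effect duration,
    starting at the event time) mean heart rate is shifted up by
    ``effect_size * 10`` bpm. On the night following an event day, minute
    RMSSD is scaled by ``1 - min(0.5, 0.05 * effect_size)`` and sleep
    efficiency reduced by ``min(0.2, 0.02 * effect_size)``. Overlapping
    effect windows do not stack: any minute inside at least one window gets
    exactly the single-event shift, and an affected night is perturbed once.
    Streams outside effect windows and non-following nights are untouched.
    """
    if effect_size < 0:
        raise ConfigError("effect_size must be >= 0")
    out = streams.copy()
    if effect_size == 0 or len(truth) == 0:
        return out

    ts = out.hr["timestamp"]
    t_min, t_max = ts.iloc[0], ts.iloc[-1]
    hr_mask = np.zeros(len(ts), dtype=bool)
    affected_days: set[pd.Timestamp] = set()
    for ev in truth.events.itertuples():
        d = int(duration_table[ev.substance.strip().lower()])
        if ev.use_time > t_max or ev.use_time + pd.Timedelta(hours=d) < t_min:
            logger.warning("Use event at %s lies outside the stream range; skipped", ev.use_time)
            continue
        hr_mask |= ((ts >= ev.use_time) & (ts < ev.use_time + pd.Timedelta(hours=d))).to_numpy()
        affected_days.add(ev.use_time.normalize())

    out.hr.loc[hr_mask, "bpm"] = out.hr.loc[hr_mask, "bpm"] + effect_size * HR_SHIFT_PER_EFFECT

    rmssd_factor = 1.0 - min(0.5, 0.05 * effect_size)
    eff_drop = min(0.2, 0.02 * effect_size)
    if not out.sleep.empty:
        night_day = out.sleep["onset_time"].dt.normalize()
        night_hit = night_day.isin(affected_days).to_numpy()
        out.sleep.loc[night_hit, "efficiency"] = np.clip(
            out.sleep.loc[night_hit, "efficiency"] - eff_drop, 0.0, 1.0
        )
        if not out.hrv.empty:
            hrv_hit = np.zeros(len(out.hrv), dtype=bool)
            for row in out.sleep.loc[night_hit].itertuples():
                hrv_hit |= (
                    (out.hrv["timestamp"] >= row.onset_time)
                    & (out.hrv["timestamp"] < row.end_time)
                ).to_numpy()
            out.hrv.loc[hrv_hit, "rmssd"] = out.hrv.loc[hrv_hit, "rmssd"] * rmssd_factor
    return out


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _gap_mask(n: int, target_remove: int, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping contiguous gaps (each >= MIN_GAP_MINUTES) totalling
    ~target_remove minutes, placed uniformly by distributing the free space."""
    mask = np.zeros(n, dtype=bool)
    if target_remove < MIN_GAP_MINUTES:
        return mask
    lengths: list[int] = []
    total = 0
    while total < target_remove:
        length = int(rng.integers(MIN_GAP_MINUTES, MAX_GAP_MINUTES + 1))
        if total + length > target_remove:
            length = target_remove - total
            if length < MIN_GAP_MINUTES:
                if lengths:
                    lengths[-1] += length  # fold the remainder into the last gap
                    total += length
                break
        lengths.append(length)
        total += length
    free = n - sum(lengths)
    if free < 0:  # extreme wear fractions; trim the last gaps
        while free < 0 and lengths:
            free += lengths.pop()
    k = len(lengths)
    if k == 0:
        return mask
    spacings = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    pos = 0
    for i, length in enumerate(lengths):
        pos += int(spacings[i])
        mask[pos : pos + length] = True
        pos += length
    return mask


def apply_missingness(
    streams: RawStreams, wear_fraction: float, rng: np.random.Generator
) -> RawStreams:
    """Remove contiguous non-wear gaps so the retained minute fraction of the
    HR/step streams is within ±2 percentage points of ``wear_fraction``; each
    sleep record (with its SpO2/HRV minutes) is independently dropped with
    probability ``1 - wear_fraction``."""
    if not (0.0 < wear_fraction <= 1.0):
        raise ConfigError("wear_fraction must be in (0, 1]")
    out = streams.copy()
    if wear_fraction == 1.0:
        return out
    n = len(out.hr)
    target_remove = int(round((1.0 - wear_fraction) * n))
    mask = _gap_mask(n, target_remove, rng)
    out.hr = out.hr.loc[~mask].reset_index(drop=True)
    out.steps = out.steps.loc[~mask].reset_index(drop=True)

    keep_night = rng.random(len(out.sleep)) >= (1.0 - wear_fraction)
    dropped = out.sleep.loc[~keep_night]
    out.sleep = out.sleep.loc[keep_night].reset_index(drop=True)
    for row in dropped.itertuples():
        for name in ("spo2", "hrv"):
            frame = getattr(out, name)
            if frame.empty:
                continue
            inside = (frame["timestamp"] >= row.onset_time) & (frame["timestamp"] < row.end_time)
            setattr(out, name, frame.loc[~inside].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# participant generation
# ---------------------------------------------------------------------------

def _ema_log(
    truth: GroundTruth, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for ev in truth.events.itertuples():
        report = ev.use_time + pd.Timedelta(minutes=int(rng.integers(30, 721)))
        reported_use = ev.use_time
        if config.ema_recall_minutes > 0:
            jitter = rng.uniform(-config.ema_recall_minutes, config.ema_recall_minutes)
            reported_use = ev.use_time + pd.Timedelta(minutes=float(round(jitter, 1)))
        reported_use = min(reported_use, report)
        reported_use = max(reported_use, report - pd.Timedelta(hours=24))
        rows.append(
            {"report_time": report.floor("min"), "use_time": reported_use.floor("min"),
             "substance": ev.substance}
        )
    return pd.DataFrame(rows, columns=["report_time", "use_time", "substance"])


def generate_participant(
    config: CohortConfig, participant_index: int
) -> tuple[RawStreams, pd.DataFrame, GroundTruth]:
    """Generate one participant's streams, EMA log and ground truth.

    Deterministic in ``(config.rng_seed, participant_index)``. The returned
    streams already carry the use-coupled perturbations and non-wear gaps.
    """
    if not (0 <= participant_index < config.n_participants):
        raise ConfigError("participant_index must be in [0, n_participants)")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed) & 0x7FFFFFFF, participant_index])
    )
    minutes = pd.date_range(EPOCH, periods=config.monitoring_days * 1440, freq="min")
    periods = _sleep_periods(config.monitoring_days, rng)

    hr = pd.DataFrame({"timestamp": minutes, "bpm": np.round(_circadian_hr(minutes, rng), 2)})
    steps = pd.DataFrame({"timestamp": minutes, "steps": _steps_stream(minutes, periods, rng)})
    sleep = _sleep_frame(periods, rng)
    spo2, hrv = _sleep_minute_streams(periods, rng)
    streams = RawStreams(hr, steps, sleep, spo2, hrv)

    truth = GroundTruth(_draw_events(config, rng))
    duration_table = {k.lower(): v for k, v in config.durations.items()}
    streams = inject_use_effects(streams, truth, config.effect_size, duration_table)
    streams = apply_missingness(streams, config.wear_fraction, rng)
    ema = _ema_log(truth, config, rng)
    return streams, ema, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_FIXTURE_NAMES = ("hr", "steps", "sleep", "spo2", "hrv")


def write_fixtures(streams: RawStreams, ema_log: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write one CSV per stream plus ``ema.csv``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in _FIXTURE_NAMES:
        p = out_dir / f"{name}.csv"
        getattr(streams, name).to_csv(p, index=False)
        paths[name] = p
    p = out_dir / "ema.csv"
    ema_log.to_csv(p, index=False)
    paths["ema"] = p
    return paths


def read_fixtures(in_dir) -> tuple[RawStreams, pd.DataFrame]:
    """Read fixtures written by :func:`write_fixtures` back into memory."""
    in_dir = Path(in_dir)

    def _read(name: str, time_cols: list[str]) -> pd.DataFrame:
        # round_trip parsing keeps the CSV <-> memory mapping lossless
        df = pd.read_csv(
            in_dir / f"{name}.csv", parse_dates=time_cols, float_precision="round_trip"
        )
        return df

    hr = _read("hr", ["timestamp"])
    steps = _read("steps", ["timestamp"])
    sleep = _read("sleep", ["onset_time", "end_time"])
    spo2 = _read("spo2", ["timestamp"])
    hrv = _read("hrv", ["timestamp"])
    ema = pd.read_csv(in_dir / "ema.csv", parse_dates=["report_time", "use_time"])
    return RawStreams(hr, steps, sleep, spo2, hrv), ema


def null_config(**overrides) -> CohortConfig:
    """Convenience: a cohort with no use-coupled signal (effect_size=0)."""
    base = CohortConfig(**overrides)
    return replace(base, effect_size=0.0)
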