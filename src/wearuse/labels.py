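"""Hourly binary use/non-use labels from ecological momentary assessment (EMA) logs.

Participants self-report the approximate time and substance of each use event.
Each reported event is expanded over the average effect duration of the
substance, on a clock-aligned hourly grid: the event's hour (floor of the
reported minute) plus ``duration - 1`` following hours are labeled "use" (1);
every other hour on the grid is "non-use" (0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EFFECT_DURATIONS",
    "UseEvent",
    "parse_ema_log",
    "expand_use_events",
    "build_hourly_labels",
]

#: Average effect duration per substance, in whole hours. These are documented
#: package defaults meant to be reviewed and overridden per deployment; they
#: are not population estimates.
DEFAULT_EFFECT_DURATIONS: dict[str, int] = {
    "meth": 8,
    "alcohol": 4,
    "cannabis": 3,
    "opioids": 4,
    "cocaine": 2,
    "sedatives": 6,
    "benzodiazepines": 6,
    "nicotine": 1,
    "mushrooms": 5,
    "ghb": 2,
}


class DurationTableError(KeyError):
    """A substance in the EMA log has no entry in the effect-duration table."""


@dataclass(frozen=True)
class UseEvent:
    """A single self-reported substance use instance."""

    use_time: pd.Timestamp
    substance: str


def parse_ema_log(path) -> list[UseEvent]:
    """Read an ``ema.csv`` file into a deduplicated, sorted event list.

    See :func:`events_from_log` for the cleaning rules.
    """
    df = pd.read_csv(path, parse_dates=["report_time", "use_time"])
    return events_from_log(df)


def events_from_log(df: pd.DataFrame) -> list[UseEvent]:
    """Clean an in-memory EMA log into a deduplicated, sorted event list.

    Rows whose use time lies after the report time are physically impossible
    (uses are reported retrospectively) and are dropped with a warning.
    Two rows reporting the same substance within the same clock hour are
    collapsed to one event, keeping the earliest reported minute.
    """
    if df.empty:
        return []
    bad = df["use_time"] > df["report_time"]
    if bad.any():
        logger.warning("Rejected %d EMA rows with use_time after report_time", int(bad.sum()))
        df = df[~bad]
    df = df.sort_values("use_time", kind="stable")
    df = df.assign(_hour=df["use_time"].dt.floor("h"))
    df = df.drop_duplicates(subset=["_hour", "substance"], keep="first")
    return [UseEvent(row.use_time, row.substance) for row in df.itertuples()]


def expand_use_events(
    events: list[UseEvent], durations: dict[str, int]
) -> set[pd.Timestamp]:
    """Expand each event over its substance's effect duration.

    An event at time *t* with duration *d* hours marks hours
    ``floor(t), floor(t)+1h, ..., floor(t)+(d-1)h``. Overlapping events union
    their hours.
    """
    use_hours: set[pd.Timestamp] = set()
    for ev in events:
        key = ev.substance.strip().lower()
        if key not in durations:
            raise DurationTableError(
                f"No effect duration configured for substance {ev.substance!r}"
            )
        d = int(durations[key])
        start = ev.use_time.floor("h")
        use_hours.update(start + pd.Timedelta(hours=h) for h in range(d))
    return use_hours


def build_hourly_labels(
    use_hours: set[pd.Timestamp], hour_index: pd.DatetimeIndex
) -> pd.Series:
    """Binary label series aligned with a feature-matrix hour index.

    Use-hours falling outside the grid (e.g. reported after monitoring ended)
    are dropped with a logged count.
    """
    grid = set(hour_index)
    outside = len(use_hours - grid)
    if outside:
        logger.warning("%d use-hours fall outside the hourly grid and were dropped", outside)
    labels = pd.Series(0, index=hour_index, dtype=int, name="label")
    inside = sorted(use_hours & grid)
    if inside:
        labels.loc[inside] = 1
    return labels
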