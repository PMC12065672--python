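import numpy as np
import pandas as pd
import pytest

from wearuse import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.CohortConfig(
        n_participants=2, monitoring_days=7, wear_fraction=0.8,
        daily_use_rate=2.0, effect_size=1.0, rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_participant(small_cohort):
    """Streams, EMA log and ground truth for one 7-day participant."""
    return synthetic.generate_participant(small_cohort, 0)


def constant_streams(days: int = 3, bpm: float = 72.0) -> synthetic.RawStreams:
    """Noise-free streams: flat heart rate, zero steps, one bland night per
    day — a controlled substrate for perturbation tests."""
    minutes = pd.date_range(synthetic.EPOCH, periods=days * 1440, freq="min")
    hr = pd.DataFrame({"timestamp": minutes, "bpm": np.full(len(minutes), bpm)})
    steps = pd.DataFrame({"timestamp": minutes, "steps": np.zeros(len(minutes), dtype=int)})
    sleep_rows = []
    spo2_parts, hrv_parts = [], []
    for d in range(days - 1):
        onset = synthetic.EPOCH + pd.Timedelta(days=d, hours=23)
        end = synthetic.EPOCH + pd.Timedelta(days=d + 1, hours=7)
        sleep_rows.append({
            "onset_time": onset, "end_time": end, "efficiency": 0.9,
            "total_minutes": 432.0, "minutes_awake": 48.0,
            "br_deep": 14.0, "br_rem": 15.5, "br_light": 15.0, "br_full": 15.0,
        })
        idx = pd.date_range(onset, end - pd.Timedelta(minutes=1), freq="min")
        spo2_parts.append(pd.DataFrame({"timestamp": idx, "spo2": np.full(len(idx), 96.0)}))
        hrv_parts.append(pd.DataFrame({
            "timestamp": idx, "rmssd": np.full(len(idx), 50.0),
            "lf": np.full(len(idx), 400.0), "hf": np.full(len(idx), 200.0),
            "coverage": np.full(len(idx), 0.95),
        }))
    return synthetic.RawStreams(
        hr, steps, pd.DataFrame(sleep_rows),
        pd.concat(spo2_parts, ignore_index=True),
        pd.concat(hrv_parts, ignore_index=True),
    )


@pytest.fixture()
def flat_streams():
    return constant_streams()
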