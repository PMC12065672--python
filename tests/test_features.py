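"""Feature engineering: FFT dominant frequency, hourly/nightly aggregation,
previous-day mapping, missingness preservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearuse import features, synthetic

from conftest import constant_streams


def brute_force_domfreq(x: np.ndarray) -> float:
    """O(N^2) DFT-magnitude argmax oracle with the same tie/degeneracy rules."""
    n = len(x)
    if n < 2:
        return np.nan
    mags = []
    for k in range(1, n // 2 + 1):
        s = sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
        mags.append(abs(s))
    if max(mags) < 1e-9:
        return 0.0
    return float(np.argmax(mags) + 1)


class TestDominantFrequency:
    @pytest.mark.parametrize("k", [1, 5, 13, 29])
    def test_pure_tone_recovered_exactly(self, k):
        n = 60
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        assert features.dominant_frequency(x) == k

    def test_constant_signal_returns_zero(self):
        assert features.dominant_frequency(np.full(60, 72.0)) == 0.0

    def test_too_short_returns_missing(self):
        assert np.isnan(features.dominant_frequency([5.0]))

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 65))
            x = rng.normal(70, 5, n)
            assert features.dominant_frequency(x) == brute_force_domfreq(x)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                    min_size=2, max_size=64))
    def test_brute_force_agreement_is_universal(self, xs):
        x = np.asarray(xs)
        got = features.dominant_frequency(x)
        expected = brute_force_domfreq(x)
        # exact ties and the degeneracy threshold are sensitive to float
        # rounding, which legitimately differs between rfft and a naive sum;
        # the argmax must agree whenever the maximum is clearly separated
        mags = np.sort(np.abs(np.fft.rfft(x))[1 : len(x) // 2 + 1])
        clearly_nonzero = mags.size and abs(float(mags[-1]) - 1e-9) > 1e-7
        clearly_separated = mags.size < 2 or mags[-1] - mags[-2] > 1e-6 * max(1.0, mags[-1])
        if clearly_nonzero and clearly_separated:
            assert got == expected


def _minutes(hour: int, values) -> pd.DataFrame:
    idx = pd.date_range(
        synthetic.EPOCH + pd.Timedelta(hours=hour), periods=len(values), freq="min"
    )
    return pd.DataFrame({"timestamp": idx, "bpm": values})


class TestHourlyAggregates:
    def test_constant_hour(self):
        out = features.aggregate_hr_hourly(_minutes(0, np.full(60, 72.0)))
        row = out.iloc[0]
        assert (row["hr_mean"], row["hr_sd"], row["hr_max"], row["hr_domfreq"]) == (
            72.0, 0.0, 72.0, 0.0,
        )

    def test_two_point_statistics(self):
        out = features.aggregate_hr_hourly(_minutes(3, [60.0, 80.0]))
        row = out.iloc[0]
        assert row["hr_mean"] == 70.0
        assert row["hr_sd"] == 10.0  # population SD
        assert row["hr_max"] == 80.0

    def test_random_hour_matches_streaming_recomputation(self):
        rng = np.random.default_rng(11)
        values = rng.normal(75, 8, 60)
        out = features.aggregate_hr_hourly(_minutes(5, values)).iloc[0]
        mean = sum(values) / len(values)
        sd = (sum((v - mean) ** 2 for v in values) / len(values)) ** 0.5
        assert out["hr_mean"] == pytest.approx(mean, abs=1e-9)
        assert out["hr_sd"] == pytest.approx(sd, abs=1e-9)
        assert out["hr_max"] == max(values)

    def test_order_invariance_within_hour(self):
        rng = np.random.default_rng(12)
        df = _minutes(2, rng.normal(70, 5, 60))
        shuffled = df.sample(frac=1.0, random_state=1)
        a = features.aggregate_hr_hourly(df)
        b = features.aggregate_hr_hourly(shuffled.sort_values("timestamp"))
        pd.testing.assert_frame_equal(a, b)

    def test_steps_examples_and_brute_force_active_minutes(self):
        idx = pd.date_range(synthetic.EPOCH, periods=60, freq="min")
        zeros = pd.DataFrame({"timestamp": idx, "steps": np.zeros(60, dtype=int)})
        out = features.aggregate_steps_hourly(zeros).iloc[0]
        assert (out["steps_avg"], out["steps_max"], out["active_minutes"]) == (0, 0, 0)

        vals = np.zeros(60, dtype=int)
        vals[40], vals[41] = 100, 20
        out = features.aggregate_steps_hourly(
            pd.DataFrame({"timestamp": idx, "steps": vals})
        ).iloc[0]
        assert out["active_minutes"] == 2 and out["steps_max"] == 100

        rng = np.random.default_rng(13)
        vals = rng.poisson(1.0, 60)
        out = features.aggregate_steps_hourly(
            pd.DataFrame({"timestamp": idx, "steps": vals})
        ).iloc[0]
        assert out["active_minutes"] == sum(1 for v in vals if v > 0)


class TestNightlyAggregates:
    def test_spo2_strict_hypoxemia_boundary(self):
        idx = pd.date_range(synthetic.EPOCH + pd.Timedelta(hours=1), periods=4, freq="min")
        df = pd.DataFrame({"timestamp": idx, "spo2": [91.0, 89.0, 90.0, 88.0]})
        out = features.spo2_daily_features(df).iloc[0]
        assert out["spo2_minutes_below90"] == 2  # 90 itself is not hypoxemic
        assert out["hypoxemia_flag"] == 1.0

    def test_spo2_all_healthy(self):
        idx = pd.date_range(synthetic.EPOCH + pd.Timedelta(hours=1), periods=30, freq="min")
        out = features.spo2_daily_features(
            pd.DataFrame({"timestamp": idx, "spo2": np.full(30, 95.0)})
        ).iloc[0]
        assert out["spo2_mean"] == 95.0
        assert out["spo2_minutes_below90"] == 0
        assert out["hypoxemia_flag"] == 0.0

    def test_spo2_brute_force_count(self):
        rng = np.random.default_rng(21)
        idx = pd.date_range(synthetic.EPOCH + pd.Timedelta(hours=2), periods=120, freq="min")
        vals = rng.normal(92, 3, 120)
        out = features.spo2_daily_features(pd.DataFrame({"timestamp": idx, "spo2": vals}))
        assert out.iloc[0]["spo2_minutes_below90"] == sum(1 for v in vals if v < 90.0)

    def test_multiple_cycles_averaged_and_lh_ratio(self):
        base = synthetic.EPOCH + pd.Timedelta(hours=22)
        sleep = pd.DataFrame({
            "onset_time": [base, base + pd.Timedelta(hours=4)],
            "end_time": [base + pd.Timedelta(hours=3), base + pd.Timedelta(hours=8)],
            "efficiency": [0.8, 0.9],
            "total_minutes": [150.0, 200.0],
            "minutes_awake": [30.0, 40.0],
            "br_deep": [14.0, 14.0], "br_rem": [15.0, 15.0],
            "br_light": [15.0, 15.0], "br_full": [15.0, 15.0],
        })
        idx = pd.date_range(base, periods=10, freq="min")
        hrv = pd.DataFrame({
            "timestamp": idx, "rmssd": np.full(10, 40.0),
            "lf": np.full(10, 40.0), "hf": np.full(10, 20.0),
            "coverage": np.full(10, 1.0),
        })
        out = features.sleep_daily_features(sleep, hrv)
        assert len(out) == 1
        assert out.iloc[0]["sleep_efficiency"] == pytest.approx(0.85)
        assert out.iloc[0]["hrv_lh_ratio"] == pytest.approx(2.0)

    def test_lh_ratio_missing_when_hf_zero(self):
        base = synthetic.EPOCH + pd.Timedelta(hours=23)
        sleep = pd.DataFrame({
            "onset_time": [base], "end_time": [base + pd.Timedelta(hours=8)],
            "efficiency": [0.9], "total_minutes": [400.0], "minutes_awake": [20.0],
            "br_deep": [14.0], "br_rem": [15.0], "br_light": [15.0], "br_full": [15.0],
        })
        hrv = pd.DataFrame({
            "timestamp": [base], "rmssd": [40.0], "lf": [40.0], "hf": [0.0],
            "coverage": [1.0],
        })
        out = features.sleep_daily_features(sleep, hrv)
        assert np.isnan(out.iloc[0]["hrv_lh_ratio"])


class TestAssembly:
    def test_night_maps_to_previous_day(self, flat_streams):
        matrix = features.assemble_feature_matrix(
            features.aggregate_hr_hourly(flat_streams.hr),
            features.aggregate_steps_hourly(flat_streams.steps),
            features.spo2_daily_features(flat_streams.spo2),
            features.sleep_daily_features(flat_streams.sleep, flat_streams.hrv),
            start=synthetic.EPOCH, periods=3 * 24,
        )
        # the night spanning day 0 23:00 -> day 1 07:00 ends on day 1,
        # so its features sit on every hour of day 0
        day0 = matrix.iloc[:24]
        assert (day0["sleep_efficiency"] == 0.9).all()
        # the last day has no following night: sleep features missing
        assert matrix.iloc[-24:]["sleep_efficiency"].isna().all()

    def test_28_day_grid_has_672_rows(self):
        streams = constant_streams(days=28)
        matrix = features.assemble_feature_matrix(
            features.aggregate_hr_hourly(streams.hr),
            features.aggregate_steps_hourly(streams.steps),
            features.spo2_daily_features(streams.spo2),
            features.sleep_daily_features(streams.sleep, streams.hrv),
            start=synthetic.EPOCH, periods=28 * 24,
        )
        assert matrix.shape == (672, len(features.FEATURE_COLUMNS))

    def test_missing_hours_stay_missing(self, flat_streams):
        hr = flat_streams.hr
        gap = (hr["timestamp"] >= synthetic.EPOCH + pd.Timedelta(hours=10)) & (
            hr["timestamp"] < synthetic.EPOCH + pd.Timedelta(hours=12)
        )
        matrix = features.assemble_feature_matrix(
            features.aggregate_hr_hourly(hr.loc[~gap]),
            features.aggregate_steps_hourly(flat_streams.steps),
            features.spo2_daily_features(flat_streams.spo2),
            features.sleep_daily_features(flat_streams.sleep, flat_streams.hrv),
            start=synthetic.EPOCH, periods=3 * 24,
        )
        assert matrix["hr_mean"].iloc[10:12].isna().all()
        assert matrix["hr_mean"].iloc[12:24].notna().all()
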