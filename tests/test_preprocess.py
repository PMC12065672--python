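"""Windowing, oversampling, feature selection, imputation, normalization,
and the train-only leakage guard."""

import numpy as np
import pandas as pd
import pytest

from wearuse import preprocess, synthetic
from wearuse.preprocess import PreprocessError


def _matrix(n_hours: int, n_features: int = 4, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    idx = pd.date_range(synthetic.EPOCH, periods=n_hours, freq="h")
    return pd.DataFrame(
        rng.normal(0, 1, (n_hours, n_features)),
        index=idx, columns=[f"f{i}" for i in range(n_features)],
    )


def _labels(matrix: pd.DataFrame, values=None, seed: int = 1) -> pd.Series:
    if values is None:
        rng = np.random.default_rng(seed)
        values = (rng.random(len(matrix)) < 0.2).astype(int)
    return pd.Series(values, index=matrix.index, name="label")


class TestChronoSplit:
    @pytest.mark.parametrize("n,expected_train", [(100, 70), (101, 71)])
    def test_ceiling_rule(self, n, expected_train):
        m = _matrix(n)
        (tm, ty), (sm, sy) = preprocess.chrono_split(m, _labels(m))
        assert len(tm) == expected_train and len(sm) == n - expected_train

    def test_chronology(self):
        m = _matrix(100)
        (tm, _), (sm, _) = preprocess.chrono_split(m, _labels(m))
        assert tm.index.max() < sm.index.min()

    def test_too_short_rejected(self):
        m = _matrix(20)
        with pytest.raises(PreprocessError):
            preprocess.chrono_split(m, _labels(m))


class TestMakeWindows:
    def test_window_count_identity(self):
        for n in (12, 20, 100):
            m = _matrix(n)
            w = preprocess.make_windows(m, _labels(m))
            assert len(w) == n - 11

    def test_all_zero_labels(self):
        m = _matrix(30)
        w = preprocess.make_windows(m, _labels(m, values=np.zeros(30, dtype=int)))
        assert w.labels.sum() == 0

    def test_window_label_is_final_hour_label(self):
        m = _matrix(60)
        y = _labels(m, seed=4)
        w = preprocess.make_windows(m, y)
        for i in range(len(w)):
            assert w.labels[i] == y.iloc[w.end_hour[i]]
            np.testing.assert_array_equal(
                w.windows[i], m.iloc[w.end_hour[i] - 11 : w.end_hour[i] + 1].to_numpy()
            )

    def test_short_slice_yields_empty_set(self):
        m = _matrix(30).iloc[:8]
        w = preprocess.make_windows(m, _labels(m)[:8])
        assert len(w) == 0


class TestOversample:
    def test_no_positives_identity(self):
        m = _matrix(48)
        w = preprocess.make_windows(m, _labels(m, values=np.zeros(48, dtype=int)))
        out = preprocess.oversample_use(w, rng=np.random.default_rng(0))
        assert out is w

    def test_two_positives_in_ten_reach_half(self):
        m = _matrix(23)  # 12 windows, one 24 h segment
        vals = np.zeros(23, dtype=int)
        vals[[15, 18]] = 1
        w = preprocess.make_windows(m, _labels(m, values=vals))
        assert len(w) == 12 and w.labels.sum() == 2
        out = preprocess.oversample_use(w, target_ratio=0.5,
                                        rng=np.random.default_rng(0))
        assert out.labels.sum() >= 8
        assert out.labels.mean() >= 0.5

    def test_order_preserved_and_features_unaltered(self):
        m = _matrix(80)
        w = preprocess.make_windows(m, _labels(m, seed=6))
        out = preprocess.oversample_use(w, rng=np.random.default_rng(0))
        assert (np.diff(out.end_hour) >= 0).all()
        # every output row is byte-identical to the source window it duplicates
        by_end = {int(e): w.windows[i] for i, e in enumerate(w.end_hour)}
        for i, e in enumerate(out.end_hour):
            np.testing.assert_array_equal(out.windows[i], by_end[int(e)])

    def test_invalid_ratio_rejected(self):
        m = _matrix(30)
        w = preprocess.make_windows(m, _labels(m))
        with pytest.raises(PreprocessError):
            preprocess.oversample_use(w, target_ratio=1.5)


class TestSelectFeatures:
    def _signal_windows(self, seed: int):
        rng = np.random.default_rng(seed)
        n = 150
        idx = pd.date_range(synthetic.EPOCH, periods=n, freq="h")
        y = (rng.random(n) < 0.3).astype(int)
        m = pd.DataFrame(rng.normal(0, 1, (n, 5)), index=idx,
                         columns=["hr_mean", "a", "b", "c", "d"])
        m["hr_mean"] += 3.0 * y  # only hr_mean carries signal
        return preprocess.make_windows(m, pd.Series(y, index=idx))

    def test_informative_feature_recovered(self):
        hits = sum(
            "hr_mean" in preprocess.select_features(self._signal_windows(s), s).retained
            for s in range(20)
        )
        assert hits >= 18

    def test_strict_median_rule(self):
        sel = preprocess.select_features(self._signal_windows(0), 0)
        med = np.median(list(sel.importance.values()))
        if not sel.fallback_used:
            assert set(sel.retained) == {
                f for f, v in sel.importance.items() if v > med
            }

    def test_tied_importances_fall_back_to_top_half(self):
        # identical feature columns -> near-tied importances can empty the
        # strict-median rule; the fallback keeps the top half by rank
        rng = np.random.default_rng(2)
        n = 80
        idx = pd.date_range(synthetic.EPOCH, periods=n, freq="h")
        col = rng.normal(0, 1, n)
        m = pd.DataFrame({f"f{i}": col for i in range(4)}, index=idx)
        y = pd.Series((rng.random(n) < 0.4).astype(int), index=idx)
        sel = preprocess.select_features(preprocess.make_windows(m, y), 0)
        assert len(sel.retained) >= 2

    def test_single_class_rejected(self):
        m = _matrix(40)
        w = preprocess.make_windows(m, _labels(m, values=np.zeros(40, dtype=int)))
        with pytest.raises(PreprocessError):
            preprocess.select_features(w, 0)


class TestImputation:
    def test_no_missing_is_identity(self):
        tm, sm = _matrix(100, seed=3), _matrix(30, seed=4)
        a, b, _ = preprocess.impute_missing(tm, sm, 0)
        pd.testing.assert_frame_equal(a, tm)
        pd.testing.assert_frame_equal(b, sm)

    def test_constant_column_imputed_to_constant(self):
        tm = _matrix(60, seed=5)
        tm["f0"] = 7.0
        tm.iloc[10, 0] = np.nan
        a, _, _ = preprocess.impute_missing(tm, tm.iloc[:5], 0)
        assert a.iloc[10, 0] == pytest.approx(7.0)

    def test_observed_values_unchanged(self):
        tm = _matrix(80, seed=6)
        tm.iloc[5, 1] = np.nan
        a, _, _ = preprocess.impute_missing(tm, tm.iloc[:5], 0)
        mask = tm.notna()
        pd.testing.assert_frame_equal(a[mask], tm[mask])

    def test_mcar_recovery_beats_column_sd(self):
        # correlated columns -> the imputer should recover masked cells with
        # RMSE below the column SD (the error of mean imputation)
        rng = np.random.default_rng(7)
        n = 250
        idx = pd.date_range(synthetic.EPOCH, periods=n, freq="h")
        base = rng.normal(0, 1, n)
        tm = pd.DataFrame({
            "f0": base + rng.normal(0, 0.2, n),
            "f1": base + rng.normal(0, 0.2, n),
            "f2": 2 * base + rng.normal(0, 0.2, n),
        }, index=idx)
        truth = tm.copy()
        mask = rng.random((n, 3)) < 0.1
        tm = tm.mask(mask)
        a, _, _ = preprocess.impute_missing(tm, tm.iloc[:5], 0)
        err = (a.to_numpy() - truth.to_numpy())[mask]
        rmse = float(np.sqrt(np.mean(err ** 2)))
        assert rmse < truth.stack().std()

    def test_fully_missing_feature_dropped(self, caplog):
        tm = _matrix(50, seed=8)
        tm["f3"] = np.nan
        a, b, _ = preprocess.impute_missing(tm, tm.iloc[:5], 0)
        assert "f3" not in a.columns and "f3" not in b.columns


class TestNormalize:
    def test_two_point_zscore(self):
        idx = pd.date_range(synthetic.EPOCH, periods=2, freq="h")
        tm = pd.DataFrame({"f0": [0.0, 2.0]}, index=idx)
        norm = preprocess.normalize_fit(tm)
        out = norm.transform_matrix(tm)
        np.testing.assert_allclose(out["f0"].to_numpy(), [-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        idx = pd.date_range(synthetic.EPOCH, periods=5, freq="h")
        tm = pd.DataFrame({"f0": np.full(5, 3.3)}, index=idx)
        out = preprocess.normalize_fit(tm).transform_matrix(tm)
        np.testing.assert_allclose(out["f0"].to_numpy(), 0.0)

    def test_training_means_are_zero_after_transform(self):
        tm = _matrix(100, seed=9)
        out = preprocess.normalize_fit(tm).transform_matrix(tm)
        np.testing.assert_allclose(out.mean().to_numpy(), 0.0, atol=1e-9)


class TestPipelineChain:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        idx = pd.date_range(synthetic.EPOCH, periods=n, freq="h")
        m = pd.DataFrame(rng.normal(0, 1, (n, 4)), index=idx,
                         columns=["f0", "f1", "f2", "f3"])
        y = pd.Series((rng.random(n) < 0.25).astype(int), index=idx)
        m["f0"] += 2.0 * y
        m = m.mask(rng.random((n, 4)) < 0.05)
        return m, y

    def test_leakage_guard_train_statistics_ignore_test_slice(self):
        """Corrupting the test slice must not change any fitted statistic or
        any training-window value (bit-wise)."""
        m, y = self._inputs()
        res_a = preprocess.preprocess_participant(m, y, rng_seed=0)
        m2 = m.copy()
        m2.iloc[140:] = m2.iloc[140:] * 100.0 + 7.0  # test slice is hours 140..199
        res_b = preprocess.preprocess_participant(m2, y, rng_seed=0)
        np.testing.assert_array_equal(res_a.normalizer.mean, res_b.normalizer.mean)
        np.testing.assert_array_equal(res_a.normalizer.sd, res_b.normalizer.sd)
        assert res_a.selection.retained == res_b.selection.retained
        np.testing.assert_array_equal(res_a.train.windows, res_b.train.windows)
        np.testing.assert_array_equal(res_a.train_raw.windows, res_b.train_raw.windows)

    def test_validation_tail_is_chronological_and_never_oversampled(self):
        m, y = self._inputs(1)
        res = preprocess.preprocess_participant(m, y, rng_seed=1)
        assert res.val.end_hour.min() > res.train.end_hour.max()
        assert len(np.unique(res.val.end_hour)) == len(res.val.end_hour)
        n_fit_raw = len(np.unique(res.train.end_hour))
        assert len(res.train_raw) == len(res.val) + n_fit_raw

    def test_deterministic(self):
        m, y = self._inputs(2)
        a = preprocess.preprocess_participant(m, y, rng_seed=5)
        b = preprocess.preprocess_participant(m, y, rng_seed=5)
        np.testing.assert_array_equal(a.train.windows, b.train.windows)
        assert a.selection.retained == b.selection.retained
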