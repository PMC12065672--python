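"""Train/test window construction for per-participant classifiers.

The hourly feature matrix and its labels are split chronologically (first 70%
of hours train, rest test), missing values are imputed with an iterative
random-forest imputer fitted on the training hours only, features are
z-scored with training statistics, stride-1 overlapping 12-hour windows are
cut (each window labeled by its final hour), features are selected by
random-forest Gini importance against the per-participant median, and the
scarce "use" windows are locally oversampled within 24-hour segments of the
training set. Every fitted statistic depends only on the training slice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOW_STEPS",
    "LabeledWindowSet",
    "FeatureSelection",
    "Normalizer",
    "chrono_split",
    "make_windows",
    "oversample_use",
    "select_features",
    "impute_missing",
    "normalize_fit",
    "preprocess_participant",
]

WINDOW_STEPS = 12
RF_TREES = 100      # feature-importance forest
IMPUTE_TREES = 20   # per-feature regressor inside the iterative imputer


class PreprocessError(ValueError):
    pass


@dataclass
class LabeledWindowSet:
    """Overlapping 12-step windows with end-aligned binary labels."""

    windows: np.ndarray          # (n_windows, 12, n_features)
    labels: np.ndarray           # (n_windows,) in {0, 1}
    end_hour: np.ndarray         # grid position of each window's final step
    end_time: pd.DatetimeIndex   # timestamp of each window's final step
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def subset_features(self, names: list[str]) -> "LabeledWindowSet":
        idx = [self.feature_names.index(n) for n in names]
        return LabeledWindowSet(
            self.windows[:, :, idx], self.labels, self.end_hour, self.end_time, list(names)
        )

    def subset_rows(self, idx) -> "LabeledWindowSet":
        return LabeledWindowSet(
            self.windows[idx], self.labels[idx], self.end_hour[idx],
            self.end_time[idx], self.feature_names,
        )


@dataclass
class FeatureSelection:
    importance: dict[str, float]
    retained: list[str]
    threshold: float
    fallback_used: bool = False


@dataclass
class Normalizer:
    """Per-feature z-scoring with training mean/SD; zero-variance features map to 0."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def transform_matrix(self, matrix: pd.DataFrame) -> pd.DataFrame:
        sd = np.where(self.sd == 0.0, 1.0, self.sd)
        return (matrix - self.mean) / sd


def chrono_split(
    matrix: pd.DataFrame, labels: pd.Series, train_fraction: float = 0.7
) -> tuple[tuple[pd.DataFrame, pd.Series], tuple[pd.DataFrame, pd.Series]]:
    """Chronological split: first ``ceil(train_fraction * n)`` hours train."""
    if len(matrix) != len(labels):
        raise PreprocessError("matrix and labels are not aligned")
    n = len(matrix)
    if n < 24:
        raise PreprocessError(f"need at least 24 hours to split, got {n}")
    n_train = int(np.ceil(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = (matrix.iloc[:n_train], labels.iloc[:n_train])
    test = (matrix.iloc[n_train:], labels.iloc[n_train:])
    if int(test[1].sum()) == 0:
        logger.warning("Test slice contains no positive labels")
    return train, test


def make_windows(
    matrix: pd.DataFrame, labels: pd.Series, offset: int = 0
) -> LabeledWindowSet:
    """Stride-1 sliding windows of 12 hours; label = label of the final hour.

    ``offset`` shifts the recorded grid positions (used so test windows carry
    absolute positions within the full monitoring period).
    """
    n = len(matrix)
    names = list(matrix.columns)
    if n < WINDOW_STEPS:
        logger.warning("Slice of %d hours is shorter than one window; empty set", n)
        empty = np.empty((0, WINDOW_STEPS, len(names)))
        return LabeledWindowSet(
            empty, np.empty(0, dtype=int), np.empty(0, dtype=int),
            pd.DatetimeIndex([]), names,
        )
    values = matrix.to_numpy(dtype=float)
    n_windows = n - WINDOW_STEPS + 1
    windows = np.lib.stride_tricks.sliding_window_view(values, WINDOW_STEPS, axis=0)
    windows = np.ascontiguousarray(np.moveaxis(windows, 2, 1))  # (n_windows, 12, F)
    end = np.arange(WINDOW_STEPS - 1, n)
    return LabeledWindowSet(
        windows,
        labels.to_numpy(dtype=int)[end],
        end + offset,
        pd.DatetimeIndex(matrix.index[end]),
        names,
    )


def oversample_use(
    windows: LabeledWindowSet,
    target_ratio: float = 0.5,
    segment_hours: int = 24,
    rng: np.random.Generator | None = None,
) -> LabeledWindowSet:
    """Duplicate positive windows within local segments of the training set.

    Within each contiguous ``segment_hours`` segment, every positive window is
    duplicated adjacently (preserving temporal order) until the segment's
    positive fraction reaches ``target_ratio`` or each positive has been
    copied 10 times. Feature values are never altered; segments without
    positives are unchanged. Never apply this to test windows.
    """
    if not (0.0 < target_ratio < 1.0):
        raise PreprocessError("target_ratio must be in (0, 1)")
    if len(windows) == 0 or windows.labels.sum() == 0:
        return windows
    seg = (windows.end_hour - windows.end_hour[0]) // segment_hours
    keep_order: list[np.ndarray] = []
    for s in np.unique(seg):
        idx = np.flatnonzero(seg == s)
        pos = idx[windows.labels[idx] == 1]
        n_tot, n_pos = len(idx), len(pos)
        if n_pos == 0:
            keep_order.append(idx)
            continue
        # k extra copies per positive: smallest k with p(1+k) >= ratio*(n+p*k);
        # capped so no positive appears more than 10 times in total
        k = int(np.ceil((target_ratio * n_tot - n_pos) / (n_pos * (1.0 - target_ratio))))
        k = min(max(k, 0), 9)
        reps = np.where(windows.labels[idx] == 1, 1 + k, 1)
        keep_order.append(np.repeat(idx, reps))
    order = np.concatenate(keep_order)
    return LabeledWindowSet(
        windows.windows[order],
        windows.labels[order],
        windows.end_hour[order],
        windows.end_time[order],
        windows.feature_names,
    )


def select_features(train_windows: LabeledWindowSet, rng_seed: int = 0) -> FeatureSelection:
    """Per-participant feature selection by random-forest Gini importance.

    A 100-tree forest is fitted on flattened training windows; each feature's
    importance is summed over its 12 time positions and features strictly
    above the median importance are retained. If fewer than two survive
    (e.g. ties), the top half by rank is retained instead (ties broken by
    feature order).
    """
    names = train_windows.feature_names
    if len(names) < 2:
        raise PreprocessError("need at least 2 features to select from")
    y = train_windows.labels
    if len(np.unique(y)) < 2:
        raise PreprocessError(
            "training labels contain a single class; generate a longer or "
            "denser monitoring period"
        )
    X = train_windows.windows.reshape(len(train_windows), -1)
    forest = RandomForestClassifier(
        n_estimators=RF_TREES, random_state=int(rng_seed) & 0x7FFFFFFF, n_jobs=1
    )
    forest.fit(X, y)
    per_cell = forest.feature_importances_.reshape(WINDOW_STEPS, len(names))
    importance = dict(zip(names, per_cell.sum(axis=0)))
    threshold = float(np.median(list(importance.values())))
    retained = [n for n in names if importance[n] > threshold]
    fallback = len(retained) < 2
    if fallback:
        order = sorted(names, key=lambda n: (-importance[n], names.index(n)))
        retained = sorted(order[: int(np.ceil(len(names) / 2))], key=names.index)
    return FeatureSelection(
        {k: float(v) for k, v in importance.items()}, retained, threshold, fallback
    )


def impute_missing(
    train_matrix: pd.DataFrame,
    test_matrix: pd.DataFrame,
    rng_seed: int = 0,
    max_iter: int = 5,
    n_trees: int = IMPUTE_TREES,
) -> tuple[pd.DataFrame, pd.DataFrame, IterativeImputer]:
    """Iterative random-forest imputation fitted on training hours only.

    The per-feature regressor uses a modest 20-tree forest: inside the
    round-robin imputer each feature is refit up to ``max_iter`` times, and
    a small forest recovers conditional means on a few hundred hourly rows
    as well as a large one at a fraction of the cost.

    Features with no observed training value cannot be imputed and are
    dropped from both slices with a warning. Observed values pass through
    unchanged.
    """
    all_missing = [c for c in train_matrix.columns if train_matrix[c].isna().all()]
    if all_missing:
        logger.warning("Dropping features fully missing in training: %s", all_missing)
        train_matrix = train_matrix.drop(columns=all_missing)
        test_matrix = test_matrix.drop(columns=all_missing)
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(
            n_estimators=n_trees, random_state=int(rng_seed) & 0x7FFFFFFF, n_jobs=1
        ),
        max_iter=max_iter,
        random_state=int(rng_seed) & 0x7FFFFFFF,
        keep_empty_features=False,
    )
    with warnings.catch_warnings():
        # the round cap is deliberate; convergence chatter is not actionable
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        train_values = imputer.fit_transform(train_matrix.to_numpy(dtype=float))
        test_values = imputer.transform(test_matrix.to_numpy(dtype=float))
    train_out = pd.DataFrame(train_values, index=train_matrix.index, columns=train_matrix.columns)
    test_out = pd.DataFrame(test_values, index=test_matrix.index, columns=test_matrix.columns)
    return train_out, test_out, imputer


def normalize_fit(train_matrix: pd.DataFrame) -> Normalizer:
    """Fit per-feature z-score parameters (population SD) on training hours."""
    values = train_matrix.to_numpy(dtype=float)
    return Normalizer(
        mean=np.nanmean(values, axis=0),
        sd=np.nanstd(values, axis=0, ddof=0),
        feature_names=list(train_matrix.columns),
    )


@dataclass
class PreprocessResult:
    train: LabeledWindowSet          # fitted portion, selected features, oversampled
    val: LabeledWindowSet            # chronological last 20% of train windows, raw
    test: LabeledWindowSet           # selected features, untouched order
    train_raw: LabeledWindowSet      # all training windows before oversampling
    selection: FeatureSelection
    normalizer: Normalizer


def preprocess_participant(
    matrix: pd.DataFrame,
    labels: pd.Series,
    train_fraction: float = 0.7,
    target_ratio: float = 0.5,
    segment_hours: int = 24,
    rng_seed: int = 0,
    impute_trees: int = IMPUTE_TREES,
    validation_fraction: float = 0.2,
) -> PreprocessResult:
    """Full preprocessing chain for one participant.

    Order: chronological split -> train-fitted imputation -> train-fitted
    normalization -> windowing -> Gini feature selection -> local
    oversampling of the fitted training windows. The chronologically last
    ``validation_fraction`` of the training windows is held out (raw, never
    oversampled) as the early-stopping validation set.
    """
    (train_m, train_y), (test_m, test_y) = chrono_split(matrix, labels, train_fraction)
    train_m, test_m, _ = impute_missing(train_m, test_m, rng_seed, n_trees=impute_trees)
    norm = normalize_fit(train_m)
    train_m = norm.transform_matrix(train_m)
    test_m = norm.transform_matrix(test_m)
    train_w = make_windows(train_m, train_y, offset=0)
    test_w = make_windows(test_m, test_y, offset=len(train_m))
    selection = select_features(train_w, rng_seed)
    train_w = train_w.subset_features(selection.retained)
    test_w = test_w.subset_features(selection.retained)
    n = len(train_w)
    n_val = min(max(1, int(round(validation_fraction * n))), n - 1)
    fit_w = train_w.subset_rows(np.arange(n - n_val))
    val_w = train_w.subset_rows(np.arange(n - n_val, n))
    rng = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)
    train_over = oversample_use(fit_w, target_ratio, segment_hours, rng)
    return PreprocessResult(train_over, val_w, test_w, train_w, selection, norm)
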