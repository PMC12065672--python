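"""Classifier evaluation: confusion metrics, ROC AUC, threshold sweeps, the
moving-block bootstrap, and operating-threshold selection.

Definitions used throughout (TP/FP/TN/FN at a decision threshold, predicted
positive when probability >= threshold):

* sensitivity (TPR) = TP / (TP + FN)
* specificity (TNR) = TN / (FP + TN)
* precision   (PPV) = TP / (TP + FP)
* AUC: area under the ROC curve, computed as the Mann–Whitney statistic
  P(p+ > p-) + 0.5 P(p+ = p-) over all positive/negative score pairs.

Zero-denominator metrics are reported as NaN and excluded (with a logged
count) from bootstrap aggregation rather than imputed.

The moving-block bootstrap resamples contiguous blocks of the time-ordered
test set — block length floor(sqrt(n)) — to estimate the variability of the
threshold metrics while preserving serial dependence, which ordinary
cross-validation folds on sparse-event time series do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "SWEEP_THRESHOLDS",
    "ConfusionCounts",
    "BootstrapReport",
    "ThresholdChoice",
    "confusion_at_threshold",
    "compute_metrics",
    "auc_score",
    "threshold_sweep",
    "block_bootstrap",
    "select_operating_threshold",
]

#: The canonical reporting thresholds 0.1 .. 0.9.
SWEEP_THRESHOLDS = np.round(np.arange(0.1, 0.95, 0.1), 10)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_aligned(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if probs.shape != labels.shape:
        raise EvaluationError("probs and labels have different lengths")
    return probs, labels


def confusion_at_threshold(probs, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with the >= decision rule."""
    probs, labels = _check_aligned(probs, labels)
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and precision; NaN on zero denominators."""

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan

    return {
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.fp + counts.tn),
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
    }


def auc_score(probs, labels) -> float:
    """ROC AUC via the rank (Mann–Whitney) formulation; NaN if single-class."""
    probs, labels = _check_aligned(probs, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(probs)  # average ranks handle ties as half-wins
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def threshold_sweep(probs, labels, thresholds=None) -> pd.DataFrame:
    """Per-threshold metric table (default thresholds 0.1 .. 0.9)."""
    thresholds = SWEEP_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)
    rows = []
    for t in thresholds:
        counts = confusion_at_threshold(probs, labels, float(t))
        row = {"threshold": float(t), **compute_metrics(counts)}
        rows.append(row)
    out = pd.DataFrame(rows)
    out["auc"] = auc_score(probs, labels)
    return out


@dataclass
class BootstrapReport:
    """Per-threshold mean ± SD of sensitivity/specificity over bootstrap
    trials, plus the AUC distribution and the full-sample AUC."""

    table: pd.DataFrame      # threshold, sensitivity_mean/sd, specificity_mean/sd, n_defined
    auc_mean: float
    auc_sd: float
    auc_full: float
    n_trials: int
    block_length: int

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "auc_full": self.auc_full,
            "n_trials": self.n_trials,
            "block_length": self.block_length,
        }


def block_bootstrap_indices(n: int, block_length: int, rng: np.random.Generator) -> np.ndarray:
    """One trial's index sequence: ceil(n / L) contiguous blocks of length L
    drawn uniformly from start positions 0 .. n - L, concatenated and
    truncated to n."""
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n - block_length + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()
    return idx[:n]


def block_bootstrap(probs, labels, n_trials: int = 30,
                    rng: np.random.Generator | None = None) -> BootstrapReport:
    """Moving-block bootstrap of the threshold sweep and AUC.

    Block length is floor(sqrt(n_test)). Trials where a metric is undefined
    at some threshold (e.g. a resample without positives) are excluded from
    that cell's aggregation, with a logged count.
    """
    probs, labels = _check_aligned(probs, labels)
    n = len(probs)
    if n < 4:
        raise EvaluationError("need at least 4 test windows to bootstrap")
    rng = rng if rng is not None else np.random.default_rng(0)
    block_length = max(1, int(np.floor(np.sqrt(n))))
    sens = np.full((n_trials, len(SWEEP_THRESHOLDS)), np.nan)
    spec = np.full((n_trials, len(SWEEP_THRESHOLDS)), np.nan)
    aucs = np.full(n_trials, np.nan)
    for trial in range(n_trials):
        idx = block_bootstrap_indices(n, block_length, rng)
        p, y = probs[idx], labels[idx]
        aucs[trial] = auc_score(p, y)
        for j, t in enumerate(SWEEP_THRESHOLDS):
            m = compute_metrics(confusion_at_threshold(p, y, float(t)))
            sens[trial, j] = m["sensitivity"]
            spec[trial, j] = m["specificity"]
    n_undef = int(np.isnan(sens).sum() + np.isnan(spec).sum() + np.isnan(aucs).sum())
    if n_undef:
        logger.info("%d undefined metric cells excluded from bootstrap aggregation", n_undef)
    with np.errstate(invalid="ignore"):
        table = pd.DataFrame(
            {
                "threshold": SWEEP_THRESHOLDS,
                "sensitivity_mean": np.nanmean(sens, axis=0),
                "sensitivity_sd": np.nanstd(sens, axis=0, ddof=0),
                "specificity_mean": np.nanmean(spec, axis=0),
                "specificity_sd": np.nanstd(spec, axis=0, ddof=0),
                "n_defined_sensitivity": np.sum(~np.isnan(sens), axis=0),
                "n_defined_specificity": np.sum(~np.isnan(spec), axis=0),
            }
        )
        defined_aucs = aucs[~np.isnan(aucs)]
        auc_mean = float(np.mean(defined_aucs)) if defined_aucs.size else np.nan
        auc_sd = float(np.std(defined_aucs, ddof=0)) if defined_aucs.size else np.nan
    return BootstrapReport(
        table=table,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        auc_full=auc_score(probs, labels),
        n_trials=n_trials,
        block_length=block_length,
    )


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    feasible: bool
    sensitivity: float
    specificity: float


def select_operating_threshold(train_sweep: pd.DataFrame, mode: str = "prefer_specificity",
                               floor: float = 0.5) -> ThresholdChoice:
    """Constrained operating-point selection on a (training) threshold sweep.

    ``prefer_specificity``: maximize specificity subject to sensitivity >=
    floor; ``prefer_sensitivity``: the converse. Ties break toward the
    threshold nearest 0.5. If no row satisfies the constraint, the choice is
    flagged infeasible and the row maximizing the *constrained* metric is
    returned instead.
    """
    if train_sweep.empty:
        raise EvaluationError("empty threshold sweep")
    if mode == "prefer_specificity":
        objective, constraint = "specificity", "sensitivity"
    elif mode == "prefer_sensitivity":
        objective, constraint = "sensitivity", "specificity"
    else:
        raise EvaluationError(f"unknown mode {mode!r}")
    sweep = train_sweep.dropna(subset=[objective, constraint])
    if sweep.empty:
        raise EvaluationError("no rows with both metrics defined")

    def _pick(frame: pd.DataFrame, column: str) -> pd.Series:
        best = frame[frame[column] == frame[column].max()]
        dist = (best["threshold"] - 0.5).abs()
        return best.loc[dist.idxmin()]

    feasible = sweep[sweep[constraint] >= floor]
    if len(feasible):
        row = _pick(feasible, objective)
        ok = True
    else:
        row = _pick(sweep, constraint)
        ok = False
    return ThresholdChoice(
        threshold=float(row["threshold"]),
        feasible=ok,
        sensitivity=float(row["sensitivity"]),
        specificity=float(row["specificity"]),
    )
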