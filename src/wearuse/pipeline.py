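"""End-to-end orchestration: simulate → featurize → label → preprocess →
train (supervised and/or SSL) → evaluate, independently per participant.

Each participant's classifiers are trained exclusively on that participant's
data ("personalized" modeling); participants reporting fewer than a minimum
number of use instances (default 10) are skipped, mirroring typical
eligibility rules for such studies. All randomness derives from one pipeline
seed, so a rerun from the same configuration reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, labels, models, preprocess, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ParticipantResult",
    "validate_config",
    "featurize_streams",
    "labels_for_matrix",
    "run_participant_experiment",
    "run_pipeline",
]

#: Fine threshold grid used for operating-point selection on training output.
FINE_THRESHOLDS = np.round(np.arange(0.01, 1.0, 0.01), 10)


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    durations: dict = field(default_factory=lambda: dict(labels.DEFAULT_EFFECT_DURATIONS))
    train_fraction: float = 0.7
    oversample_ratio: float = 0.5
    segment_hours: int = 24
    train: models.TrainConfig = field(default_factory=models.TrainConfig)
    ssl: models.SslConfig = field(default_factory=models.SslConfig)
    n_bootstrap: int = 30
    model_variants: tuple[str, ...] = ("cnn", "ssl")
    min_use_instances: int = 10
    enforce_eligibility: bool = True
    out_dir: str = "runs"

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _build_config(raw: dict) -> tuple[PipelineConfig | None, list[str]]:
    errors: list[str] = []

    def _sub(cls, key):
        params = dict(raw.get(key, {}) or {})
        if key == "cohort" and "substances" in params:
            params["substances"] = tuple(params["substances"])
        try:
            return cls(**params)
        except TypeError as exc:
            errors.append(f"{key}: {exc}")
        except (ValueError, models.ModelError) as exc:
            errors.append(f"{key}: {exc}")
        return None

    cohort = _sub(synthetic.CohortConfig, "cohort")
    train = _sub(models.TrainConfig, "model")
    ssl = _sub(models.SslConfig, "ssl")
    durations = {
        str(k).lower(): int(v)
        for k, v in (raw.get("durations") or labels.DEFAULT_EFFECT_DURATIONS).items()
    }
    for sub, d in durations.items():
        if d < 1:
            errors.append(f"durations.{sub}: duration must be >= 1 hour")
    if cohort is not None:
        for sub in cohort.substances:
            if sub.strip().lower() not in durations:
                errors.append(f"durations: missing substance {sub!r}")
    train_fraction = float(raw.get("train_fraction", 0.7))
    if not (0.0 < train_fraction < 1.0):
        errors.append("train_fraction: must be in (0, 1)")
    over = dict(raw.get("oversample", {}) or {})
    oversample_ratio = float(over.get("target_ratio", 0.5))
    if not (0.0 < oversample_ratio < 1.0):
        errors.append("oversample.target_ratio: must be in (0, 1)")
    segment_hours = int(over.get("segment_hours", 24))
    if segment_hours < 1:
        errors.append("oversample.segment_hours: must be >= 1")
    ev = dict(raw.get("evaluation", {}) or {})
    n_bootstrap = int(ev.get("n_trials", 30))
    if n_bootstrap < 1:
        errors.append("evaluation.n_trials: must be >= 1")
    variants = tuple(raw.get("models", ("cnn", "ssl")))
    for v in variants:
        if v not in ("cnn", "ssl"):
            errors.append(f"models: unknown variant {v!r}")
    if errors or cohort is None or train is None or ssl is None:
        return None, errors
    return (
        PipelineConfig(
            cohort=cohort,
            durations=durations,
            train_fraction=train_fraction,
            oversample_ratio=oversample_ratio,
            segment_hours=segment_hours,
            train=train,
            ssl=ssl,
            n_bootstrap=n_bootstrap,
            model_variants=variants,
            min_use_instances=int(raw.get("min_use_instances", 10)),
            enforce_eligibility=bool(raw.get("enforce_eligibility", True)),
            out_dir=str(raw.get("out_dir", "runs")),
        ),
        [],
    )


def validate_config(config_path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML pipeline configuration.

    Returns ``(config, [])`` on success or ``(None, errors)`` where each
    error names the offending field. No pipeline stage is executed.
    """
    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        return None, [f"unparsable YAML: {exc}"]
    if not isinstance(raw, dict):
        return None, ["configuration root must be a mapping"]
    return _build_config(raw)


# ---------------------------------------------------------------------------
# in-memory per-participant experiment
# ---------------------------------------------------------------------------

def featurize_streams(streams: synthetic.RawStreams, monitoring_days: int) -> pd.DataFrame:
    """Engineered hourly feature matrix for one participant's streams."""
    return features.assemble_feature_matrix(
        features.aggregate_hr_hourly(streams.hr),
        features.aggregate_steps_hourly(streams.steps),
        features.spo2_daily_features(streams.spo2),
        features.sleep_daily_features(streams.sleep, streams.hrv),
        start=synthetic.EPOCH,
        periods=monitoring_days * 24,
    )


def labels_for_matrix(ema_log: pd.DataFrame, matrix: pd.DataFrame,
                      durations: dict[str, int]) -> tuple[pd.Series, list]:
    """Hourly labels aligned to a feature matrix, from an in-memory EMA log."""
    events = labels.events_from_log(ema_log)
    use_hours = labels.expand_use_events(events, durations)
    return labels.build_hourly_labels(use_hours, matrix.index), events


@dataclass
class ParticipantResult:
    participant: int
    n_use_instances: int
    eligible: bool
    selection: preprocess.FeatureSelection | None = None
    reports: dict = field(default_factory=dict)        # variant -> BootstrapReport
    test_probs: dict = field(default_factory=dict)     # variant -> np.ndarray
    test_labels: np.ndarray | None = None
    operating: dict = field(default_factory=dict)      # variant -> ThresholdChoice
    skipped_reason: str | None = None

    def summary_row(self) -> dict:
        row: dict = {"participant": self.participant,
                     "n_use_instances": self.n_use_instances}
        for variant, report in self.reports.items():
            at_half = report.table[np.isclose(report.table["threshold"], 0.5)].iloc[0]
            row[f"{variant}_specificity"] = float(at_half["specificity_mean"])
            row[f"{variant}_sensitivity"] = float(at_half["sensitivity_mean"])
            row[f"{variant}_auc"] = report.auc_full
            row[f"{variant}_auc_boot_mean"] = report.auc_mean
        return row


def run_participant_experiment(
    config: PipelineConfig, participant_index: int, enforce_eligibility: bool | None = None
) -> ParticipantResult:
    """Generate, featurize, label, preprocess, train and evaluate one participant."""
    cohort = config.cohort
    streams, ema, _truth = synthetic.generate_participant(cohort, participant_index)
    matrix = featurize_streams(streams, cohort.monitoring_days)
    y, events = labels_for_matrix(ema, matrix, config.durations)
    result = ParticipantResult(participant_index, len(events), True)
    enforce = config.enforce_eligibility if enforce_eligibility is None else enforce_eligibility
    if enforce and len(events) < config.min_use_instances:
        result.eligible = False
        result.skipped_reason = (
            f"only {len(events)} use instances (< {config.min_use_instances})"
        )
        logger.warning("Participant %d skipped: %s", participant_index, result.skipped_reason)
        return result

    seed = (int(config.train.seed) * 1000003 + participant_index) & 0x7FFFFFFF
    prep = preprocess.preprocess_participant(
        matrix, y,
        train_fraction=config.train_fraction,
        target_ratio=config.oversample_ratio,
        segment_hours=config.segment_hours,
        rng_seed=seed,
    )
    result.selection = prep.selection
    result.test_labels = prep.test.labels
    train_cfg = models.TrainConfig(**{**asdict(config.train), "seed": seed})

    trained: dict[str, models.TrainedClassifier] = {}
    if "cnn" in config.model_variants:
        trained["cnn"] = models.train_supervised(prep.train, train_cfg, val_windows=prep.val)
    if "ssl" in config.model_variants:
        backbone, _ = models.pretrain_ssl(models.CnnSpec(), prep.train_raw, config.ssl, train_cfg)
        trained["ssl"] = models.finetune_transferred(
            backbone, prep.train, train_cfg, config.ssl, val_windows=prep.val
        )

    for variant, clf in trained.items():
        probs = models.predict_probabilities(clf, prep.test)
        result.test_probs[variant] = probs
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, len(variant)]))
        result.reports[variant] = evaluation.block_bootstrap(
            probs, prep.test.labels, n_trials=config.n_bootstrap, rng=rng
        )
        train_probs = models.predict_probabilities(clf, prep.train_raw)
        train_sweep = evaluation.threshold_sweep(
            train_probs, prep.train_raw.labels, thresholds=FINE_THRESHOLDS
        )
        try:
            result.operating[variant] = evaluation.select_operating_threshold(train_sweep)
        except evaluation.EvaluationError:
            pass
    return result


# ---------------------------------------------------------------------------
# on-disk run
# ---------------------------------------------------------------------------

def _write_participant_artifacts(part_dir: Path, streams, ema, matrix, y, result):
    synthetic.write_fixtures(streams, ema, part_dir)
    matrix.to_csv(part_dir / "features.csv")
    y.rename("label").to_frame().to_csv(part_dir / "labels.csv", index_label="hour_index")
    if result.selection is not None:
        (part_dir / "selection.json").write_text(
            json.dumps(
                {
                    "importance": result.selection.importance,
                    "retained": result.selection.retained,
                    "threshold": result.selection.threshold,
                    "fallback_used": result.selection.fallback_used,
                },
                indent=2,
            )
        )
    for variant, report in result.reports.items():
        (part_dir / f"report_{variant}.json").write_text(
            json.dumps(_as_jsonable(report.to_dict()), indent=2)
        )
        report.table.to_csv(part_dir / f"table_{variant}.csv", index=False)
        pd.DataFrame(
            {"probability": result.test_probs[variant], "label": result.test_labels}
        ).to_csv(part_dir / f"probs_test_{variant}.csv", index=False)
    if result.operating:
        (part_dir / "operating_thresholds.json").write_text(
            json.dumps({v: asdict(c) for v, c in result.operating.items()}, indent=2)
        )


def run_pipeline(config: PipelineConfig, run_name: str | None = None) -> pd.DataFrame:
    """Run the full per-participant pipeline and write artifacts.

    Artifacts go under ``<out_dir>/<run_name>`` (default: a timestamped
    name). A failing stage aborts only that participant. Returns the summary
    table (one row per processed participant)."""
    run_name = run_name or datetime.now().strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(config.out_dir) / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "manifest.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "rng_seed": config.cohort.rng_seed,
                "train_seed": config.train.seed,
                "n_participants": config.cohort.n_participants,
                "model_variants": list(config.model_variants),
            },
            indent=2,
        )
    )
    rows = []
    for i in range(config.cohort.n_participants):
        part_dir = run_dir / f"participant_{i:02d}"
        part_dir.mkdir(exist_ok=True)
        try:
            streams, ema, _ = synthetic.generate_participant(config.cohort, i)
            matrix = featurize_streams(streams, config.cohort.monitoring_days)
            y, _ = labels_for_matrix(ema, matrix, config.durations)
            result = run_participant_experiment(config, i)
            _write_participant_artifacts(part_dir, streams, ema, matrix, y, result)
            if result.eligible:
                rows.append(result.summary_row())
            else:
                (part_dir / "skipped.txt").write_text(result.skipped_reason or "skipped")
        except Exception as exc:  # continue the cohort on per-participant failure
            logger.error("Participant %d failed: %s", i, exc)
            (part_dir / "failed.txt").write_text(str(exc))
    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "summary.csv", index=False)
    return summary
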