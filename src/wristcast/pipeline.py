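"""End-to-end orchestration: SQI → segments → labels → LSTM → forecast → stats.

`run_forecast_experiment` is the single entry point used by the CLI and the
test suite: given a recording and seizure annotations (real files or the
synthetic generator's output) it computes quality indices, assembles the
17-channel segments, labels them, picks the chronological split, trains the
classifier on the balanced training set, calibrates the operating threshold
on training forecasts, and evaluates the test interval with AUC, sensitivity,
time in warning, alert lead time, the Poisson chance-predictor p-value and
interval-preserving surrogate AUCs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import yaml

from . import evaluation, stats
from .e4_io import Modality, MultimodalRecording, SeizureAnnotations
from .labeling import (LabelingRules, SplitSpec, augment_preictal, choose_split,
                       find_lead_seizures, label_batch)
from .model import (LSTMForecaster, ModelConfig, TrainConfig, predict,
                    save_checkpoint, train)
from .preprocessing import (LABEL_INTERICTAL, LABEL_PREICTAL,
                            SegmentBatch, apply_normalization, assemble_segments,
                            fit_normalization)
from .signal_quality import (QualitySeries, SQIThresholds, acc_sqi, bvp_sqi,
                             eda_sqi)

logger = logging.getLogger("wristcast")

__all__ = ["PipelineConfig", "compute_quality", "prepare_batches",
           "run_forecast_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one experiment (fully serializable)."""

    thresholds: SQIThresholds = field(default_factory=SQIThresholds)
    rules: LabelingRules = field(default_factory=LabelingRules)
    # segments arrive pre-decimated by assembly_stride, so the model itself
    # applies no further decimation by default
    model: ModelConfig = field(default_factory=lambda: ModelConfig(temporal_stride=1))
    training: TrainConfig = field(default_factory=TrainConfig)
    assembly_stride: int = 16       # decimation applied when segments are built
    timezone: str = "UTC"
    min_train_seizures: int = 4
    min_train_preictal_segments: int = 240
    interictal_cap_ratio: float = 6.0   # max interictal:preictal ratio kept in training
    target_time_in_warning: float = 7.0  # h/day, used to calibrate the threshold
    n_surrogates: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def compute_quality(recording: MultimodalRecording,
                    thresholds: SQIThresholds = SQIThresholds()) -> dict[str, QualitySeries]:
    """Per-minute EDA/BVP/ACC quality series over all sessions of a recording."""
    def _concat(series: list[QualitySeries], modality: str) -> QualitySeries:
        if not series:
            return QualitySeries(modality, np.empty(0), np.empty(0), np.empty(0, bool))
        return QualitySeries(modality,
                             np.concatenate([s.minute_start_times for s in series]),
                             np.concatenate([s.sqi for s in series]),
                             np.concatenate([s.good for s in series]))

    eda = [eda_sqi(tr, thresholds) for tr in recording.traces.get(Modality.EDA, [])]
    bvp = [bvp_sqi(tr, thresholds) for tr in recording.traces.get(Modality.BVP, [])]
    acc = [acc_sqi(x, y, z, thresholds)
           for x, y, z in zip(recording.traces.get(Modality.ACCX, []),
                              recording.traces.get(Modality.ACCY, []),
                              recording.traces.get(Modality.ACCZ, []))]
    return {"EDA": _concat(eda, "EDA"), "BVP": _concat(bvp, "BVP"),
            "ACC": _concat(acc, "ACC")}


def prepare_batches(recording: MultimodalRecording,
                    annotations: SeizureAnnotations,
                    config: PipelineConfig
                    ) -> dict[str, Any]:
    """Quality, segments, labels and chronological split for one recording."""
    quality = compute_quality(recording, config.thresholds)
    batch, excluded_starts = assemble_segments(
        recording, quality, stride=config.assembly_stride, timezone=config.timezone)
    leads, clustered = find_lead_seizures(annotations, config.rules)
    batch = label_batch(batch, leads, annotations, config.rules)
    split = choose_split(recording, annotations, config.rules,
                         config.min_train_seizures, config.min_train_preictal_segments)
    train_mask = batch.start_times + 60.0 <= split.cutoff_time
    return {"quality": quality, "batch": batch, "excluded_starts": excluded_starts,
            "leads": leads, "clustered": clustered, "split": split,
            "train_batch": batch.subset(train_mask),
            "test_batch": batch.subset(~train_mask)}


def _training_subset(train_batch: SegmentBatch, cap_ratio: float,
                     seed: int) -> SegmentBatch:
    """Labeled training segments with the interictal class capped at
    ``cap_ratio`` times the preictal count (seeded subsample)."""
    labels = train_batch.labels
    pre_idx = np.flatnonzero(labels == LABEL_PREICTAL)
    int_idx = np.flatnonzero(labels == LABEL_INTERICTAL)
    if pre_idx.size == 0:
        raise ValueError("no preictal training segments")
    max_inter = int(cap_ratio * pre_idx.size)
    if int_idx.size > max_inter:
        rng = np.random.default_rng(seed)
        int_idx = np.sort(rng.choice(int_idx, size=max_inter, replace=False))
    keep = np.zeros(len(train_batch), dtype=bool)
    keep[pre_idx] = True
    keep[int_idx] = True
    return train_batch.subset(keep)


def run_forecast_experiment(recording: MultimodalRecording,
                            annotations: SeizureAnnotations,
                            config: PipelineConfig = PipelineConfig(),
                            checkpoint_path=None) -> dict[str, Any]:
    """Full train-then-evaluate experiment on one recording.

    Returns a dictionary with the trained model, loss history, forecast
    traces, the evaluation summary, and the statistics report
    (Poisson chance p-value, surrogate AUC mean/sd, sensitivity improvement).
    All randomness (interictal subsampling, augmentation, initialization,
    dropout, shuffling, surrogates) derives from ``config.seed``.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    s_sub, s_aug, s_model, s_train, s_surr = (
        int(s % (2**31)) for s in seed_seq.generate_state(5))

    prep = prepare_batches(recording, annotations, config)
    split: SplitSpec = prep["split"]
    leads: SeizureAnnotations = prep["leads"]
    logger.info("split cutoff at %.0f (%d lead seizures total)",
                split.cutoff_time, len(leads))

    train_sel = _training_subset(prep["train_batch"], config.interictal_cap_ratio, s_sub)
    norm_stats = fit_normalization(train_sel)
    train_aug = augment_preictal(train_sel, seed=s_aug)
    train_aug = apply_normalization(train_aug, norm_stats)

    model = LSTMForecaster(replace(config.model,
                                   n_channels=len(train_aug.channels), seed=s_model))
    y = (train_aug.labels == LABEL_PREICTAL).astype(np.float32)
    history = train(model, train_aug.segments, y,
                    replace(config.training, seed=s_train))

    # threshold calibrated on training-interval forecasts only
    train_all_n = apply_normalization(prep["train_batch"], norm_stats)
    train_probs = predict(model, train_all_n.segments)
    train_trace = evaluation.aggregate(train_all_n.start_times, train_probs,
                                       train_all_n.labels)
    threshold = evaluation.calibrate_threshold(train_trace,
                                               config.target_time_in_warning)

    test_n = apply_normalization(prep["test_batch"], norm_stats)
    test_probs = predict(model, test_n.segments)
    test_leads = SeizureAnnotations(leads.onsets[leads.onsets >= split.cutoff_time],
                                    leads.source)
    test_trace, summary = evaluation.evaluate_forecast(
        test_n.start_times, test_probs, test_n.labels, test_leads,
        threshold, config.rules)

    # chance predictor + surrogate null
    chance = stats.chance_model_from_warning(
        summary.warning_fraction,
        evaluation.mean_warning_duration(test_trace, threshold) or 3600.0,
        horizon=config.rules.preictal_len)
    p_value = stats.snyder_pvalue(summary.n_hit, summary.n_seizures, chance) \
        if summary.n_seizures else float("nan")
    improvement = stats.improvement_over_chance(summary.sensitivity, chance) \
        if summary.n_seizures else float("nan")

    surrogate_aucs = surrogate_hourly_aucs(
        test_trace, test_leads, recording.span, config, seed=s_surr)

    report = {
        "auc": summary.auc,
        "sensitivity": summary.sensitivity,
        "time_in_warning_h_per_day": summary.time_in_warning,
        "mean_alert_lead_min": summary.mean_alert_lead,
        "n_seizures": summary.n_seizures,
        "n_hit": summary.n_hit,
        "threshold": threshold,
        "p_value": p_value,
        "sensitivity_improvement": improvement,
        "random_auc_mean": float(np.nanmean(surrogate_aucs)) if surrogate_aucs.size else float("nan"),
        "random_auc_sd": float(np.nanstd(surrogate_aucs)) if surrogate_aucs.size else float("nan"),
        "config_hash": config.config_hash,
    }
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return {"model": model, "history": history, "norm_stats": norm_stats,
            "split": split, "threshold": threshold,
            "train_trace": train_trace, "test_trace": test_trace,
            "summary": summary, "report": report,
            "surrogate_aucs": surrogate_aucs, "prep": prep}


def surrogate_hourly_aucs(test_trace: evaluation.ForecastTrace,
                          test_leads: SeizureAnnotations,
                          span: tuple[float, float],
                          config: PipelineConfig,
                          seed: int = 0) -> np.ndarray:
    """Hourly AUC of the fixed forecast against randomized seizure times.

    Each surrogate permutes the inter-seizure intervals of the test-interval
    lead seizures; hour labels are re-derived from the surrogate onsets and
    the unchanged hourly scores are re-scored.  AUCs near 0.5 indicate the
    forecast carries no information about arbitrary (non-seizure) times.
    """
    if len(test_leads) < 2 or test_trace.hour_times.size == 0:
        return np.empty(0)
    lo = max(span[0], float(test_trace.hour_times.min()))
    hi = min(span[1], float(test_trace.hour_times.max()) + 3600.0)
    surr = stats.surrogate_seizure_times(test_leads, (lo, hi),
                                         n_reps=config.n_surrogates, seed=seed)
    aucs = []
    from .labeling import label_timeline
    for rep in surr.replicates:
        ann = SeizureAnnotations(rep, "surrogate")
        rep_leads, _ = find_lead_seizures(ann, config.rules)
        labels = label_timeline(test_trace.minute_times, rep_leads, ann, config.rules)
        trace = evaluation.aggregate(test_trace.minute_times,
                                     test_trace.minute_probs, labels)
        try:
            aucs.append(evaluation.hourly_auc(trace))
        except ValueError:
            aucs.append(np.nan)
    return np.asarray(aucs)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
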