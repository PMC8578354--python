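"""Leave-one-signal-out feature importance.

Each wearable signal contributes a group of input channels (its time series,
derived FFT channel, and quality index where one exists).  Importance is
measured by retraining the classifier with one group removed and subtracting
the resulting hourly AUC from the full model's: ΔAUC > 0 means the signal
helps.  Because weight initialization is random, every variant (including the
full model) is trained ``n_reps`` times with seeds derived deterministically
from a master seed, and the mean difference is reported.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd


from .evaluation import aggregate, hourly_auc
from .labeling import augment_preictal
from .model import LSTMForecaster, ModelConfig, TrainConfig, predict, train
from .preprocessing import (CHANNELS, LABEL_PREICTAL, SegmentBatch,
                            apply_normalization, fit_normalization)

__all__ = ["SIGNAL_GROUPS", "feature_importance"]

#: Channel groups per wearable signal; together they partition the 17 channels.
SIGNAL_GROUPS: dict[str, tuple[str, ...]] = {
    "ACC": ("ACCX", "ACCY", "ACCZ", "ACCMag", "FFT_ACCMag", "SQI_ACC"),
    "BVP": ("BVP", "FFT_BVP", "SQI_BVP"),
    "EDA": ("EDA", "FFT_EDA", "SQI_EDA"),
    "TEMP": ("TEMP", "FFT_TEMP"),
    "HR": ("HR", "FFT_HR"),
    "TIME_OF_DAY": ("TIME_OF_DAY",),
}

assert tuple(c for g in SIGNAL_GROUPS.values() for c in g) == CHANNELS or \
    sorted(c for g in SIGNAL_GROUPS.values() for c in g) == sorted(CHANNELS)


def _run_variant(train_batch: SegmentBatch, test_batch: SegmentBatch,
                 removed: tuple[str, ...], seed: int,
                 model_config: ModelConfig, train_config: TrainConfig) -> float:
    """Train one model without ``removed`` channels; return hourly test AUC."""
    tb = train_batch.drop_channels(removed) if removed else train_batch
    eb = test_batch.drop_channels(removed) if removed else test_batch
    stats = fit_normalization(tb)  # refit per variant: uniform contract
    aug = augment_preictal(tb, seed=seed)
    aug = apply_normalization(aug, stats)
    eb_n = apply_normalization(eb, stats)
    mc = replace(model_config, n_channels=len(tb.channels), seed=seed)
    tc = replace(train_config, seed=seed)
    model = LSTMForecaster(mc)
    y = (aug.labels == LABEL_PREICTAL).astype(np.float32)
    train(model, aug.segments, y, tc)
    probs = predict(model, eb_n.segments)
    trace = aggregate(eb_n.start_times, probs, eb_n.labels)
    return hourly_auc(trace)


def feature_importance(train_batch: SegmentBatch, test_batch: SegmentBatch,
                       groups: dict[str, tuple[str, ...]] = SIGNAL_GROUPS,
                       n_reps: int = 5, master_seed: int = 0,
                       model_config: ModelConfig = ModelConfig(),
                       train_config: TrainConfig = TrainConfig()
                       ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-signal ΔAUC by leave-one-group-out retraining.

    ``train_batch`` holds labeled (unnormalized, unaugmented) training
    segments; ``test_batch`` labeled test segments.  Every variant shares the
    identical split; normalization is refit on the reduced channel set; the
    full model is itself re-averaged over the same ``n_reps`` seeds.  Returns
    a tidy frame (group, delta_auc_mean, delta_auc_sd, n_reps) and the raw
    per-rep AUCs (including the ``"full"`` reference, which is never mutated
    by ablation runs).
    """
    for name, chans in groups.items():
        if set(chans) >= set(train_batch.channels):
            raise ValueError(f"group {name!r} would remove every channel")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_reps) % (2**31)
    aucs: dict[str, np.ndarray] = {}
    aucs["full"] = np.array([
        _run_variant(train_batch, test_batch, (), int(s), model_config, train_config)
        for s in seeds])
    rows = []
    for name, chans in groups.items():
        removed = tuple(c for c in chans if c in train_batch.channels)
        vals = np.array([
            _run_variant(train_batch, test_batch, removed, int(s), model_config, train_config)
            for s in seeds])
        aucs[name] = vals
        delta = aucs["full"].mean() - vals
        rows.append({"group": name,
                     "delta_auc_mean": float(aucs["full"].mean() - vals.mean()),
                     "delta_auc_sd": float(delta.std(ddof=1)) if n_reps > 1 else 0.0,
                     "n_reps": n_reps})
    return pd.DataFrame(rows), aucs
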