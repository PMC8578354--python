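"""Preictal/interictal labeling, lead-seizure filtering, split and augmentation.

A *lead* seizure has no preceding seizure within 4 h; clustered (non-lead)
seizures are excluded so a run of seizures does not inflate performance.  For
each lead seizure the preictal window is the hour ending 15 min before the
EEG-confirmed onset, i.e. [onset − 75 min, onset − 15 min): the 15-min
set-back guards against early seizure detection masquerading as forecasting
and absorbs wearable/implant clock misalignment.  Minutes inside the set-back,
the seizure itself and a post-ictal exclusion zone after every onset (default
4 h, configurable to 0) are excluded; everything else is interictal.

The train/test split is chronological: the cutoff starts at one third of the
record duration and is advanced until at least four lead seizures and at least
240 preictal minutes precede it.  Class balance in training is restored by
appending noise-added copies of preictal segments (uniform [0, 1) noise scaled
by the per-channel median of the segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .e4_io import MultimodalRecording, SeizureAnnotations
from .preprocessing import (LABEL_EXCLUDED, LABEL_INTERICTAL, LABEL_PREICTAL,
                            SEGMENT_SECONDS, SegmentBatch)

__all__ = [
    "LabelingRules",
    "SplitSpec",
    "find_lead_seizures",
    "label_timeline",
    "label_batch",
    "choose_split",
    "augment_preictal",
]

LABEL_NAMES = {LABEL_INTERICTAL: "interictal", LABEL_PREICTAL: "preictal",
               LABEL_EXCLUDED: "excluded"}


@dataclass(frozen=True)
class LabelingRules:
    """Durations (seconds) defining the label geometry.

    preictal_len 60 min, setback 15 min → preictal = [onset−75, onset−15) min;
    lead_gap 4 h separates lead from clustered seizures; postictal_exclusion
    removes the recovery period after every onset from the interictal class.
    """

    preictal_len: float = 60 * 60.0
    setback: float = 15 * 60.0
    lead_gap: float = 4 * 3600.0
    postictal_exclusion: float = 4 * 3600.0

    def __post_init__(self) -> None:
        if min(self.preictal_len, self.setback, self.lead_gap) <= 0:
            raise ValueError("durations must be positive")
        if self.postictal_exclusion < 0:
            raise ValueError("postictal_exclusion must be >= 0")

    @property
    def preictal_start_offset(self) -> float:
        """Seconds before onset at which the preictal window opens (75 min)."""
        return self.preictal_len + self.setback


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/test cutoff and the constraints that shaped it."""

    cutoff_time: float
    min_train_seizures: int = 4
    min_train_preictal_segments: int = 240


def find_lead_seizures(annotations: SeizureAnnotations,
                       rules: LabelingRules = LabelingRules()
                       ) -> tuple[SeizureAnnotations, SeizureAnnotations]:
    """Split onsets into lead and clustered seizures.

    An onset is lead iff its gap to the preceding onset is at least
    ``lead_gap`` (a gap of exactly 4 h still counts as lead); the first onset
    is always lead.  Returns ``(leads, excluded)``.
    """
    onsets = annotations.onsets
    if onsets.size == 0:
        return SeizureAnnotations(onsets, annotations.source), SeizureAnnotations(np.empty(0))
    gaps = np.diff(onsets)
    is_lead = np.concatenate([[True], gaps >= rules.lead_gap - 1e-9])
    return (SeizureAnnotations(onsets[is_lead], annotations.source),
            SeizureAnnotations(onsets[~is_lead], annotations.source))


def label_timeline(minute_starts: np.ndarray,
                   lead_seizures: SeizureAnnotations,
                   all_seizures: SeizureAnnotations,
                   rules: LabelingRules = LabelingRules()) -> np.ndarray:
    """Label each minute as interictal (0), preictal (1) or excluded (2).

    A minute [t, t+60) is preictal when it lies inside a lead seizure's
    [onset−75 min, onset−15 min) window; it is excluded when it overlaps the
    set-back [onset−15 min, onset], the post-ictal zone (onset,
    onset+postictal_exclusion], or the preictal window of a *clustered*
    seizure; everything else is interictal.  Exclusion wins over preictal.
    """
    t = np.asarray(minute_starts, dtype=np.float64)
    labels = np.full(t.size, LABEL_INTERICTAL, dtype=np.int8)
    leads = set(np.round(lead_seizures.onsets, 6).tolist())
    for onset in lead_seizures.onsets:
        pre0, pre1 = onset - rules.preictal_start_offset, onset - rules.setback
        labels[(t >= pre0 - 1e-9) & (t + SEGMENT_SECONDS <= pre1 + 1e-9)] = LABEL_PREICTAL
    for onset in all_seizures.onsets:
        ex0 = onset - rules.setback
        ex1 = onset + rules.postictal_exclusion
        labels[(t + SEGMENT_SECONDS > ex0 + 1e-9) & (t < ex1 - 1e-9)] = LABEL_EXCLUDED
        if round(float(onset), 6) not in leads:  # clustered: drop its preictal window too
            pre0, pre1 = onset - rules.preictal_start_offset, onset - rules.setback
            labels[(t + SEGMENT_SECONDS > pre0) & (t < pre1)] = LABEL_EXCLUDED
    return labels


def label_batch(batch: SegmentBatch, lead_seizures: SeizureAnnotations,
                all_seizures: SeizureAnnotations,
                rules: LabelingRules = LabelingRules()) -> SegmentBatch:
    """Return the batch with labels assigned from the seizure annotations."""
    labels = label_timeline(batch.start_times, lead_seizures, all_seizures, rules)
    return SegmentBatch(batch.segments, batch.start_times, labels,
                        batch.stride, batch.channels, batch.augmented)


def export_label_track(minute_starts: np.ndarray, labels: np.ndarray, path) -> None:
    """Write the label track as an interval CSV (start_unix, end_unix, label)."""
    df = pd.DataFrame({
        "start_unix": minute_starts,
        "end_unix": np.asarray(minute_starts) + SEGMENT_SECONDS,
        "label": [LABEL_NAMES[int(v)] for v in labels],
    })
    df.to_csv(path, index=False)


def choose_split(recording: MultimodalRecording,
                 annotations: SeizureAnnotations,
                 rules: LabelingRules = LabelingRules(),
                 min_train_seizures: int = 4,
                 min_train_preictal_segments: int = 240) -> SplitSpec:
    """Pick the chronological train/test cutoff.

    Starts at one third of the record span and advances to the earliest time
    at which at least ``min_train_seizures`` lead seizures and at least
    ``min_train_preictal_segments`` preictal minutes fall strictly before the
    cutoff.  Requires at least ``min_train_seizures + 1`` lead seizures in
    total so the test interval is non-trivial.
    """
    leads, _ = find_lead_seizures(annotations, rules)
    span0, span1 = recording.span
    if len(leads) < min_train_seizures + 1:
        raise ValueError(
            f"need at least {min_train_seizures + 1} lead seizures "
            f"(≥{min_train_seizures} for training plus ≥1 for testing), got {len(leads)}")

    minute_starts = span0 + SEGMENT_SECONDS * np.arange(int((span1 - span0) // SEGMENT_SECONDS))
    labels = label_timeline(minute_starts, leads, annotations, rules)
    pre_minutes = minute_starts[labels == LABEL_PREICTAL]

    def satisfied(cut: float) -> bool:
        n_sz = int(np.sum(leads.onsets < cut))
        n_pre = int(np.sum(pre_minutes + SEGMENT_SECONDS <= cut))
        return n_sz >= min_train_seizures and n_pre >= min_train_preictal_segments

    cutoff = span0 + (span1 - span0) / 3.0
    if not satisfied(cutoff):
        # candidate cutoffs: just after each lead onset (the constraint can only
        # change state there or as preictal minutes accumulate)
        for onset in leads.onsets:
            cand = onset + SEGMENT_SECONDS
            if cand > cutoff and satisfied(cand):
                cutoff = cand
                break
        else:
            raise ValueError(
                "no cutoff satisfies the training constraints "
                f"(≥{min_train_seizures} lead seizures and "
                f"≥{min_train_preictal_segments} preictal minutes before cutoff)")
    if cutoff >= span1:
        raise ValueError("cutoff falls at or beyond the end of the recording")
    return SplitSpec(float(cutoff), min_train_seizures, min_train_preictal_segments)


def augment_preictal(train: SegmentBatch, seed: int) -> SegmentBatch:
    """Balance classes by appending noise-added preictal copies.

    Each copy is ``original + U[0,1)·median(original per channel)`` with fresh
    uniform draws per sample; originals are untouched and copies carry the
    ``augmented`` flag (and the original's label and timestamp) so they can be
    audited out of any evaluation.  Requires interictal count ≥ preictal count.
    """
    rng = np.random.default_rng(seed)
    pre_idx = np.flatnonzero(train.labels == LABEL_PREICTAL)
    n_inter = int(np.sum(train.labels == LABEL_INTERICTAL))
    if pre_idx.size == 0:
        raise ValueError("no preictal segments to augment")
    n_copies = n_inter - pre_idx.size
    if n_copies < 0:
        raise ValueError("interictal:preictal ratio below 1; augmentation not applicable")
    if n_copies == 0:
        return train
    src = pre_idx[rng.integers(0, pre_idx.size, size=n_copies)]
    originals = train.segments[src]
    med = np.median(originals, axis=2, keepdims=True)
    noise = rng.random(originals.shape, dtype=np.float32)
    copies = originals + noise * med
    return SegmentBatch(
        np.concatenate([train.segments, copies]),
        np.concatenate([train.start_times, train.start_times[src]]),
        np.concatenate([train.labels, train.labels[src]]),
        train.stride, train.channels,
        np.concatenate([train.augmented, np.ones(n_copies, dtype=bool)]))
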