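"""Forecast aggregation and performance metrics.

Per-minute classifier probabilities are averaged over groups of five
consecutive 1-min segments (aligned to clock 5-min bins), and each clock hour
is scored with the maximum of its group means.  Performance is summarized by:

* **AUC-ROC** over hourly scores, an hour being preictal when it overlaps a
  lead seizure's preictal window;
* **sensitivity**: the fraction of lead seizures whose preictal window
  overlaps a warned hour at the chosen operating threshold;
* **time in warning** (h/day): how long the system spends in the alarmed
  state, normalized to a 24-h day;
* **mean alert lead**: minutes between the first warning within
  [onset − 75 min, onset] and the seizure onset, averaged over hits.

Hours with less than 45 min of scored minutes are dropped; hours whose valid
minutes are all excluded (ictal/post-ictal) take part in neither class.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .e4_io import SeizureAnnotations
from .labeling import LabelingRules
from .preprocessing import LABEL_EXCLUDED, LABEL_INTERICTAL, LABEL_PREICTAL

__all__ = [
    "ForecastTrace",
    "EvalSummary",
    "aggregate",
    "hourly_auc",
    "alarms_and_warning",
    "calibrate_threshold",
    "evaluate_forecast",
]

GROUP_SECONDS = 300
HOUR_SECONDS = 3600
#: minimum scored minutes for an hour to be evaluable
MIN_MINUTES_PER_HOUR = 45


@dataclass
class ForecastTrace:
    """Per-minute probabilities rolled up to 5-min group means and hourly scores."""

    minute_times: np.ndarray
    minute_probs: np.ndarray
    group_times: np.ndarray
    group_means: np.ndarray
    hour_times: np.ndarray          # hour start (UNIX s), evaluable hours only
    hourly_scores: np.ndarray       # max of the hour's group means
    hourly_labels: np.ndarray       # LABEL_PREICTAL / LABEL_INTERICTAL / LABEL_EXCLUDED
    minutes_per_hour: np.ndarray


@dataclass
class EvalSummary:
    """Headline forecast metrics at one operating threshold."""

    auc: float
    threshold: float
    sensitivity: float
    time_in_warning: float          # hours/day
    mean_alert_lead: float          # minutes; NaN when no seizure was hit
    n_seizures: int
    n_hit: int
    warning_fraction: float
    n_hours: int

    def to_dict(self) -> dict:
        return asdict(self)


def aggregate(minute_times: np.ndarray, minute_probs: np.ndarray,
              minute_labels: np.ndarray | None = None) -> ForecastTrace:
    """Roll per-minute probabilities up to 5-min groups and clock-hour scores.

    Group means are taken over whatever minutes of a clock-aligned 5-min bin
    are present; an hour is evaluable with ≥45 scored minutes.  The hour label
    is preictal if it contains any preictal minute, interictal if it contains
    an interictal minute and no preictal one, and excluded otherwise.
    """
    t = np.asarray(minute_times, dtype=np.float64)
    p = np.asarray(minute_probs, dtype=np.float64)
    if t.size != p.size:
        raise ValueError("times and probabilities must align")
    if minute_labels is None:
        minute_labels = np.full(t.size, LABEL_INTERICTAL, dtype=np.int8)
    labels = np.asarray(minute_labels)
    order = np.argsort(t)
    t, p, labels = t[order], p[order], labels[order]

    empty = np.empty(0)
    if t.size == 0:
        return ForecastTrace(t, p, empty, empty, empty, empty,
                             empty.astype(np.int8), empty.astype(int))

    g_id = np.floor_divide(t, GROUP_SECONDS).astype(np.int64)
    g_uniq, g_inv = np.unique(g_id, return_inverse=True)
    g_sum = np.bincount(g_inv, weights=p)
    g_cnt = np.bincount(g_inv)
    g_means = g_sum / g_cnt
    g_times = g_uniq.astype(np.float64) * GROUP_SECONDS

    h_of_group = np.floor_divide(g_uniq * GROUP_SECONDS, HOUR_SECONDS)
    h_uniq, h_inv = np.unique(h_of_group, return_inverse=True)
    scores = np.full(h_uniq.size, -np.inf)
    np.maximum.at(scores, h_inv, g_means)

    h_of_min = np.floor_divide(t, HOUR_SECONDS).astype(np.int64)
    h_min_inv = np.searchsorted(h_uniq, h_of_min)
    minutes_per_hour = np.bincount(h_min_inv, minlength=h_uniq.size)
    has_pre = np.bincount(h_min_inv, weights=(labels == LABEL_PREICTAL), minlength=h_uniq.size) > 0
    has_inter = np.bincount(h_min_inv, weights=(labels == LABEL_INTERICTAL), minlength=h_uniq.size) > 0
    h_labels = np.where(has_pre, LABEL_PREICTAL,
                        np.where(has_inter, LABEL_INTERICTAL, LABEL_EXCLUDED)).astype(np.int8)

    keep = minutes_per_hour >= MIN_MINUTES_PER_HOUR
    return ForecastTrace(t, p, g_times, g_means,
                         h_uniq[keep].astype(np.float64) * HOUR_SECONDS,
                         scores[keep], h_labels[keep], minutes_per_hour[keep])


def hourly_auc(trace: ForecastTrace) -> float:
    """AUC-ROC over evaluable hourly scores (ties count one half).

    Requires at least one preictal and one interictal hour.
    """
    mask = trace.hourly_labels != LABEL_EXCLUDED
    y = (trace.hourly_labels[mask] == LABEL_PREICTAL).astype(int)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("hourly AUC needs both preictal and interictal hours")
    return float(roc_auc_score(y, trace.hourly_scores[mask]))


def roc_points(trace: ForecastTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPR, TPR and thresholds of the hourly ROC curve (for plotting/export)."""
    mask = trace.hourly_labels != LABEL_EXCLUDED
    y = (trace.hourly_labels[mask] == LABEL_PREICTAL).astype(int)
    return roc_curve(y, trace.hourly_scores[mask])


def _warned_intervals(trace: ForecastTrace, threshold: float) -> list[tuple[float, float]]:
    """Merged [start, end) intervals of consecutive warned hours."""
    warned = trace.hour_times[trace.hourly_scores >= threshold]
    out: list[tuple[float, float]] = []
    for h in warned:
        if out and abs(out[-1][1] - h) < 1e-6:
            out[-1] = (out[-1][0], h + HOUR_SECONDS)
        else:
            out.append((h, h + HOUR_SECONDS))
    return out


def alarms_and_warning(trace: ForecastTrace, threshold: float,
                       lead_seizures: SeizureAnnotations,
                       rules: LabelingRules = LabelingRules()) -> EvalSummary:
    """Operating-point metrics: warnings, sensitivity, time in warning, lead time.

    A warning is on for every hour whose score reaches ``threshold``.  A lead
    seizure is hit when a warning is on at some point of its preictal window
    [onset − 75, onset − 15) min; the alert lead is measured from the first
    warned moment within [onset − 75 min, onset] to the onset.
    """
    n_hours = trace.hour_times.size
    warned = _warned_intervals(trace, threshold)
    n_warned_hours = sum(e - s for s, e in warned) / HOUR_SECONDS
    warning_fraction = n_warned_hours / n_hours if n_hours else 0.0

    hits = 0
    lead_minutes = []
    # only lead seizures whose preictal window is scored at all are assessable
    assessed = 0
    for onset in lead_seizures.onsets:
        pre0 = onset - rules.preictal_start_offset
        pre1 = onset - rules.setback
        scored = np.any((trace.minute_times >= pre0 - 1e-9) & (trace.minute_times < pre1))
        if not scored:
            continue
        assessed += 1
        hit = any(max(s, pre0) < min(e, pre1) for s, e in warned)
        if hit:
            hits += 1
            first_warn = min(max(s, pre0) for s, e in warned
                             if max(s, pre0) < min(e, onset))
            lead_minutes.append((onset - first_warn) / 60.0)

    sensitivity = hits / assessed if assessed else 0.0
    mean_lead = float(np.mean(lead_minutes)) if lead_minutes else float("nan")
    try:
        auc = hourly_auc(trace)
    except ValueError:
        auc = float("nan")
    return EvalSummary(auc=auc, threshold=float(threshold),
                       sensitivity=float(sensitivity),
                       time_in_warning=float(24.0 * warning_fraction),
                       mean_alert_lead=mean_lead,
                       n_seizures=assessed, n_hit=hits,
                       warning_fraction=float(warning_fraction),
                       n_hours=int(n_hours))


def mean_warning_duration(trace: ForecastTrace, threshold: float) -> float:
    """Mean contiguous warning-episode duration in seconds (0 if never warned)."""
    iv = _warned_intervals(trace, threshold)
    return float(np.mean([e - s for s, e in iv])) if iv else 0.0


def calibrate_threshold(train_trace: ForecastTrace,
                        target_time_in_warning: float = 7.0) -> float:
    """Operating threshold chosen on *training* forecasts.

    Picks the hourly-score quantile whose exceedance fraction matches the
    target time in warning (hours/day, default 7 within the plausible clinical
    range); evaluation never sees test scores when the threshold is set.
    """
    if train_trace.hourly_scores.size == 0:
        raise ValueError("cannot calibrate a threshold without training hours")
    frac = np.clip(target_time_in_warning / 24.0, 0.0, 1.0)
    return float(np.quantile(train_trace.hourly_scores, 1.0 - frac))


def evaluate_forecast(minute_times: np.ndarray, minute_probs: np.ndarray,
                      minute_labels: np.ndarray,
                      lead_seizures: SeizureAnnotations,
                      threshold: float,
                      rules: LabelingRules = LabelingRules()) -> tuple[ForecastTrace, EvalSummary]:
    """Aggregate minute probabilities and compute the full metric summary."""
    trace = aggregate(minute_times, minute_probs, minute_labels)
    return trace, alarms_and_warning(trace, threshold, lead_seizures, rules)
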