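"""Per-minute signal quality indices (SQI) for EDA, BVP and ACC.

Three modality-specific artifact detectors, each producing one value per
contiguous minute of data:

* **EDA** — rate of amplitude change between consecutive one-second windows.
  A second whose mean changes by at least +20% or −10% relative to the
  previous second is artifact (motion or poor electrode contact).  The
  per-minute SQI is the fraction of clean seconds.
* **BVP** — normalized spectral entropy of 1-min segments averaged over
  non-overlapping 4-s windows.  Clean photoplethysmography is pulsatile and
  spectrally concentrated (low entropy); a minute is good quality iff its
  entropy is strictly below 0.9.  SQI = 1 − entropy.
* **ACC** — ratio of narrowband "physiological" (0.8–5 Hz) to broadband
  (0.8 Hz–Nyquist) periodogram power of the acceleration magnitude, averaged
  over non-overlapping 4-s segments.

All indices lie in [0, 1] and are scale invariant.  Trailing partial minutes
are dropped, since downstream segments are strictly 60 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .e4_io import Modality, SignalTrace

__all__ = [
    "SQIThresholds",
    "QualitySeries",
    "eda_sqi",
    "bvp_spectral_entropy",
    "bvp_sqi",
    "acc_sqi",
]

#: numeric tolerance so a change of exactly the stated threshold counts as artifact
_EDGE = 1e-12


@dataclass(frozen=True)
class SQIThresholds:
    """Artifact-detection constants.

    eda_rise_frac / eda_fall_frac : per-second relative change beyond which an
        EDA second is artifact (+20% / −10%).
    bvp_entropy_cutoff : minutes with normalized spectral entropy below this
        are good-quality BVP.
    acc_band_lo, acc_band_hi : physiological accelerometry band in Hz.
    window_s : spectral window length (4 s, non-overlapping).
    epoch_s : SQI epoch length (60 s).
    """

    eda_rise_frac: float = 0.20
    eda_fall_frac: float = 0.10
    bvp_entropy_cutoff: float = 0.9
    acc_band_lo: float = 0.8
    acc_band_hi: float = 5.0
    window_s: float = 4.0
    epoch_s: float = 60.0
    eda_floor: float = 1e-6  # µS floor for the relative-change denominator

    def __post_init__(self) -> None:
        if not (0 < self.acc_band_lo < self.acc_band_hi):
            raise ValueError("need 0 < acc_band_lo < acc_band_hi")


@dataclass
class QualitySeries:
    """Per-minute SQI values for one modality.

    ``sqi`` is the continuous index in [0, 1]; ``good`` the binary
    good-quality flag.  ``minute_start_times`` are UNIX seconds.
    """

    modality: str
    minute_start_times: np.ndarray
    sqi: np.ndarray
    good: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start_times = np.asarray(self.minute_start_times, dtype=np.float64)
        self.sqi = np.asarray(self.sqi, dtype=np.float64)
        self.good = np.asarray(self.good, dtype=bool)
        if not (self.minute_start_times.size == self.sqi.size == self.good.size):
            raise ValueError("minute_start_times, sqi and good must align")
        if self.sqi.size and (self.sqi.min() < -1e-9 or self.sqi.max() > 1 + 1e-9):
            raise ValueError("sqi values must lie in [0, 1]")

    def value_at(self, minute_start: float, default: float = np.nan) -> float:
        idx = np.searchsorted(self.minute_start_times, minute_start - 1e-6)
        if idx < self.minute_start_times.size and abs(self.minute_start_times[idx] - minute_start) < 1.0:
            return float(self.sqi[idx])
        return default


def _second_means(x: np.ndarray, rate: float) -> np.ndarray:
    per_sec = int(round(rate))
    n_sec = x.size // per_sec
    return x[: n_sec * per_sec].astype(np.float64).reshape(n_sec, per_sec).mean(axis=1)


def eda_artifact_seconds(trace: SignalTrace, thresholds: SQIThresholds = SQIThresholds()) -> np.ndarray:
    """Boolean artifact flag per whole second of an EDA trace.

    The relative change r_t = (mean(sec t) − mean(sec t−1)) / max(mean(sec t−1), floor)
    marks second t as artifact when r_t reaches +``eda_rise_frac`` or
    −``eda_fall_frac``.  The first second has no predecessor and is clean.
    """
    m = _second_means(trace.samples, trace.rate)
    art = np.zeros(m.size, dtype=bool)
    if m.size >= 2:
        denom = np.maximum(m[:-1], thresholds.eda_floor)
        r = (m[1:] - m[:-1]) / denom
        art[1:] = (r >= thresholds.eda_rise_frac - _EDGE) | (r <= -thresholds.eda_fall_frac + _EDGE)
    return art


def eda_sqi(trace: SignalTrace, thresholds: SQIThresholds = SQIThresholds()) -> QualitySeries:
    """Per-minute EDA quality: fraction of artifact-free seconds.

    A minute is ``good`` only if every one of its seconds is clean.  Traces
    shorter than two seconds yield an empty series.
    """
    if trace.rate < 1:
        raise ValueError("EDA SQI requires at least 1 Hz sampling")
    art = eda_artifact_seconds(trace, thresholds)
    sec_per_min = int(round(thresholds.epoch_s))
    n_min = art.size // sec_per_min
    if art.size < 2 or n_min == 0:
        z = np.empty(0)
        return QualitySeries("EDA", z, z, z.astype(bool))
    a = art[: n_min * sec_per_min].reshape(n_min, sec_per_min)
    sqi = 1.0 - a.mean(axis=1)
    starts = trace.start_time + np.arange(n_min) * thresholds.epoch_s
    return QualitySeries("EDA", starts, sqi, sqi >= 1.0 - _EDGE)


def _window_spectral_entropy(windows: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of the power spectrum, one value per row.

    The DC bin is dropped after mean removal; entropy is normalized by
    log(#bins) so the result lies in [0, 1] regardless of log base.
    All-zero windows are maximally uninformative and score 1.
    """
    windows = windows.astype(np.float64)
    w = windows - windows.mean(axis=1, keepdims=True)
    p = np.abs(np.fft.rfft(w, axis=1)[:, 1:]) ** 2
    tot = p.sum(axis=1, keepdims=True)
    zero = tot[:, 0] <= 0
    tot[zero] = 1.0
    q = p / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1) / np.log(q.shape[1])
    ent[zero] = 1.0
    return ent


def bvp_spectral_entropy(segment: np.ndarray, rate: float = 64.0, window_s: float = 4.0) -> float:
    """Spectral entropy of a 1-min BVP segment, averaged over 4-s windows.

    Requires at least one full window.  An all-zero window contributes
    entropy 1 (with a warning).
    """
    segment = np.asarray(segment, dtype=np.float64)
    n_win_samp = int(round(rate * window_s))
    n_win = segment.size // n_win_samp
    if n_win < 1:
        raise ValueError("segment shorter than one spectral window")
    windows = segment[: n_win * n_win_samp].reshape(n_win, n_win_samp)
    if np.any(np.ptp(windows, axis=1) == 0):
        warnings.warn("constant BVP window: entropy set to 1", stacklevel=2)
    return float(_window_spectral_entropy(windows).mean())


def bvp_sqi(trace: SignalTrace, thresholds: SQIThresholds = SQIThresholds()) -> QualitySeries:
    """Per-minute BVP quality from windowed spectral entropy.

    good iff entropy < ``bvp_entropy_cutoff`` (strict); sqi = 1 − entropy.
    """
    samp_per_min = int(round(trace.rate * thresholds.epoch_s))
    n_min = trace.samples.size // samp_per_min
    if n_min == 0:
        z = np.empty(0)
        return QualitySeries("BVP", z, z, z.astype(bool))
    n_win_samp = int(round(trace.rate * thresholds.window_s))
    wins_per_min = samp_per_min // n_win_samp
    x = trace.samples[: n_min * samp_per_min].reshape(n_min, samp_per_min)
    windows = x[:, : wins_per_min * n_win_samp].reshape(n_min * wins_per_min, n_win_samp)
    ent = _window_spectral_entropy(windows).reshape(n_min, wins_per_min).mean(axis=1)
    starts = trace.start_time + np.arange(n_min) * thresholds.epoch_s
    return QualitySeries("BVP", starts, 1.0 - ent, ent < thresholds.bvp_entropy_cutoff)


def acc_magnitude_series(x: SignalTrace, y: SignalTrace, z: SignalTrace) -> SignalTrace:
    """Vector magnitude sqrt(x² + y² + z²) of three aligned ACC axes."""
    for t in (y, z):
        if t.rate != x.rate or abs(t.start_time - x.start_time) > 1e-9 or t.samples.size != x.samples.size:
            raise ValueError("ACC axes must share start, rate and length")
    mag = np.sqrt(x.samples**2 + y.samples**2 + z.samples**2)
    return SignalTrace(Modality.ACCX, x.start_time, x.rate, mag)


def acc_sqi(x: SignalTrace, y: SignalTrace, z: SignalTrace,
            thresholds: SQIThresholds = SQIThresholds()) -> QualitySeries:
    """Per-minute ACC quality: in-band power fraction of the magnitude signal.

    For non-overlapping 4-s segments of the acceleration magnitude, the
    periodogram power inside [0.8, 5] Hz is divided by the power inside
    [0.8, Nyquist] Hz; minutes average their segments.  A segment with no
    power above 0.8 Hz (e.g. perfectly still) scores 0.  good iff sqi ≥ 0.5.
    """
    mag = acc_magnitude_series(x, y, z)
    rate = mag.rate
    n_seg_samp = int(round(rate * thresholds.window_s))
    samp_per_min = int(round(rate * thresholds.epoch_s))
    n_min = mag.samples.size // samp_per_min
    if n_min == 0:
        zz = np.empty(0)
        return QualitySeries("ACC", zz, zz, zz.astype(bool))
    segs_per_min = samp_per_min // n_seg_samp
    m = mag.samples[: n_min * samp_per_min].reshape(n_min, samp_per_min)
    segs = m[:, : segs_per_min * n_seg_samp].reshape(n_min * segs_per_min, n_seg_samp)
    segs = segs.astype(np.float64)
    segs = segs - segs.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_seg_samp, d=1.0 / rate)
    broad = (freqs >= thresholds.acc_band_lo - _EDGE)
    narrow = broad & (freqs <= thresholds.acc_band_hi + _EDGE)
    p_broad = power[:, broad].sum(axis=1)
    p_narrow = power[:, narrow].sum(axis=1)
    ratio = np.divide(p_narrow, p_broad, out=np.zeros_like(p_narrow), where=p_broad > 0)
    sqi = ratio.reshape(n_min, segs_per_min).mean(axis=1)
    sqi = np.clip(sqi, 0.0, 1.0)
    starts = mag.start_time + np.arange(n_min) * thresholds.epoch_s
    return QualitySeries("ACC", starts, sqi, sqi >= 0.5)
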