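"""Channel assembly: common 128 Hz grid, 60-s segments, 17-channel tensors.

Every modality is brought onto a shared 128 Hz grid (slow channels by linear
interpolation, ACC/BVP by polyphase antialiased upsampling), the recording is
carved into consecutive non-overlapping 60-s segments aligned to whole minutes
of each session, and each segment becomes a 17 × 7680 tensor:

    ACCX, ACCY, ACCZ, ACCMag, BVP, EDA, TEMP, HR,
    FFT_ACCMag, FFT_BVP, FFT_EDA, FFT_TEMP, FFT_HR,
    SQI_ACC, SQI_BVP, SQI_EDA, TIME_OF_DAY

FFT channels hold the one-sided magnitude spectrum of the mean-removed
segment, linearly stretched from 3841 bins to 7680 samples so every channel
shares one time axis.  SQI channels replicate the minute's quality index;
TIME_OF_DAY replicates the local hour (0–23).  Z-score normalization uses
training-data statistics only.

Segments may be decimated on assembly (``stride``) for tractable sequence
models; stride 1 keeps the full 7680-sample resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import h5py
import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .e4_io import Modality, MultimodalRecording, SignalTrace
from .signal_quality import QualitySeries

__all__ = [
    "CHANNELS",
    "TARGET_RATE",
    "SEGMENT_SECONDS",
    "SEGMENT_SAMPLES",
    "SegmentBatch",
    "NormalizationStats",
    "resample_to_grid",
    "acc_magnitude",
    "fft_feature_channel",
    "time_of_day_channel",
    "assemble_segments",
    "fit_normalization",
    "apply_normalization",
]

#: The 17 input channels, in their single-source-of-truth order.
CHANNELS: tuple[str, ...] = (
    "ACCX", "ACCY", "ACCZ", "ACCMag", "BVP", "EDA", "TEMP", "HR",
    "FFT_ACCMag", "FFT_BVP", "FFT_EDA", "FFT_TEMP", "FFT_HR",
    "SQI_ACC", "SQI_BVP", "SQI_EDA", "TIME_OF_DAY",
)

TARGET_RATE = 128          # Hz, common grid
SEGMENT_SECONDS = 60
SEGMENT_SAMPLES = TARGET_RATE * SEGMENT_SECONDS  # 7680

#: label codes used across the package (assigned by the labeling module)
LABEL_UNASSIGNED, LABEL_INTERICTAL, LABEL_PREICTAL, LABEL_EXCLUDED = -1, 0, 1, 2

_SUPPORTED_RATES = (1, 4, 32, 64)
#: modalities upsampled with the antialiased polyphase filter; the rest are linear
_POLY_RATES = (32, 64)


@dataclass
class SegmentBatch:
    """A stack of 60-s, 17-channel segments.

    ``segments`` has shape (n, 17, T) with T = 7680 / stride; ``labels`` uses
    the LABEL_* codes; ``augmented`` flags noise-added training copies.
    """

    segments: np.ndarray
    start_times: np.ndarray
    labels: np.ndarray
    stride: int = 1
    channels: tuple[str, ...] = CHANNELS
    augmented: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float32)
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.augmented is None:
            self.augmented = np.zeros(len(self.start_times), dtype=bool)
        self.augmented = np.asarray(self.augmented, dtype=bool)
        n_ch = len(self.channels)
        if self.segments.ndim != 3 or self.segments.shape[1] != n_ch:
            raise ValueError(f"segments must be (n, {n_ch}, T)")
        if self.segments.shape[2] * self.stride != SEGMENT_SAMPLES:
            raise ValueError("timesteps × stride must equal 7680")
        if not (len(self.start_times) == len(self.labels) == len(self.segments) == len(self.augmented)):
            raise ValueError("per-segment arrays must align")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_timesteps(self) -> int:
        return self.segments.shape[2]

    def subset(self, mask: np.ndarray) -> "SegmentBatch":
        return SegmentBatch(self.segments[mask], self.start_times[mask],
                            self.labels[mask], self.stride, self.channels,
                            self.augmented[mask])

    def drop_channels(self, names: Sequence[str]) -> "SegmentBatch":
        """A copy without the named channels (for signal-group ablation)."""
        keep = [i for i, c in enumerate(self.channels) if c not in set(names)]
        return SegmentBatch(self.segments[:, keep], self.start_times, self.labels,
                            self.stride, tuple(self.channels[i] for i in keep),
                            self.augmented)

    @staticmethod
    def concatenate(batches: Sequence["SegmentBatch"]) -> "SegmentBatch":
        b0 = batches[0]
        for b in batches[1:]:
            if b.stride != b0.stride or b.channels != b0.channels:
                raise ValueError("cannot concatenate batches with differing layout")
        return SegmentBatch(
            np.concatenate([b.segments for b in batches]),
            np.concatenate([b.start_times for b in batches]),
            np.concatenate([b.labels for b in batches]),
            b0.stride, b0.channels,
            np.concatenate([b.augmented for b in batches]))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("segments", data=self.segments, compression="gzip")
            f.create_dataset("start_times", data=self.start_times)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("augmented", data=self.augmented)
            f.attrs["stride"] = self.stride
            f.attrs["channels"] = ",".join(self.channels)

    @staticmethod
    def load(path) -> "SegmentBatch":
        with h5py.File(path, "r") as f:
            return SegmentBatch(f["segments"][...], f["start_times"][...],
                                f["labels"][...], int(f.attrs["stride"]),
                                tuple(str(f.attrs["channels"]).split(",")),
                                f["augmented"][...])


# ---------------------------------------------------------------------------
# Elementary channel operations
# ---------------------------------------------------------------------------

def _linear_upsample(rows: np.ndarray, rate: float, n_out: int) -> np.ndarray:
    """Linear interpolation of (n, rate·60) rows onto the 128 Hz grid."""
    n_nat = rows.shape[1]
    pos = np.arange(n_out) * rate / TARGET_RATE
    i0 = np.minimum(pos.astype(np.int64), n_nat - 1)
    i1 = np.minimum(i0 + 1, n_nat - 1)
    frac = np.clip(pos - i0, 0.0, 1.0).astype(rows.dtype)
    return rows[:, i0] * (1 - frac) + rows[:, i1] * frac


def _upsample_rows(rows: np.ndarray, rate: int) -> np.ndarray:
    """Upsample (n, rate·60) rows to (n, 7680)."""
    if rate == TARGET_RATE:
        return rows
    if rate in _POLY_RATES:
        return resample_poly(rows, TARGET_RATE // rate, 1, axis=1)
    return _linear_upsample(rows, rate, SEGMENT_SAMPLES)


def resample_to_grid(trace: SignalTrace, target_rate: int = TARGET_RATE) -> SignalTrace:
    """Resample one trace to the common grid (whole-second aligned).

    Linear interpolation for slow channels (≤4 Hz and HR), polyphase
    antialiased upsampling for ACC (32 Hz) and BVP (64 Hz).  Constant signals
    are preserved exactly.
    """
    if target_rate != TARGET_RATE:
        raise ValueError("only the 128 Hz common grid is supported")
    rate = int(round(trace.rate))
    if rate not in _SUPPORTED_RATES and rate != TARGET_RATE:
        raise ValueError(f"unsupported native rate {trace.rate} Hz")
    x = trace.samples[None, :]
    if rate in _POLY_RATES:
        out = resample_poly(x, TARGET_RATE // rate, 1, axis=1)[0]
    else:
        n_out = int(round(trace.samples.size * TARGET_RATE / rate))
        out = _linear_upsample(x, rate, n_out)[0]
    return SignalTrace(trace.modality, trace.start_time, float(TARGET_RATE), out)


def acc_magnitude(x: SignalTrace, y: SignalTrace, z: SignalTrace) -> SignalTrace:
    """Per-sample vector magnitude sqrt(x² + y² + z²) of aligned axes."""
    for t in (y, z):
        if (t.rate != x.rate or abs(t.start_time - x.start_time) > 1e-9
                or t.samples.size != x.samples.size):
            raise ValueError("ACC axes must be aligned (start, rate, length)")
    return SignalTrace(Modality.ACCX, x.start_time, x.rate,
                       np.sqrt(x.samples**2 + y.samples**2 + z.samples**2))


# stretch positions mapping 3841 spectrum bins onto 7680 samples
_N_BINS = SEGMENT_SAMPLES // 2 + 1
_STRETCH_POS = np.arange(SEGMENT_SAMPLES) * (_N_BINS - 1) / (SEGMENT_SAMPLES - 1)
_STRETCH_I0 = np.minimum(_STRETCH_POS.astype(np.int64), _N_BINS - 2)
_STRETCH_F = _STRETCH_POS - _STRETCH_I0


def _fft_rows(rows: np.ndarray) -> np.ndarray:
    """One-sided magnitude spectra of mean-removed rows, stretched to 7680."""
    spec = np.abs(np.fft.rfft(rows - rows.mean(axis=1, keepdims=True), axis=1))
    return spec[:, _STRETCH_I0] * (1.0 - _STRETCH_F) + spec[:, _STRETCH_I0 + 1] * _STRETCH_F


def _strided_channel(rows: np.ndarray, rate: int, stride: int) -> np.ndarray:
    """Sample the 128 Hz version of native-rate rows at every ``stride``-th
    grid point.  Where those points coincide with native samples the values
    are taken directly; otherwise linear interpolation is used."""
    T = SEGMENT_SAMPLES // stride
    num = stride * rate
    if num % TARGET_RATE == 0:
        return rows[:, :: num // TARGET_RATE][:, :T]
    n_nat = rows.shape[1]
    pos = np.arange(T) * (stride * rate / TARGET_RATE)
    i0 = np.minimum(pos.astype(np.int64), n_nat - 1)
    i1 = np.minimum(i0 + 1, n_nat - 1)
    frac = np.clip(pos - i0, 0.0, 1.0).astype(rows.dtype)
    return rows[:, i0] * (1 - frac) + rows[:, i1] * frac


def _fft_rows_strided(rows: np.ndarray, rate: int, stride: int) -> np.ndarray:
    """Strided FFT channel computed from native-rate rows.

    The native spectrum shares the 1/60 Hz bin spacing of the 128 Hz
    spectrum, so it forms the lower bins of the full 3841-bin spectrum
    (scaled by the upsampling factor); bins above the native Nyquist are
    zero.  Only the requested strided stretch positions are materialized.
    """
    spec = np.abs(np.fft.rfft(rows.astype(np.float32), axis=1)) * np.float32(TARGET_RATE / rate)
    full = np.zeros((rows.shape[0], _N_BINS), dtype=np.float32)
    full[:, : spec.shape[1]] = spec
    i0 = _STRETCH_I0[::stride]
    f = _STRETCH_F[::stride].astype(np.float32)
    return full[:, i0] * (1 - f) + full[:, i0 + 1] * f


def fft_feature_channel(segment_channel: np.ndarray) -> np.ndarray:
    """FFT feature for one 60-s, 128 Hz channel.

    Magnitude of the DFT of the mean-removed segment (one-sided, 3841 bins),
    linearly stretched to 7680 samples so it stacks as a channel.
    """
    x = np.asarray(segment_channel, dtype=np.float64)
    if x.size != SEGMENT_SAMPLES:
        raise ValueError(f"expected {SEGMENT_SAMPLES} samples, got {x.size}")
    return _fft_rows(x[None, :])[0]


def local_hour(start_times: np.ndarray, timezone: str | None = "UTC") -> np.ndarray:
    """Local hour-of-day (0–23) for UNIX-second timestamps."""
    if timezone is None:
        warnings.warn("no timezone given: using UTC for the time-of-day channel", stacklevel=2)
        timezone = "UTC"
    ts = pd.to_datetime(np.asarray(start_times, dtype=np.float64), unit="s", utc=True)
    return ts.tz_convert(ZoneInfo(timezone)).hour.to_numpy()


def time_of_day_channel(start_time: float, timezone: str | None = "UTC") -> np.ndarray:
    """Constant channel holding the local hour, replicated across 7680 samples."""
    hour = local_hour(np.array([start_time]), timezone)[0]
    return np.full(SEGMENT_SAMPLES, float(hour))


# ---------------------------------------------------------------------------
# Segment assembly
# ---------------------------------------------------------------------------

def _minute_rows(trace: SignalTrace, starts: np.ndarray) -> np.ndarray:
    """Gather (n, rate·60) native-sample rows, one per minute start."""
    rate = int(round(trace.rate))
    per_min = rate * SEGMENT_SECONDS
    offsets = np.round((starts - trace.start_time) * rate).astype(np.int64)
    idx = offsets[:, None] + np.arange(per_min)[None, :]
    return trace.samples[idx]


def _sqi_lookup(series: QualitySeries | None, starts: np.ndarray) -> np.ndarray:
    """Vectorized per-minute SQI lookup; NaN where no value exists."""
    out = np.full(starts.size, np.nan)
    if series is None or series.minute_start_times.size == 0:
        return out
    pos = np.searchsorted(series.minute_start_times, starts - 1.0)
    pos = np.clip(pos, 0, series.minute_start_times.size - 1)
    ok = np.abs(series.minute_start_times[pos] - starts) < 1.0
    out[ok] = series.sqi[pos[ok]]
    return out


def assemble_segments(recording: MultimodalRecording,
                      quality: Mapping[str, QualitySeries],
                      segment_starts: np.ndarray | None = None,
                      stride: int = 1,
                      timezone: str = "UTC",
                      chunk_size: int = 1024) -> tuple[SegmentBatch, np.ndarray]:
    """Build the 17-channel tensor for every requested (or every covered) minute.

    Minutes not fully covered by all modalities, or lacking an SQI value, are
    excluded rather than zero-filled.  Returns ``(batch, excluded_starts)``.

    ``stride`` decimates each assembled channel from 7680 samples to
    7680/stride, which is how long recordings stay tractable for the sequence
    model; stride 1 keeps full resolution.
    """
    if SEGMENT_SAMPLES % stride:
        raise ValueError("stride must divide 7680")
    sessions = recording.sessions
    if segment_starts is None:
        segment_starts = np.concatenate([
            s0 + SEGMENT_SECONDS * np.arange(int((s1 - s0) // SEGMENT_SECONDS))
            for s0, s1 in sessions]) if sessions else np.empty(0)
    segment_starts = np.asarray(segment_starts, dtype=np.float64)

    covered = np.zeros(segment_starts.size, dtype=bool)
    for s0, s1 in sessions:
        covered |= (segment_starts >= s0 - 1e-9) & (segment_starts + SEGMENT_SECONDS <= s1 + 1e-9)
    sqi_acc = _sqi_lookup(quality.get("ACC"), segment_starts)
    sqi_bvp = _sqi_lookup(quality.get("BVP"), segment_starts)
    sqi_eda = _sqi_lookup(quality.get("EDA"), segment_starts)
    valid = covered & np.isfinite(sqi_acc) & np.isfinite(sqi_bvp) & np.isfinite(sqi_eda)
    excluded = segment_starts[~valid]
    starts = segment_starts[valid]

    n = starts.size
    T = SEGMENT_SAMPLES // stride
    segs = np.empty((n, len(CHANNELS), T), dtype=np.float32)
    ch_idx = {c: i for i, c in enumerate(CHANNELS)}
    hours = local_hour(starts, timezone)
    segs[:, ch_idx["TIME_OF_DAY"], :] = hours[:, None]
    segs[:, ch_idx["SQI_ACC"], :] = sqi_acc[valid][:, None]
    segs[:, ch_idx["SQI_BVP"], :] = sqi_bvp[valid][:, None]
    segs[:, ch_idx["SQI_EDA"], :] = sqi_eda[valid][:, None]

    raw_specs = [  # (channel, modality or None for ACCMag, fft channel or None)
        ("ACCX", Modality.ACCX, None),
        ("ACCY", Modality.ACCY, None),
        ("ACCZ", Modality.ACCZ, None),
        ("ACCMag", None, "FFT_ACCMag"),
        ("BVP", Modality.BVP, "FFT_BVP"),
        ("EDA", Modality.EDA, "FFT_EDA"),
        ("TEMP", Modality.TEMP, "FFT_TEMP"),
        ("HR", Modality.HR, "FFT_HR"),
    ]

    for lo in range(0, n, chunk_size):
        sl = slice(lo, min(lo + chunk_size, n))
        st = starts[sl]
        # map each minute to its covering session trace per modality
        nat_rows: dict[Modality, np.ndarray] = {}
        for mod in Modality:
            tr_list = recording.traces[mod]
            rate = int(round(tr_list[0].rate))
            rows = np.empty((st.size, rate * SEGMENT_SECONDS))
            for tr in tr_list:
                in_tr = (st >= tr.start_time - 1e-9) & (st + SEGMENT_SECONDS <= tr.end_time + 1e-9)
                if in_tr.any():
                    rows[in_tr] = _minute_rows(tr, st[in_tr])
            nat_rows[mod] = rows
        mag_nat = np.sqrt(nat_rows[Modality.ACCX]**2 + nat_rows[Modality.ACCY]**2
                          + nat_rows[Modality.ACCZ]**2)
        for name, mod, fft_name in raw_specs:
            if mod is None:
                rows, rate = mag_nat, 32
            else:
                rows, rate = nat_rows[mod], int(round(recording.traces[mod][0].rate))
            if stride == 1:
                up = _upsample_rows(rows, rate)
                segs[sl, ch_idx[name], :] = up
                if fft_name is not None:
                    segs[sl, ch_idx[fft_name], :] = _fft_rows(up)
            else:
                segs[sl, ch_idx[name], :] = _strided_channel(rows, rate, stride)
                if fft_name is not None:
                    segs[sl, ch_idx[fft_name], :] = _fft_rows_strided(rows, rate, stride)

    labels = np.full(n, LABEL_UNASSIGNED, dtype=np.int8)
    return SegmentBatch(segs, starts, labels, stride), excluded


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-channel mean and standard deviation fitted on training data."""

    mean: np.ndarray
    std: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if np.any(self.std <= 0):
            raise ValueError("std must be positive")


def fit_normalization(train: SegmentBatch) -> NormalizationStats:
    """Per-channel mean/sd over all training segments and timesteps.

    Degenerate (zero-variance) channels get sd = 1 with a warning so that
    z-scoring stays defined.
    """
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty batch")
    x = train.segments
    mean = x.mean(axis=(0, 2), dtype=np.float64)
    std = x.std(axis=(0, 2), dtype=np.float64)
    if np.any(std == 0):
        warnings.warn("zero-variance channel(s): sd set to 1", stacklevel=2)
        std = np.where(std == 0, 1.0, std)
    return NormalizationStats(mean, std, train.channels)


def apply_normalization(batch: SegmentBatch, stats: NormalizationStats) -> SegmentBatch:
    """Z-score every channel with the (training) statistics. Affine, invertible."""
    if batch.channels != stats.channels:
        raise ValueError("channel layout of batch and stats differ")
    z = (batch.segments - stats.mean[None, :, None].astype(np.float32)) \
        / stats.std[None, :, None].astype(np.float32)
    return SegmentBatch(z, batch.start_times, batch.labels, batch.stride,
                        batch.channels, batch.augmented)
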