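"""Reading and writing Empatica-E4-style CSV recordings and seizure annotations.

The E4 cloud export stores each modality in its own CSV file inside a session
directory: line 1 is the initial UNIX timestamp (UTC seconds), line 2 the
sampling rate in Hz, and every following line one sample (three comma-separated
columns for the accelerometer).  Seizure annotations are a single-column CSV of
EEG-confirmed onset times with header ``onset_unix_s``.

Timestamps are UTC UNIX seconds throughout the package; local time only enters
when the time-of-day channel is derived.  Missing data are represented as
absent sessions rather than sentinel values, so downstream code can tell "bad"
from "not recorded".
"""

from __future__ import annotations

import enum
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "NATIVE_RATES",
    "E4FormatError",
    "SignalTrace",
    "MultimodalRecording",
    "SeizureAnnotations",
    "read_e4_csv",
    "write_e4_csv",
    "read_session_dir",
    "write_session_dir",
    "read_annotations",
    "write_annotations",
]


class Modality(str, enum.Enum):
    """One wrist-sensor channel as exported by the device."""

    ACCX = "ACCX"
    ACCY = "ACCY"
    ACCZ = "ACCZ"
    BVP = "BVP"
    EDA = "EDA"
    TEMP = "TEMP"
    HR = "HR"


#: Native sampling rates of the device, in Hz (ACC 32, BVP 64, EDA 4, TEMP 4, HR 1).
NATIVE_RATES: dict[Modality, float] = {
    Modality.ACCX: 32.0,
    Modality.ACCY: 32.0,
    Modality.ACCZ: 32.0,
    Modality.BVP: 64.0,
    Modality.EDA: 4.0,
    Modality.TEMP: 4.0,
    Modality.HR: 1.0,
}

#: File-name stem per modality in a session directory. ACC axes share one file.
_FILE_STEMS = {
    Modality.BVP: "BVP",
    Modality.EDA: "EDA",
    Modality.TEMP: "TEMP",
    Modality.HR: "HR",
}


class E4FormatError(ValueError):
    """Raised for malformed E4 CSV headers or unparseable sample rows."""


@dataclass
class SignalTrace:
    """One modality's uniformly sampled series.

    Parameters
    ----------
    modality : Modality
    start_time : float
        UNIX seconds (UTC) of the first sample.
    rate : float
        Sampling rate in samples/second; must be positive.
    samples : ndarray
        Ordered, finite sample values.
    """

    modality: Modality
    start_time: float
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.samples = np.asarray(self.samples)
        if self.samples.dtype.kind != "f":
            self.samples = self.samples.astype(np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Covered duration in seconds (len / rate)."""
        return self.samples.size / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps (UNIX seconds)."""
        return self.start_time + np.arange(self.samples.size) / self.rate

    def slice(self, t0: float, t1: float) -> "SignalTrace":
        """Samples with timestamps in [t0, t1)."""
        i0 = int(np.ceil(round((t0 - self.start_time) * self.rate, 6)))
        i1 = int(np.ceil(round((t1 - self.start_time) * self.rate, 6)))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.samples.size)
        return SignalTrace(self.modality, self.start_time + i0 / self.rate,
                           self.rate, self.samples[i0:i1])


@dataclass
class MultimodalRecording:
    """A subject's recording: per-modality traces split into sessions.

    ``traces`` maps each modality to a time-ordered list of contiguous
    :class:`SignalTrace` sessions.  A session interval is covered only where
    all modalities overlap.
    """

    subject_id: str
    traces: dict[Modality, list[SignalTrace]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mod, tr_list in self.traces.items():
            tr_list.sort(key=lambda t: t.start_time)
            for a, b in zip(tr_list, tr_list[1:]):
                if b.start_time < a.end_time - 1e-9:
                    raise ValueError(f"overlapping sessions for {mod}")

    @property
    def sessions(self) -> list[tuple[float, float]]:
        """Non-overlapping (start, end) intervals covered by *all* modalities.

        Sessions of different modalities are intersected; a gap in any one
        modality splits the covered interval.
        """
        if not self.traces:
            return []
        per_mod: list[list[tuple[float, float]]] = []
        for mod in Modality:
            tr_list = self.traces.get(mod)
            if not tr_list:
                return []
            per_mod.append([(t.start_time, t.end_time) for t in tr_list])
        out = per_mod[0]
        for ivs in per_mod[1:]:
            out = _intersect_intervals(out, ivs)
        return out

    @property
    def span(self) -> tuple[float, float]:
        s = self.sessions
        if not s:
            raise ValueError("empty recording")
        return s[0][0], s[-1][1]

    def get(self, modality: Modality, t0: float, t1: float) -> SignalTrace | None:
        """The single session trace covering [t0, t1), sliced; None if absent."""
        for tr in self.traces.get(Modality(modality), []):
            if tr.start_time <= t0 + 1e-9 and tr.end_time >= t1 - 1e-9:
                return tr.slice(t0, t1)
        return None


def _intersect_intervals(a: Sequence[tuple[float, float]],
                         b: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass
class SeizureAnnotations:
    """EEG-confirmed seizure onset times, sorted ascending (UNIX seconds)."""

    onsets: np.ndarray
    source: str = "iEEG"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64).ravel()
        self.onsets = np.unique(self.onsets)  # sorts and deduplicates

    def __len__(self) -> int:
        return self.onsets.size


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def read_e4_csv(path: str | os.PathLike, modality: Modality | str) -> list[SignalTrace]:
    """Read one E4 CSV file.

    Returns a list of traces: one for scalar modalities, three (X, Y, Z) for an
    ACC file.  Pass any of ACCX/ACCY/ACCZ (or the string ``"ACC"``) to read an
    accelerometer file.
    """
    path = Path(path)
    is_acc = str(modality).upper().startswith("ACC") or str(modality) == "ACC"
    with open(path) as fh:
        header = fh.readline().strip()
        rate_line = fh.readline().strip()
        if not header or not rate_line:
            raise E4FormatError(f"{path}: missing header lines")
        try:
            start_time = float(header.split(",")[0])
            rate = float(rate_line.split(",")[0])
        except ValueError as exc:
            raise E4FormatError(f"{path}: malformed header: {exc}") from None
        if not rate > 0:
            raise E4FormatError(f"{path}: sampling rate must be positive, got {rate}")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError:
                raise E4FormatError(f"{path}:{lineno}: non-numeric sample row") from None
    data = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, 3 if is_acc else 1))
    if is_acc:
        if data.size and data.shape[1] != 3:
            raise E4FormatError(f"{path}: ACC file must have 3 columns, got {data.shape[1]}")
        mods = (Modality.ACCX, Modality.ACCY, Modality.ACCZ)
        return [SignalTrace(m, start_time, rate, data[:, i] if data.size else np.empty(0))
                for i, m in enumerate(mods)]
    if data.size and data.shape[1] != 1:
        raise E4FormatError(f"{path}: expected a single column, got {data.shape[1]}")
    return [SignalTrace(Modality(modality), start_time, rate, data[:, 0] if data.size else np.empty(0))]


def write_e4_csv(traces: SignalTrace | Sequence[SignalTrace], path: str | os.PathLike) -> None:
    """Write one or three (ACC) traces in the E4 CSV dialect.

    Round-trips bit-exactly for the header fields and within repr-float
    formatting for samples.
    """
    if isinstance(traces, SignalTrace):
        traces = [traces]
    start = traces[0].start_time
    rate = traces[0].rate
    for tr in traces:
        if tr.start_time != start or tr.rate != rate or tr.samples.size != traces[0].samples.size:
            raise ValueError("traces written to one file must share start, rate and length")
    ncol = len(traces)
    with open(path, "w") as fh:
        fh.write(",".join([repr(start)] * ncol) + "\n")
        fh.write(",".join([repr(rate)] * ncol) + "\n")
        if traces[0].samples.size:
            cols = np.column_stack([t.samples for t in traces])
            pd.DataFrame(cols).to_csv(fh, header=False, index=False,
                                      float_format="%.12g", lineterminator="\n")


def write_session_dir(recording_session: dict[Modality, SignalTrace],
                      directory: str | os.PathLike) -> None:
    """Write one session's traces as ACC.csv, BVP.csv, EDA.csv, TEMP.csv, HR.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    acc = [recording_session.get(m) for m in (Modality.ACCX, Modality.ACCY, Modality.ACCZ)]
    if any(t is not None for t in acc):
        if any(t is None for t in acc):
            raise ValueError("all three ACC axes are required to write ACC.csv")
        write_e4_csv([t for t in acc if t is not None], directory / "ACC.csv")
    for mod, stem in _FILE_STEMS.items():
        tr = recording_session.get(mod)
        if tr is not None:
            write_e4_csv(tr, directory / f"{stem}.csv")


def read_session_dir(directory: str | os.PathLike) -> dict[Modality, SignalTrace]:
    """Read one session directory back into per-modality traces."""
    directory = Path(directory)
    out: dict[Modality, SignalTrace] = {}
    acc_path = directory / "ACC.csv"
    if acc_path.exists():
        for tr in read_e4_csv(acc_path, "ACC"):
            out[tr.modality] = tr
    for mod, stem in _FILE_STEMS.items():
        p = directory / f"{stem}.csv"
        if p.exists():
            out[mod] = read_e4_csv(p, mod)[0]
    return out


def read_recording(root: str | os.PathLike, subject_id: str = "subject") -> MultimodalRecording:
    """Read a recording from a root holding one or more session directories.

    ``root`` may itself be a session directory (contains EDA.csv) or contain
    session subdirectories, one per contiguous recorded interval.
    """
    root = Path(root)
    session_dirs = [root] if (root / "EDA.csv").exists() else sorted(
        p for p in root.iterdir() if p.is_dir() and (p / "EDA.csv").exists())
    traces: dict[Modality, list[SignalTrace]] = {m: [] for m in Modality}
    for d in session_dirs:
        for mod, tr in read_session_dir(d).items():
            traces[mod].append(tr)
    return MultimodalRecording(subject_id, {m: v for m, v in traces.items() if v})


def read_annotations(path: str | os.PathLike) -> SeizureAnnotations:
    """Read a seizure-annotation CSV (header ``onset_unix_s``).

    Unsorted input is accepted and sorted; duplicate onsets are collapsed with
    a warning.  An empty file yields a valid zero-onset object.
    """
    df = pd.read_csv(path)
    if "onset_unix_s" not in df.columns:
        raise E4FormatError(f"{path}: annotation CSV needs an 'onset_unix_s' column")
    onsets = df["onset_unix_s"].to_numpy(dtype=np.float64)
    if onsets.size != np.unique(onsets).size:
        warnings.warn("duplicate seizure onsets collapsed", stacklevel=2)
    return SeizureAnnotations(onsets)


def write_annotations(ann: SeizureAnnotations, path: str | os.PathLike) -> None:
    pd.DataFrame({"onset_unix_s": ann.onsets}).to_csv(path, index=False)
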