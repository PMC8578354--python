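"""Synthetic multimodal wrist recordings with controllable forecastability.

Long-term ambulatory wearable datasets with EEG-confirmed seizures are
private, so every downstream stage of this package is exercised on simulated
recordings that emulate the device's five modalities at their native rates
(ACC 32 Hz × 3 axes, BVP 64 Hz, EDA 4 Hz, TEMP 4 Hz, HR 1 Hz):

* **HR** — circadian baseline (lower at night) plus Ornstein–Uhlenbeck
  variability and activity-driven elevation;
* **BVP** — a pulse waveform with harmonics, oscillating at the instantaneous
  heart rate, so clean minutes sit in the low-spectral-entropy regime;
* **EDA** — slowly varying tonic level plus Poisson phasic skin-conductance
  responses (fast rise, ~4 s decay);
* **TEMP** — wrist temperature around 32–33 °C with circadian swing and slow
  drift;
* **ACC** — rest noise around gravity with daytime activity bouts of
  band-limited (≈2 Hz) oscillation.

Seizure onsets follow a circadian-modulated Poisson process; each seizure can
spawn a clustered follow-up within 4 h (self-exciting draw), which exercises
the lead-seizure filter.  An optional preictal signature of configurable
effect size (HR rise, EDA phasic-rate multiplier, TEMP drift) is injected in
the window [onset − 75 min, onset − 15 min), matching the label geometry so
that signal recovery is a clean end-to-end test.  ``inject_artifacts`` adds
motion bursts, EDA steps and flat segments with ground-truth intervals.

Identical config + seed reproduces recordings bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter, oaconvolve
from scipy.special import i0

import yaml

from .e4_io import (Modality, MultimodalRecording, SeizureAnnotations,
                    SignalTrace, write_annotations, write_session_dir)

__all__ = [
    "PreictalEffect",
    "SimulationConfig",
    "gen_seizure_times",
    "gen_recording",
    "inject_artifacts",
    "simulate_to_dir",
]


@dataclass(frozen=True)
class PreictalEffect:
    """Per-modality preictal signature sizes (all zero / one ⇒ no signature)."""

    hr_bpm: float = 0.0          # mean heart-rate rise in bpm
    eda_rate_mult: float = 1.0   # multiplier on the phasic SCR event rate
    temp_drift_c: float = 0.0    # wrist-temperature offset in °C

    @property
    def is_null(self) -> bool:
        return self.hr_bpm == 0.0 and self.eda_rate_mult == 1.0 and self.temp_drift_c == 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated subject.

    Defaults emulate a two-week ambulatory recording with ~1.5 seizures/day,
    moderate circadian clustering of onsets and occasional clustered
    follow-ups.  The preictal signature window mirrors the labeling geometry
    ([−75, −15) min before onset) and is configurable for robustness tests.
    """

    duration_days: float = 14.0
    start_time: float = 1_600_002_000.0  # whole clock hour, UTC
    seizure_rate_per_day: float = 1.5
    circadian_concentration: float = 1.0     # von-Mises-style peaking of onsets
    circadian_peak_hour: float = 8.0
    cluster_prob: float = 0.2                # chance a seizure spawns a follow-up < 4 h
    preictal_effect: PreictalEffect = field(default_factory=PreictalEffect)
    preictal_window: tuple[float, float] = (75 * 60.0, 15 * 60.0)  # s before onset
    artifact_rate_per_hour: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if min(self.seizure_rate_per_day, self.circadian_concentration,
               self.artifact_rate_per_hour) < 0 or not 0 <= self.cluster_prob <= 1:
            raise ValueError("rates must be >= 0 and cluster_prob in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.duration_days * 86400.0


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# Seizure times
# ---------------------------------------------------------------------------

def gen_seizure_times(config: SimulationConfig) -> SeizureAnnotations:
    """Circadian-modulated Poisson seizure onsets with self-exciting clusters.

    Lead events are drawn by thinning an inhomogeneous Poisson process whose
    daily-average intensity equals ``seizure_rate_per_day``; with
    ``circadian_concentration`` κ = 0 the onset hours are uniform.  Each event
    spawns a clustered follow-up within (0.5 h, 4 h) with probability
    ``cluster_prob`` (recursively).
    """
    rng = _rng_for(config, 0)
    T = config.duration_s
    base = config.seizure_rate_per_day / 86400.0
    if base == 0:
        return SeizureAnnotations(np.empty(0), source="synthetic")
    kappa = config.circadian_concentration
    lam_max = base * np.exp(kappa) / i0(kappa)
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    hours = ((config.start_time + cand) / 3600.0) % 24.0
    lam = base * np.exp(kappa * np.cos(2 * np.pi * (hours - config.circadian_peak_hour) / 24.0)) / i0(kappa)
    keep = rng.random(n_cand) < lam / lam_max
    leads = cand[keep]

    onsets = list(leads)
    queue = list(leads)
    while queue:
        t0 = queue.pop()
        if rng.random() < config.cluster_prob:
            follow = t0 + rng.uniform(0.5 * 3600.0, 4.0 * 3600.0 - 1.0)
            if follow < T:
                onsets.append(follow)
                queue.append(follow)
    onsets = np.round(np.sort(np.asarray(onsets)) / 60.0) * 60.0  # minute-aligned onsets
    onsets = onsets[(onsets > 0) & (onsets < T)]
    return SeizureAnnotations(config.start_time + onsets, source="synthetic")


# ---------------------------------------------------------------------------
# Signal synthesis helpers
# ---------------------------------------------------------------------------

def _ou_noise(rng: np.random.Generator, n: int, tau_s: float, sigma: float,
              rate: float = 1.0) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise sampled at ``rate`` Hz."""
    alpha = np.exp(-1.0 / (tau_s * rate))
    eps = rng.standard_normal(n, dtype=np.float32)
    x = lfilter([np.sqrt(1 - alpha**2)], [1.0, -alpha], eps).astype(np.float32)
    return (sigma * x).astype(np.float32)


def _preictal_mask_1hz(config: SimulationConfig, annotations: SeizureAnnotations,
                       ramp_s: float = 60.0) -> np.ndarray:
    """Smooth 0→1 mask of the preictal signature window on the 1 Hz grid."""
    n = int(round(config.duration_s))
    mask = np.zeros(n, dtype=np.float32)
    off0, off1 = config.preictal_window
    t = None
    for onset in annotations.onsets:
        a = (onset - off0) - config.start_time
        b = (onset - off1) - config.start_time
        i0_, i1_ = int(max(a, 0)), int(min(b, n))
        if i1_ <= i0_:
            continue
        if t is None:
            t = np.arange(n, dtype=np.float32)
        seg = np.ones(i1_ - i0_, dtype=np.float32)
        r = int(ramp_s)
        if seg.size > 2 * r:
            ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(r, dtype=np.float32) / r)
            seg[:r] = ramp
            seg[-r:] = ramp[::-1]
        np.maximum(mask[i0_:i1_], seg, out=mask[i0_:i1_])
    return mask


def _activity_envelope(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Daytime activity bouts (0..1) on the 1 Hz grid, with soft edges."""
    n = int(round(config.duration_s))
    env = np.zeros(n, dtype=np.float32)
    n_bouts = rng.poisson(16 * config.duration_days)
    starts = rng.uniform(0, config.duration_s, size=n_bouts)
    hours = ((config.start_time + starts) / 3600.0) % 24.0
    starts = starts[(hours > 7) & (hours < 23)]  # active mostly while awake
    for s in np.sort(starts):
        dur = rng.uniform(300.0, 2400.0)
        i0_, i1_ = int(s), min(int(s + dur), n)
        env[i0_:i1_] = np.maximum(env[i0_:i1_], rng.uniform(0.4, 1.0))
    # soften edges with a 30-s moving average
    kernel = np.ones(30, dtype=np.float32) / 30.0
    return oaconvolve(env, kernel, mode="same").astype(np.float32)


def _circadian(config: SimulationConfig, n: int, rate: float,
               amplitude: float, peak_hour: float) -> np.ndarray:
    t = config.start_time + np.arange(n, dtype=np.float64) / rate
    return (amplitude * np.cos(2 * np.pi * ((t / 3600.0) % 24.0 - peak_hour) / 24.0)).astype(np.float32)


def _repeat(x: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(x, factor)


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

def gen_recording(config: SimulationConfig,
                  annotations: SeizureAnnotations) -> MultimodalRecording:
    """Synthesize one continuous session of all five modalities.

    Raises if any annotation falls outside the simulated span.  The preictal
    signature is injected iff ``config.preictal_effect`` is non-null; with a
    null effect, preictal and interictal physiology are statistically
    indistinguishable.
    """
    t0, T = config.start_time, config.duration_s
    if annotations.onsets.size and (annotations.onsets.min() < t0
                                    or annotations.onsets.max() > t0 + T):
        raise ValueError("annotations fall outside the simulated recording")
    rng = _rng_for(config, 1)
    n1 = int(round(T))                      # 1 Hz master grid
    eff = config.preictal_effect
    pre_mask = _preictal_mask_1hz(config, annotations)
    activity = _activity_envelope(rng, config)

    # --- HR (1 Hz) --------------------------------------------------------
    hr = (70.0
          + _circadian(config, n1, 1.0, 6.0, peak_hour=16.0)
          + 12.0 * activity
          + _ou_noise(rng, n1, tau_s=300.0, sigma=3.0))
    hr = hr + np.float32(eff.hr_bpm) * pre_mask
    hr = np.clip(hr, 40.0, 190.0).astype(np.float32)

    # --- BVP (64 Hz): pulse waveform at the instantaneous heart rate -------
    # cycle phase accumulated in float64 (it grows to ~1e6 cycles), then
    # reduced mod 1 so the trig runs in fast float32
    cycles = np.cumsum(_repeat(hr, 64), dtype=np.float64) * (1.0 / (60.0 * 64.0))
    cycles %= 1.0
    phase = cycles.astype(np.float32)
    del cycles
    phase *= np.float32(2 * np.pi)
    amp = np.float32(40.0) * (1 + np.float32(0.3) * _repeat(activity, 64))
    bvp = np.sin(phase)
    bvp += np.float32(0.35) * np.sin(2 * phase + 1)
    bvp += np.float32(0.15) * np.sin(3 * phase + 2)
    bvp *= amp
    del phase, amp
    bvp += rng.standard_normal(bvp.size, dtype=np.float32)  # sensor noise
    bvp = bvp.astype(np.float32)

    # --- EDA (4 Hz): tonic level + Poisson phasic responses ----------------
    n4 = n1 * 4
    tonic = (1.5 + _circadian(config, n4, 4.0, 0.3, peak_hour=14.0)
             + _ou_noise(rng, n4, tau_s=600.0, sigma=0.25, rate=4.0))
    scr_rate = (1.0 / 60.0) * (1.0 + activity) \
        * (1.0 + (eff.eda_rate_mult - 1.0) * pre_mask)          # events/s at 1 Hz
    events_per_s = rng.poisson(scr_rate).astype(np.float32)
    impulses = np.zeros(n4, dtype=np.float32)
    impulses[::4] = events_per_s * rng.exponential(0.3, size=n1).astype(np.float32)
    tk = np.arange(0, 20.0, 0.25, dtype=np.float32)
    kernel = (1.0 - np.exp(-tk / 0.7)) * np.exp(-tk / 4.0)
    phasic = oaconvolve(impulses, kernel)[:n4].astype(np.float32)
    eda = np.clip(tonic + phasic, 0.01, None).astype(np.float32)

    # --- TEMP (4 Hz) -------------------------------------------------------
    temp = (32.5 + _circadian(config, n4, 4.0, 0.8, peak_hour=18.0)
            + _ou_noise(rng, n4, tau_s=1200.0, sigma=0.15, rate=4.0)
            + np.float32(eff.temp_drift_c) * _repeat(pre_mask, 4))
    temp = temp.astype(np.float32)

    # --- ACC (32 Hz): gravity + rest noise + ~2 Hz activity oscillation ----
    n32 = n1 * 32
    env32 = _repeat(activity, 32)
    tt = np.arange(n32, dtype=np.float64) / 32.0
    traces: dict[Modality, SignalTrace] = {}
    gravity = {"ACCX": 0.1, "ACCY": -0.2, "ACCZ": 0.97}
    for axis, mod in (("ACCX", Modality.ACCX), ("ACCY", Modality.ACCY), ("ACCZ", Modality.ACCZ)):
        osc_f = rng.uniform(1.6, 2.4)
        frac = osc_f * tt
        frac += rng.uniform(0, 1)
        frac %= 1.0
        osc = frac.astype(np.float32)
        del frac
        osc *= np.float32(2 * np.pi)
        np.sin(osc, out=osc)
        osc *= np.float32(0.35) * env32
        osc += np.float32(gravity[axis])
        osc += (np.float32(0.02) + np.float32(0.08) * env32) \
            * rng.standard_normal(n32, dtype=np.float32)
        traces[mod] = SignalTrace(mod, t0, 32.0, osc)
    del tt, env32

    traces[Modality.BVP] = SignalTrace(Modality.BVP, t0, 64.0, bvp)
    traces[Modality.EDA] = SignalTrace(Modality.EDA, t0, 4.0, eda)
    traces[Modality.TEMP] = SignalTrace(Modality.TEMP, t0, 4.0, temp)
    traces[Modality.HR] = SignalTrace(Modality.HR, t0, 1.0, hr)
    return MultimodalRecording("synthetic", {m: [tr] for m, tr in traces.items()})


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(recording: MultimodalRecording, config: SimulationConfig
                     ) -> tuple[MultimodalRecording, dict[str, list[tuple[float, float]]]]:
    """Insert motion bursts, EDA steps and flat segments; return ground truth.

    Motion bursts add broadband noise to all ACC axes and corrupt BVP; EDA
    steps jump by +60% (then fall back), exceeding the ±20%/−10% per-second
    quality thresholds at both edges; flat segments freeze BVP and TEMP.
    Events arrive at ``artifact_rate_per_hour``; rate 0 returns the recording
    unchanged.
    """
    truth: dict[str, list[tuple[float, float]]] = {"motion": [], "eda_step": [], "flat": []}
    if config.artifact_rate_per_hour == 0:
        return recording, truth
    rng = _rng_for(config, 2)
    t0, T = recording.span[0], recording.span[1] - recording.span[0]
    n_events = rng.poisson(config.artifact_rate_per_hour * T / 3600.0)
    new_traces = {m: [SignalTrace(tr.modality, tr.start_time, tr.rate, tr.samples.copy())
                      for tr in lst]
                  for m, lst in recording.traces.items()}

    def _span_idx(tr: SignalTrace, a: float, b: float) -> tuple[int, int]:
        i = int(max((a - tr.start_time) * tr.rate, 0))
        j = int(min((b - tr.start_time) * tr.rate, tr.samples.size))
        return i, max(j, i)

    for _ in range(n_events):
        kind = ("motion", "eda_step", "flat")[rng.integers(3)]
        start = t0 + rng.uniform(0, T - 180.0)
        if kind == "motion":
            dur = rng.uniform(10.0, 60.0)
            for mod in (Modality.ACCX, Modality.ACCY, Modality.ACCZ):
                tr = new_traces[mod][0]
                i, j = _span_idx(tr, start, start + dur)
                tr.samples[i:j] += 0.6 * rng.standard_normal(j - i)
            tr = new_traces[Modality.BVP][0]
            i, j = _span_idx(tr, start, start + dur)
            tr.samples[i:j] = 30.0 * rng.standard_normal(j - i)
        elif kind == "eda_step":
            dur = rng.uniform(30.0, 120.0)
            tr = new_traces[Modality.EDA][0]
            i, j = _span_idx(tr, start, start + dur)
            tr.samples[i:j] *= 1.6  # +60% step up, −37.5% step back down
        else:
            dur = rng.uniform(30.0, 120.0)
            for mod in (Modality.BVP, Modality.TEMP):
                tr = new_traces[mod][0]
                i, j = _span_idx(tr, start, start + dur)
                if j > i:
                    tr.samples[i:j] = tr.samples[i]
        truth[kind].append((start, start + dur))
    rec = MultimodalRecording(recording.subject_id, new_traces)
    return rec, truth


def simulate_to_dir(config: SimulationConfig, out_dir) -> tuple[Path, Path]:
    """Generate a full recording and write E4 session files + annotations.

    Returns (session_dir, annotations_path); the resolved config is saved
    alongside as YAML.
    """
    out_dir = Path(out_dir)
    ann = gen_seizure_times(config)
    rec = gen_recording(config, ann)
    if config.artifact_rate_per_hour > 0:
        rec, _ = inject_artifacts(rec, config)
    session_dir = out_dir / "session_000"
    write_session_dir({m: lst[0] for m, lst in rec.traces.items()}, session_dir)
    ann_path = out_dir / "annotations.csv"
    write_annotations(ann, ann_path)
    cfg = asdict(config)
    cfg["preictal_effect"] = asdict(config.preictal_effect)
    with open(out_dir / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return session_dir, ann_path
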