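"""Shared fixtures: small synthetic traces and recordings."""

from __future__ import annotations

import numpy as np
import pytest

import wristcast as w
from wristcast.e4_io import Modality, SignalTrace


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_trace(modality: Modality, rate: float, duration_s: float,
               values: np.ndarray | float, start: float = 0.0) -> SignalTrace:
    n = int(round(rate * duration_s))
    samples = np.broadcast_to(np.asarray(values, dtype=np.float64), (n,)).copy() \
        if np.isscalar(values) else np.asarray(values, dtype=np.float64)
    return SignalTrace(modality, start, rate, samples)


@pytest.fixture(scope="session")
def small_recording() -> tuple[w.SimulationConfig, w.SeizureAnnotations, w.MultimodalRecording]:
    """A 6-hour recording with two seizures and a mild preictal HR signature."""
    cfg = w.SimulationConfig(duration_days=0.25, seizure_rate_per_day=0.0,
                             artifact_rate_per_hour=0.0,
                             preictal_effect=w.PreictalEffect(hr_bpm=15.0),
                             seed=7)
    onsets = np.array([cfg.start_time + 2.0 * 3600, cfg.start_time + 5.0 * 3600])
    ann = w.SeizureAnnotations(onsets, "synthetic")
    rec = w.gen_recording(cfg, ann)
    return cfg, ann, rec
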