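"""Signal-quality indices versus literal-rule / brute-force DFT oracles."""

import numpy as np
import pytest

from wristcast.e4_io import Modality, SignalTrace
from wristcast.signal_quality import (SQIThresholds, acc_sqi,
                                      bvp_spectral_entropy, bvp_sqi,
                                      eda_artifact_seconds, eda_sqi)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain loops, literal rule text)
# ---------------------------------------------------------------------------

def oracle_eda_artifacts(x: np.ndarray, rate: int) -> np.ndarray:
    """Literal rule: mean-per-second change of >= +20% or <= -10% is artifact."""
    n_sec = len(x) // rate
    means = [np.mean(np.asarray(x[i * rate:(i + 1) * rate], dtype=np.float64))
             for i in range(n_sec)]
    art = [False]
    for t in range(1, n_sec):
        r = (means[t] - means[t - 1]) / max(means[t - 1], 1e-6)
        art.append(r >= 0.20 - 1e-12 or r <= -0.10 + 1e-12)
    return np.asarray(art)


def oracle_entropy(segment: np.ndarray, rate: int, window_s: int = 4) -> float:
    """Direct-DFT normalized spectral entropy averaged over 4-s windows."""
    nw = rate * window_s
    ents = []
    for k in range(len(segment) // nw):
        w = np.asarray(segment[k * nw:(k + 1) * nw], dtype=np.float64)
        w = w - w.mean()
        nbins = nw // 2
        power = np.empty(nbins)
        for j in range(1, nbins + 1):  # literal DFT, DC excluded
            e = np.exp(-2j * np.pi * j * np.arange(nw) / nw)
            power[j - 1] = abs(np.sum(w * e)) ** 2
        tot = power.sum()
        if tot == 0:
            ents.append(1.0)
            continue
        q = power / tot
        q = q[q > 0]
        ents.append(float(-(q * np.log(q)).sum() / np.log(nbins)))
    return float(np.mean(ents))


def oracle_acc_ratio(mag: np.ndarray, rate: int = 32, window_s: int = 4) -> np.ndarray:
    """Per-4-s-segment narrowband/broadband periodogram power ratio."""
    nw = rate * window_s
    out = []
    for k in range(len(mag) // nw):
        w = np.asarray(mag[k * nw:(k + 1) * nw], dtype=np.float64)
        w = w - w.mean()
        spec = np.abs(np.fft.rfft(w)) ** 2
        freqs = np.fft.rfftfreq(nw, 1 / rate)
        broad = spec[(freqs >= 0.8 - 1e-12)].sum()
        narrow = spec[(freqs >= 0.8 - 1e-12) & (freqs <= 5 + 1e-12)].sum()
        out.append(narrow / broad if broad > 0 else 0.0)
    return np.asarray(out)


def _eda_trace(x, rate=4):
    return SignalTrace(Modality.EDA, 0.0, float(rate), x)


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

class TestEdaSqi:
    def test_constant_minute_good(self):
        q = eda_sqi(_eda_trace(np.full(240, 1.0)))
        assert q.sqi.tolist() == [1.0] and q.good.tolist() == [True]

    @pytest.mark.parametrize("jump,flagged", [
        (1.30, True),    # +30% rise: artifact
        (1.20, True),    # boundary rise: artifact
        (1.19, False),   # below the rise threshold
        (0.90, True),    # boundary fall: artifact
        (0.905, False),  # -9.5% fall: clean
    ])
    def test_single_second_jump(self, jump, flagged):
        x = np.ones(240)
        x[120:] = jump
        assert bool(eda_artifact_seconds(_eda_trace(x))[30]) is flagged

    def test_steady_five_percent_decay_clean(self):
        x = 2.0 * 0.95 ** np.floor(np.arange(240) / 4)
        assert not eda_artifact_seconds(_eda_trace(x)).any()

    def test_minute_good_requires_every_second_clean(self):
        x = np.ones(240)
        x[100:104] = 1.5  # one corrupted second
        q = eda_sqi(_eda_trace(x))
        assert not q.good[0]
        assert q.sqi[0] == pytest.approx(58 / 60)  # jump up + jump back down

    def test_scale_invariance(self, rng):
        x = 1.0 + 0.02 * rng.standard_normal(480).cumsum() / 20
        x = np.abs(x) + 0.5
        base = eda_sqi(_eda_trace(x)).sqi
        for c in (0.1, 3.0, 1e3):
            np.testing.assert_allclose(eda_sqi(_eda_trace(c * x)).sqi, base, atol=1e-12)

    def test_short_trace_empty(self):
        assert eda_sqi(_eda_trace(np.ones(4))).sqi.size == 0


# ---------------------------------------------------------------------------
# BVP spectral entropy
# ---------------------------------------------------------------------------

class TestBvpEntropy:
    def test_pure_sinusoid_low_entropy(self):
        t = np.arange(64 * 60) / 64
        ent = bvp_spectral_entropy(np.sin(2 * np.pi * 1.2 * t))
        assert ent < 0.3

    def test_white_noise_high_entropy(self, rng):
        ent = bvp_spectral_entropy(rng.uniform(-1, 1, 64 * 60))
        assert ent > 0.9

    def test_entropy_exactly_cutoff_not_good(self):
        # the good-quality rule is *strictly* below 0.9
        thresholds = SQIThresholds()
        q = bvp_sqi(SignalTrace(Modality.BVP, 0.0, 64.0,
                                np.random.default_rng(0).uniform(-1, 1, 64 * 60)),
                    thresholds)
        ent = 1.0 - q.sqi[0]
        assert bool(q.good[0]) == (ent < thresholds.bvp_entropy_cutoff)
        assert not (0.9 < thresholds.bvp_entropy_cutoff)  # cutoff itself excluded

    def test_clean_pulse_good_noise_bad(self, rng):
        t = np.arange(64 * 60) / 64
        ph = 2 * np.pi * 1.2 * t
        pulse = np.sin(ph) + 0.35 * np.sin(2 * ph + 1) + 0.15 * np.sin(3 * ph + 2)
        good = bvp_sqi(SignalTrace(Modality.BVP, 0.0, 64.0, pulse))
        bad = bvp_sqi(SignalTrace(Modality.BVP, 0.0, 64.0, rng.normal(size=64 * 60)))
        assert good.good[0] and not bad.good[0]

    def test_amplitude_invariance(self, rng):
        x = rng.normal(size=64 * 60)
        assert bvp_spectral_entropy(x) == pytest.approx(bvp_spectral_entropy(100 * x), abs=1e-12)

    def test_added_broadband_noise_never_decreases_entropy(self, rng):
        t = np.arange(64 * 60) / 64
        clean = np.sin(2 * np.pi * 1.3 * t)
        prev = bvp_spectral_entropy(clean)
        noise = rng.normal(size=clean.size)
        for sigma in (0.1, 0.5, 2.0, 8.0):
            ent = bvp_spectral_entropy(clean + sigma * noise)
            assert ent > prev - 0.02
            prev = ent

    def test_constant_window_warns_entropy_one(self):
        with pytest.warns(UserWarning, match="constant"):
            ent = bvp_spectral_entropy(np.zeros(64 * 60))
        assert ent == 1.0


# ---------------------------------------------------------------------------
# ACC band-power ratio
# ---------------------------------------------------------------------------

def _acc_traces(mag):
    z = np.zeros_like(mag)
    mk = lambda v: SignalTrace(Modality.ACCX, 0.0, 32.0, v)  # noqa: E731
    return mk(mag), mk(z), mk(z)


class TestAccSqi:
    def test_in_band_sinusoid(self):
        t = np.arange(32 * 60) / 32
        q = acc_sqi(*_acc_traces(2.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)))
        assert q.sqi[0] == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_sinusoid(self):
        t = np.arange(32 * 60) / 32
        q = acc_sqi(*_acc_traces(2.0 + 0.3 * np.sin(2 * np.pi * 10.0 * t)))
        assert q.sqi[0] == pytest.approx(0.0, abs=0.05)

    def test_equal_power_mixture(self):
        t = np.arange(32 * 60) / 32
        mag = 2.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t) + 0.3 * np.sin(2 * np.pi * 10.0 * t)
        q = acc_sqi(*_acc_traces(mag))
        assert q.sqi[0] == pytest.approx(0.5, abs=0.05)

    def test_amplitude_invariance(self, rng):
        x = rng.normal(size=32 * 60)
        y = rng.normal(size=32 * 60)
        z = rng.normal(size=32 * 60)
        mk = lambda v: SignalTrace(Modality.ACCX, 0.0, 32.0, v)  # noqa: E731
        q1 = acc_sqi(mk(x), mk(y), mk(z)).sqi
        q2 = acc_sqi(mk(5 * x), mk(5 * y), mk(5 * z)).sqi
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_missing_axis_rejected(self):
        t, _, _ = _acc_traces(np.ones(32 * 60))
        short = SignalTrace(Modality.ACCY, 0.0, 32.0, np.ones(10))
        with pytest.raises(ValueError):
            acc_sqi(t, short, t)


# ---------------------------------------------------------------------------
# Oracle agreement on random synthetic minutes
# ---------------------------------------------------------------------------

class TestOracleAgreement:
    N_MINUTES = 100

    def test_eda_rule_agreement(self, rng):
        for _ in range(self.N_MINUTES):
            x = np.abs(1.0 + 0.15 * rng.standard_normal(240)).cumsum() / 50 + 0.2
            got = eda_artifact_seconds(_eda_trace(x))
            np.testing.assert_array_equal(got, oracle_eda_artifacts(x, 4))

    def test_bvp_entropy_agreement(self, rng):
        worst = 0.0
        for _ in range(self.N_MINUTES):
            x = rng.normal(size=64 * 4)  # one 4-s window per draw keeps the literal DFT cheap
            got = bvp_spectral_entropy(x, rate=64)
            want = oracle_entropy(x, 64)
            worst = max(worst, abs(got - want))
        assert worst < 1e-9

    def test_acc_ratio_agreement(self, rng):
        worst = 0.0
        for _ in range(self.N_MINUTES):
            mag = np.abs(1.0 + rng.normal(size=32 * 60) * rng.uniform(0.05, 0.5))
            q = acc_sqi(*_acc_traces(mag))
            want = oracle_acc_ratio(mag).mean()
            worst = max(worst, abs(float(q.sqi[0]) - want))
        assert worst < 1e-9
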