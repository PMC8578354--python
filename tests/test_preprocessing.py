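"""Resampling, channel assembly, FFT features and normalization."""

import numpy as np
import pytest


from wristcast.e4_io import Modality, MultimodalRecording, SignalTrace
from wristcast.preprocessing import (CHANNELS, SEGMENT_SAMPLES, SegmentBatch,
                                     acc_magnitude, apply_normalization,
                                     assemble_segments, fft_feature_channel,
                                     fit_normalization, resample_to_grid,
                                     time_of_day_channel)
from wristcast.pipeline import compute_quality


class TestResample:
    def test_hr_minute_gives_7680_samples(self):
        tr = SignalTrace(Modality.HR, 0.0, 1.0, np.linspace(60, 80, 60))
        out = resample_to_grid(tr)
        assert out.samples.size == 7680 and out.rate == 128.0

    def test_constant_preserved_exactly(self):
        tr = SignalTrace(Modality.TEMP, 0.0, 4.0, np.full(240, 36.5))
        out = resample_to_grid(tr)
        np.testing.assert_array_equal(out.samples, 36.5)

    def test_linear_ramp_reproduced(self):
        ramp = np.linspace(0.0, 1.0, 240)
        out = resample_to_grid(SignalTrace(Modality.EDA, 0.0, 4.0, ramp))
        ideal = np.interp(np.arange(7680) * 4 / 128, np.arange(240), ramp)
        assert np.max(np.abs(out.samples - ideal)) < 1e-6

    def test_bandlimited_content_preserved(self):
        t = np.arange(64 * 10) / 64
        x = np.sin(2 * np.pi * 1.5 * t)
        out = resample_to_grid(SignalTrace(Modality.BVP, 0.0, 64.0, x))
        t128 = np.arange(out.samples.size) / 128
        ideal = np.sin(2 * np.pi * 1.5 * t128)
        mid = slice(256, -256)  # edges suffer filter transients
        rms = np.sqrt(np.mean((out.samples[mid] - ideal[mid]) ** 2))
        assert rms < 0.01 * np.sqrt(0.5)

    def test_unsupported_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            resample_to_grid(SignalTrace(Modality.EDA, 0.0, 3.0, np.zeros(30)))


class TestAccMagnitude:
    @pytest.mark.parametrize("xyz,expected", [
        ((3.0, 4.0, 0.0), 5.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 1.0, 1.0), np.sqrt(3.0)),
    ])
    def test_pythagoras(self, xyz, expected):
        mk = lambda v: SignalTrace(Modality.ACCX, 0.0, 32.0, np.full(4, v))  # noqa: E731
        mag = acc_magnitude(mk(xyz[0]), mk(xyz[1]), mk(xyz[2]))
        np.testing.assert_allclose(mag.samples, expected)

    def test_misaligned_rejected(self):
        a = SignalTrace(Modality.ACCX, 0.0, 32.0, np.zeros(8))
        b = SignalTrace(Modality.ACCY, 1.0, 32.0, np.zeros(8))
        with pytest.raises(ValueError):
            acc_magnitude(a, b, a)


class TestFftChannel:
    def test_zero_segment_gives_zero_channel(self):
        np.testing.assert_array_equal(fft_feature_channel(np.zeros(7680)), 0.0)

    def test_sinusoid_peak_at_expected_bin(self):
        t = np.arange(7680) / 128
        ch = fft_feature_channel(np.sin(2 * np.pi * 1.0 * t))
        # 1 Hz <-> spectrum bin 60 of 3841, stretched onto 7680 samples
        peak = np.argmax(ch)
        expected = 60 * (7680 - 1) / 3840
        assert abs(peak - expected) <= 1

    def test_parseval(self, rng):
        x = rng.normal(size=7680)
        spec = np.abs(np.fft.rfft(x - x.mean()))
        energy_spec = (spec[0] ** 2 + 2 * np.sum(spec[1:-1] ** 2) + spec[-1] ** 2) / 7680
        energy_time = np.sum((x - x.mean()) ** 2)
        assert energy_spec == pytest.approx(energy_time, rel=1e-6)
        # and the channel is exactly that spectrum, stretched
        ch = fft_feature_channel(x)
        assert ch[0] == pytest.approx(spec[0])
        assert ch[-1] == pytest.approx(spec[-1])


class TestTimeOfDay:
    @pytest.mark.parametrize("hms,expected", [((13, 59), 13), ((0, 30), 0), ((23, 59), 23)])
    def test_hour_portion(self, hms, expected):
        day0 = 1_600_041_600.0  # a UTC midnight
        start = day0 + hms[0] * 3600 + hms[1] * 60
        ch = time_of_day_channel(start, "UTC")
        assert ch.shape == (7680,)
        assert np.unique(ch).tolist() == [float(expected)]

    def test_timezone_shifts_hour(self):
        day0 = 1_600_041_600.0
        assert time_of_day_channel(day0 + 3 * 3600, "America/Chicago")[0] != \
            time_of_day_channel(day0 + 3 * 3600, "UTC")[0]


@pytest.fixture(scope="module")
def assembled(small_recording):
    _, _, rec = small_recording
    quality = compute_quality(rec)
    batch, excluded = assemble_segments(rec, quality, stride=1)
    return rec, quality, batch, excluded


class TestAssembly:
    def test_seventeen_channels_in_order(self, assembled):
        _, _, batch, _ = assembled
        assert batch.channels == CHANNELS
        assert len(CHANNELS) == 17
        assert batch.segments.shape[1:] == (17, SEGMENT_SAMPLES)

    def test_contiguous_non_overlapping_minutes(self, assembled):
        _, _, batch, _ = assembled
        diffs = np.diff(batch.start_times)
        assert (diffs >= 60.0).all()

    def test_sqi_and_tod_channels_constant_within_segment(self, assembled):
        _, quality, batch, _ = assembled
        i_sqi = CHANNELS.index("SQI_EDA")
        i_tod = CHANNELS.index("TIME_OF_DAY")
        assert np.ptp(batch.segments[0, i_sqi]) == 0
        assert np.ptp(batch.segments[0, i_tod]) == 0
        assert batch.segments[0, i_sqi, 0] == pytest.approx(
            quality["EDA"].value_at(batch.start_times[0]), abs=1e-6)

    def test_minute_with_missing_modality_excluded(self, small_recording):
        _, _, rec = small_recording
        # drop the final 10 min of BVP only
        traces = {m: list(v) for m, v in rec.traces.items()}
        bvp = traces[Modality.BVP][0]
        traces[Modality.BVP] = [SignalTrace(Modality.BVP, bvp.start_time, bvp.rate,
                                            bvp.samples[:-64 * 600])]
        rec2 = MultimodalRecording("s", traces)
        q = compute_quality(rec2)
        full_minutes = np.arange(int(rec.span[0]), int(rec.span[1]), 60, dtype=float)
        batch, excluded = assemble_segments(rec2, q, segment_starts=full_minutes)
        assert excluded.size >= 10
        assert batch.start_times.max() < bvp.end_time - 600 + 60

    def test_stride_decimates_timesteps(self, small_recording):
        _, _, rec = small_recording
        q = compute_quality(rec)
        batch, _ = assemble_segments(rec, q, stride=256)
        assert batch.segments.shape[2] == 30
        full, _ = assemble_segments(rec, q, segment_starts=batch.start_times[:2], stride=1)
        # strided raw channels sample the same instants as the full-resolution grid
        i_hr = CHANNELS.index("HR")
        np.testing.assert_allclose(batch.segments[:2, i_hr],
                                   full.segments[:, i_hr, ::256], rtol=1e-5)


class TestSerialization:
    def test_hdf5_round_trip_preserves_layout_and_values(self, rng, tmp_path):
        segs = rng.normal(size=(5, 17, 30)).astype(np.float32)
        b = SegmentBatch(segs, 60.0 * np.arange(5),
                         np.array([0, 1, 2, 0, 1], np.int8), stride=256)
        path = tmp_path / "batch.h5"
        b.save(path)
        back = SegmentBatch.load(path)
        assert back.channels == b.channels and back.stride == 256
        np.testing.assert_array_equal(back.segments, b.segments)
        np.testing.assert_array_equal(back.labels, b.labels)
        np.testing.assert_array_equal(back.start_times, b.start_times)


class TestNormalization:
    def _batch(self, rng, n=8, shift=0.0):
        segs = rng.normal(loc=shift, size=(n, 17, 64)).astype(np.float32)
        return SegmentBatch(segs, np.arange(n) * 60.0, np.zeros(n, np.int8),
                            stride=120)

    def test_zscore_identity_on_train(self, rng):
        b = self._batch(rng)
        stats = fit_normalization(b)
        z = apply_normalization(b, stats)
        assert np.abs(z.segments.mean(axis=(0, 2))).max() < 1e-5
        np.testing.assert_allclose(z.segments.std(axis=(0, 2)), 1.0, atol=1e-5)

    def test_constant_channel_sd_one_with_warning(self, rng):
        b = self._batch(rng)
        b.segments[:, 3, :] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = fit_normalization(b)
        assert stats.std[3] == 1.0
        z = apply_normalization(b, stats)
        np.testing.assert_allclose(z.segments[:, 3, :], 0.0, atol=1e-6)

    def test_test_batch_keeps_train_statistics(self, rng):
        train = self._batch(rng)
        test = self._batch(rng, shift=2.0)
        stats = fit_normalization(train)
        z = apply_normalization(test, stats)
        # shifted distribution: mean under train stats is far from zero
        assert z.segments.mean() > 1.0
        own = apply_normalization(test, fit_normalization(test))
        assert abs(own.segments.mean()) < 1e-5

    def test_affine_invertible(self, rng):
        b = self._batch(rng)
        stats = fit_normalization(b)
        z = apply_normalization(b, stats)
        back = z.segments * stats.std[None, :, None] + stats.mean[None, :, None]
        np.testing.assert_allclose(back, b.segments, rtol=1e-4, atol=1e-5)
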