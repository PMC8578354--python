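"""Synthetic recording generator: determinism, event statistics, signatures."""

import numpy as np
import pytest
from scipy import stats as sps

import wristcast as w
from wristcast.e4_io import Modality, NATIVE_RATES, SeizureAnnotations
from wristcast.signal_quality import acc_sqi, eda_artifact_seconds
from wristcast.synthetic import (PreictalEffect, SimulationConfig,
                                 gen_recording, gen_seizure_times,
                                 inject_artifacts)


class TestSeizureTimes:
    def test_zero_rate_zero_onsets(self):
        cfg = SimulationConfig(duration_days=5, seizure_rate_per_day=0.0, seed=0)
        assert len(gen_seizure_times(cfg)) == 0

    def test_count_within_poisson_interval(self):
        cfg = SimulationConfig(duration_days=30, seizure_rate_per_day=1.0,
                               cluster_prob=0.0, circadian_concentration=0.0,
                               seed=42)
        n = len(gen_seizure_times(cfg))
        lo, hi = sps.poisson.ppf([0.005, 0.995], 30)
        assert lo <= n <= hi

    def test_uniform_hours_when_concentration_zero(self):
        cfg = SimulationConfig(duration_days=400, seizure_rate_per_day=1.5,
                               cluster_prob=0.0, circadian_concentration=0.0,
                               seed=5)
        onsets = gen_seizure_times(cfg).onsets
        assert onsets.size >= 500
        hours = ((onsets / 3600.0) % 24).astype(int)
        counts = np.bincount(hours, minlength=24)
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_circadian_concentration_peaks_onsets(self):
        cfg = SimulationConfig(duration_days=400, seizure_rate_per_day=1.5,
                               cluster_prob=0.0, circadian_concentration=2.0,
                               circadian_peak_hour=8.0, seed=5)
        onsets = gen_seizure_times(cfg).onsets
        hours = ((onsets / 3600.0) % 24).astype(int)
        counts = np.bincount(hours, minlength=24)
        assert sps.chisquare(counts).pvalue < 1e-4

    def test_clustering_produces_sub_four_hour_gaps(self):
        cfg = SimulationConfig(duration_days=60, seizure_rate_per_day=1.0,
                               cluster_prob=0.5, circadian_concentration=0.0,
                               seed=2)
        onsets = gen_seizure_times(cfg).onsets
        gaps = np.diff(onsets)
        assert (gaps < 4 * 3600).any()

    def test_determinism(self):
        cfg = SimulationConfig(duration_days=10, seed=11)
        a, b = gen_seizure_times(cfg), gen_seizure_times(cfg)
        np.testing.assert_array_equal(a.onsets, b.onsets)


class TestRecording:
    def test_trace_lengths_match_rate_times_duration(self, small_recording):
        cfg, _, rec = small_recording
        for mod, rate in NATIVE_RATES.items():
            tr = rec.traces[mod][0]
            assert tr.samples.size == int(rate * cfg.duration_s)
            assert tr.rate == rate

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(duration_days=0.05, seed=9)
        ann = gen_seizure_times(cfg)
        r1, r2 = gen_recording(cfg, ann), gen_recording(cfg, ann)
        for mod in Modality:
            np.testing.assert_array_equal(r1.traces[mod][0].samples,
                                          r2.traces[mod][0].samples)

    def test_annotations_outside_duration_rejected(self):
        cfg = SimulationConfig(duration_days=0.05, seed=0)
        bad = SeizureAnnotations([cfg.start_time + cfg.duration_s + 10.0])
        with pytest.raises(ValueError, match="outside"):
            gen_recording(cfg, bad)

    def test_physiological_baselines(self, small_recording):
        _, _, rec = small_recording
        hr = rec.traces[Modality.HR][0].samples
        temp = rec.traces[Modality.TEMP][0].samples
        eda = rec.traces[Modality.EDA][0].samples
        assert 50 < hr.mean() < 110
        assert 29 < temp.mean() < 36
        assert (eda > 0).all()

    def test_hr_rise_effect_recovered_by_paired_averaging(self):
        # the same seed with and without the planted effect differs exactly by
        # the injected signature, isolating it from circadian/noise structure
        base = dict(duration_days=0.5, seizure_rate_per_day=0.0,
                    artifact_rate_per_hour=0.0, seed=17)
        cfg_eff = SimulationConfig(preictal_effect=PreictalEffect(hr_bpm=15.0), **base)
        cfg_null = SimulationConfig(preictal_effect=PreictalEffect(), **base)
        onset = cfg_eff.start_time + 6 * 3600.0
        ann = SeizureAnnotations([onset])
        hr_eff = gen_recording(cfg_eff, ann).traces[Modality.HR][0].samples
        hr_null = gen_recording(cfg_null, ann).traces[Modality.HR][0].samples
        diff = hr_eff.astype(float) - hr_null.astype(float)
        sec0 = int(onset - 75 * 60 - cfg_eff.start_time)
        sec1 = int(onset - 15 * 60 - cfg_eff.start_time)
        assert diff[sec0:sec1].mean() == pytest.approx(15.0, abs=2.0)
        outside = np.concatenate([diff[: sec0 - 120], diff[sec1 + 120:]])
        assert np.abs(outside).max() < 1e-3

    def test_null_effect_statistically_indistinguishable(self):
        # windows at seizure-like positions vs matched control windows drawn
        # from the same process must share one distribution under a null effect
        cfg = SimulationConfig(duration_days=5.0, seizure_rate_per_day=0.0,
                               artifact_rate_per_hour=0.0,
                               preictal_effect=PreictalEffect(), seed=21)
        rng = np.random.default_rng(0)
        slots = cfg.start_time + 3600.0 * rng.permutation(np.arange(3, 117, 3))
        onsets, controls = np.sort(slots[:18]), np.sort(slots[18:36])
        rec = gen_recording(cfg, SeizureAnnotations(onsets))
        for mod in (Modality.HR, Modality.EDA, Modality.TEMP):
            tr = rec.traces[mod][0]
            rate = int(tr.rate)

            def window_means(times):
                out = []
                for o in times:
                    a = int((o - 75 * 60 - cfg.start_time) * rate)
                    b = int((o - 15 * 60 - cfg.start_time) * rate)
                    out.append(tr.samples[a:b].mean())
                return np.asarray(out)

            p = sps.ks_2samp(window_means(onsets), window_means(controls)).pvalue
            assert p > 0.01, mod


@pytest.fixture(scope="module")
def with_artifacts():
    cfg = SimulationConfig(duration_days=0.25, seizure_rate_per_day=0.0,
                           artifact_rate_per_hour=4.0,
                           preictal_effect=PreictalEffect(), seed=13)
    ann = SeizureAnnotations(np.empty(0))
    clean = gen_recording(cfg, ann)
    dirty, truth = inject_artifacts(clean, cfg)
    return cfg, clean, dirty, truth


class TestArtifacts:
    def test_zero_rate_unchanged(self, small_recording):
        cfg, _, rec = small_recording
        out, truth = inject_artifacts(rec, cfg)
        assert all(not v for v in truth.values())
        np.testing.assert_array_equal(out.traces[Modality.EDA][0].samples,
                                      rec.traces[Modality.EDA][0].samples)

    def test_eda_step_flagged_by_sqi(self, with_artifacts):
        _, _, dirty, truth = with_artifacts
        assert truth["eda_step"], "fixture must generate at least one EDA step"
        art = eda_artifact_seconds(dirty.traces[Modality.EDA][0])
        tr = dirty.traces[Modality.EDA][0]
        hits = 0
        for start, _end in truth["eda_step"]:
            sec = int(start - tr.start_time)
            if art[max(sec - 1, 0): sec + 3].any():
                hits += 1
        assert hits == len(truth["eda_step"])

    def test_motion_burst_lowers_acc_sqi(self, with_artifacts):
        _, clean, dirty, truth = with_artifacts
        assert truth["motion"], "fixture must generate at least one motion burst"
        axes = lambda r: [r.traces[m][0] for m in  # noqa: E731
                          (Modality.ACCX, Modality.ACCY, Modality.ACCZ)]
        q_clean = acc_sqi(*axes(clean))
        q_dirty = acc_sqi(*axes(dirty))
        start, _ = truth["motion"][0]
        minute = int((start - clean.span[0]) // 60)
        assert q_dirty.sqi[minute] < q_clean.sqi[minute]

    def test_originals_not_mutated(self, with_artifacts):
        _, clean, dirty, _ = with_artifacts
        assert clean.traces[Modality.BVP][0].samples is not dirty.traces[Modality.BVP][0].samples
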