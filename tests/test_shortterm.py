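"""Short-term characterizations: square-wave encoder, medianRRI, alpha asymmetry."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_stream, single_event_schedule
from stressense.characterize import event_f1
from stressense.shortterm import (
    SlopeDetectorConfig,
    alpha_asymmetry,
    blink_siginc,
    detect_sig_slope_increases,
    gsr_siginc,
    median_rri,
    smooth_running_mean,
)
from stressense.streams import SensorStream
from stressense.synth import (
    ParticipantProfile,
    make_schedule,
    simulate_blinks,
    simulate_eeg,
    simulate_gsr,
)


class TestSmoothing:
    def test_constant_unchanged(self):
        t = np.arange(100) / 10.0
        assert np.allclose(smooth_running_mean(t, np.full(100, 2.0), 1.0), 2.0)

    def test_ramp_preserved_interiorly(self):
        t = np.arange(100) / 10.0
        out = smooth_running_mean(t, 3.0 * t, 1.0)
        assert np.allclose(out[10:-10], 3.0 * t[10:-10])

    def test_nyquist_alternation_suppressed(self):
        # +-1 alternation under a 5-sample window: direct convolution gives 1/5
        t = np.arange(64) / 10.0
        x = np.where(np.arange(64) % 2 == 0, 1.0, -1.0)
        out = smooth_running_mean(t, x, 0.5)
        assert np.max(np.abs(out[5:-5])) <= 0.2 + 1e-12

    def test_subsample_window_rejected(self):
        t = np.arange(10) / 10.0
        with pytest.raises(ValueError, match="2 samples"):
            smooth_running_mean(t, np.zeros(10), 0.05)


class TestSlopeDetector:
    def test_flat_signal_no_events(self):
        t = np.arange(200) / 10.0
        sw = detect_sig_slope_increases(t, np.full(200, 1.0))
        assert len(sw) == 0

    def test_three_injected_responses_recovered(self):
        from stressense.synth import sustained_kernel

        t = np.arange(3000) / 10.0
        x = np.full(t.size, 5.0)
        onsets = [50.0, 150.0, 250.0]
        for on in onsets:
            x += 0.8 * sustained_kernel(t - on, 6.0)
        rng = np.random.default_rng(1)
        x += rng.normal(0, 0.005, t.size)
        sm = smooth_running_mean(t, x, 1.0)
        sw = detect_sig_slope_increases(t, sm)
        assert len(sw) == 3
        assert np.allclose(sorted(sw.onsets), onsets, atol=0.5)

    def test_step_height_recovered(self):
        t = np.arange(500) / 10.0
        x = np.where(t >= 25.0, 7.0, 2.0) + np.random.default_rng(0).normal(0, 1e-3, 500)
        sm = smooth_running_mean(t, x, 1.0)
        sw = detect_sig_slope_increases(t, sm, SlopeDetectorConfig(min_event_s=0.3))
        assert len(sw) == 1
        assert sw.events[0].height == pytest.approx(7.0, abs=0.05)

    @given(offset=st.floats(-10, 10), scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariant_scale_equivariant(self, offset, scale):
        # MAD-based threshold: adding a constant leaves events unchanged,
        # positive scaling scales heights (minus the offset) accordingly
        t = np.arange(1500) / 10.0
        rng = np.random.default_rng(7)
        x = 5.0 + 0.8 * np.exp(-((t - 60) ** 2) / 4) + rng.normal(0, 0.004, t.size)
        base = detect_sig_slope_increases(t, x)
        moved = detect_sig_slope_increases(t, offset + scale * x)
        assert len(moved) == len(base)
        for a, b in zip(base.events, moved.events):
            assert b.onset == pytest.approx(a.onset, abs=1e-9)
            assert b.height == pytest.approx(offset + scale * a.height, rel=1e-6)


class TestGsrSiginc:
    def test_rest_session_near_zero_density(self):
        from stressense.synth import StressorSchedule

        gsr = simulate_gsr(StressorSchedule([], 300), ParticipantProfile(), 0, seed=3)
        sw = gsr_siginc(gsr)
        enc = sw.grid_encoding()
        assert np.mean(enc.values > 0) < 0.02

    def test_event_recovery_f1(self):
        # square-wave encoder recovers the schedule (F1 >= 0.9 over sessions)
        prof = ParticipantProfile()
        f1s = []
        for seed in range(5):
            sched = make_schedule(300, 8, 12, seed=seed)
            gsr = simulate_gsr(sched, prof, 0, seed=seed + 50)
            sw = gsr_siginc(gsr)
            truth = np.array([e.onset for e in sched.events]) + prof.delays["gsr"]
            f1s.append(event_f1(sw.onsets, truth, tol_s=2.0)[2])
        assert np.mean(f1s) >= 0.9

    def test_precision_degrades_monotonically_with_noise(self):
        prof = ParticipantProfile()
        sched = make_schedule(300, 8, 12, seed=4)
        truth = np.array([e.onset for e in sched.events]) + prof.delays["gsr"]
        f1s = []
        for noise in (0.005, 0.05, 0.4):
            f1_reps = []
            for rep in range(3):
                gsr = simulate_gsr(sched, prof, 0, seed=100 + rep, noise_sd=noise)
                f1_reps.append(event_f1(gsr_siginc(gsr).onsets, truth, tol_s=2.0)[2])
            f1s.append(np.mean(f1_reps))
        assert f1s[0] >= f1s[1] >= f1s[2] - 0.05

    def test_doubling_gain_doubles_heights(self):
        sched = single_event_schedule(onset=100, duration=6)
        base = ParticipantProfile()
        double = dataclasses.replace(base, scr_gain=2 * base.scr_gain)
        h1 = gsr_siginc(simulate_gsr(sched, base, 0, 9, noise_sd=0.0)).events[0].height
        h2 = gsr_siginc(simulate_gsr(sched, double, 0, 9, noise_sd=0.0)).events[0].height
        assert (h2 - base.scl_baseline) == pytest.approx(
            2 * (h1 - base.scl_baseline), rel=0.1)


class TestBlinkSiginc:
    def test_zero_stream_empty(self):
        b = make_stream(np.zeros(1280), rate=128.0, name="blink_strength")
        assert len(blink_siginc(b)) == 0

    def test_heights_bounded_by_255(self, schedule, profile):
        b = simulate_blinks(schedule, profile, seed=6)
        sw = blink_siginc(b)
        assert all(e.height <= 255.0 for e in sw.events)

    def test_bursts_detected_inside_event_windows(self, profile):
        sched = single_event_schedule(onset=100, duration=20)
        burst_prof = dataclasses.replace(profile, blink_base_rate=1.0)
        b = simulate_blinks(sched, burst_prof, seed=8)
        sw = blink_siginc(b)
        window = [o for o in sw.onsets
                  if 100 + profile.delays["blink"] - 1 <= o <= 120 + profile.delays["blink"] + 1]
        assert len(window) >= 1


class TestMedianRri:
    def test_constant_rr(self):
        beats = np.arange(1, 60, 1.0)
        ibi = SensorStream("ibi_event", beats, np.full(beats.size, 1.0))
        out = median_rri(ibi)
        assert np.allclose(out.dropna().values, 1.0)

    def test_median_then_reciprocal(self):
        # RR window {0.8, 1.0, 1.2}: median 1.0, reciprocal 1.0
        beats = np.array([1.0, 2.0, 3.0])
        ibi = SensorStream("ibi_event", beats, np.array([0.8, 1.0, 1.2]))
        out = median_rri(ibi, window_s=5.0)
        # window centered at t=2 covers all three beats: median RR = 1.0
        at_2s = np.searchsorted(out.timestamps, 2.0)
        assert out.values[at_2s] == pytest.approx(1.0)

    def test_empty_series_errors(self):
        ibi = SensorStream("ibi_event", np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            median_rri(ibi)


class TestAlphaAsymmetry:
    def _tone_eeg(self, left_amp, right_amp, n=2560, rate=256.0):
        t = np.arange(n) / rate
        eeg = {}
        for ch in ("F3", "FC3", "C3"):
            eeg[ch] = SensorStream(ch, t, left_amp * np.sin(2 * np.pi * 10 * t),
                                   nominal_rate=rate)
        for ch in ("F4", "FC4", "C4"):
            eeg[ch] = SensorStream(ch, t, right_amp * np.sin(2 * np.pi * 10 * t),
                                   nominal_rate=rate)
        return eeg

    def test_identical_hemispheres_zero(self):
        out = alpha_asymmetry(self._tone_eeg(5.0, 5.0))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_double_right_amplitude_triples_left_power(self):
        # amplitude x2 -> power x4, so right - left = 3x left power
        out = alpha_asymmetry(self._tone_eeg(5.0, 10.0))
        left = alpha_asymmetry(self._tone_eeg(5.0, 0.0))
        left_power = -left.values.mean()
        assert out.values.mean() == pytest.approx(3 * left_power, rel=0.05)

    def test_antisymmetric_under_hemisphere_swap(self):
        eeg = self._tone_eeg(3.0, 7.0)
        swapped = {"F3": eeg["F4"], "FC3": eeg["FC4"], "C3": eeg["C4"],
                   "F4": eeg["F3"], "FC4": eeg["FC3"], "C4": eeg["C3"]}
        a = alpha_asymmetry(eeg)
        b = alpha_asymmetry(swapped)
        assert np.allclose(a.values, -b.values, atol=1e-9)

    def test_missing_channel_named(self, schedule, profile):
        eeg = simulate_eeg(schedule, profile, seed=0)
        del eeg["FC4"]
        with pytest.raises(ValueError, match="FC4"):
            alpha_asymmetry(eeg)
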