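"""Synthetic cohort generator: determinism, response structure, habituation."""

import dataclasses

import numpy as np
import pytest

from conftest import single_event_schedule
from stressense.characterize import (
    estimate_rate_step_delay,
    estimate_response_delay,
)
from stressense.longterm import detect_blink_events, gsr_scl
from stressense.streams import write_session, align_streams
from stressense.synth import (
    ParticipantProfile,
    SimConfig,
    StressorSchedule,
    make_schedule,
    scr_kernel,
    simulate_blinks,
    simulate_cohort,
    simulate_eeg,
    simulate_gsr,
    simulate_ibi,
    simulate_joystick,
    simulate_lever,
    simulate_meditation,
    sustained_kernel,
)


class TestSchedule:
    def test_empty(self):
        assert make_schedule(300, 0, 10, seed=0).events == []

    def test_deterministic_under_seed(self):
        a = make_schedule(300, 5, 10, seed=3)
        b = make_schedule(300, 5, 10, seed=3)
        assert [(e.onset, e.duration) for e in a.events] == [
            (e.onset, e.duration) for e in b.events
        ]

    def test_min_gap_respected(self):
        s = make_schedule(300, 5, 10, seed=1)
        for a, b in zip(s.events, s.events[1:]):
            assert b.onset - (a.onset + a.duration) >= 10 - 1e-9

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_schedule(60, 10, 10, seed=0)


class TestKernels:
    def test_scr_kernel_unit_peak_and_causal(self):
        t = np.linspace(-2, 30, 3000)
        k = scr_kernel(t)
        assert np.all(k[t < 0] == 0)
        assert k.max() == pytest.approx(1.0, abs=1e-3)

    def test_sustained_kernel_rises_through_window(self):
        t = np.linspace(0, 30, 3000)
        k = sustained_kernel(t, dur=8.0)
        # monotone rise over most of the on-window, decay afterwards
        assert np.argmax(k) == pytest.approx(np.searchsorted(t, 8.0), abs=30)
        assert k.max() == pytest.approx(1.0, abs=1e-2)


class TestGsr:
    def test_empty_schedule_noiseless_has_no_slope_events(self):
        from stressense.shortterm import gsr_siginc

        gsr = simulate_gsr(StressorSchedule([], 300), ParticipantProfile(), 0,
                           seed=0, noise_sd=0.0)
        assert len(gsr_siginc(gsr)) == 0

    def test_habituation_amplitude_ratio(self):
        # amplitude scales as habituation_rate ** exposure (here 0.7^3)
        profile = dataclasses.replace(ParticipantProfile(), habituation_rate=0.7)
        sched = single_event_schedule(onset=100, duration=6, intensity=1.0)

        def amp(exposure):
            g = simulate_gsr(sched, profile, exposure, seed=5, noise_sd=0.0)
            tonic = gsr_scl(g).values
            return np.max(g.values - tonic)

        assert amp(3) / amp(0) == pytest.approx(0.7 ** 3, rel=0.05)

    def test_phasic_peak_follows_gsr_delay(self):
        # short impulse-like event: peak inside [onset+delay, onset+delay+4]
        sched = single_event_schedule(onset=100, duration=1.0)
        g = simulate_gsr(sched, ParticipantProfile(), 0, seed=1, noise_sd=0.0)
        t_peak = g.timestamps[np.argmax(g.values - gsr_scl(g).values)]
        assert 102.0 <= t_peak <= 106.0


class TestIbi:
    def test_constant_rr_without_modulation(self):
        p = dataclasses.replace(ParticipantProfile(), lf_amp=0.0, hf_amp=0.0)
        ibi = simulate_ibi(StressorSchedule([], 120), p, seed=0, jitter_sd=0.0)
        assert np.allclose(ibi.values, p.ibi_baseline)

    def test_nonphysiological_parameters_rejected(self):
        p = dataclasses.replace(ParticipantProfile(), ibi_baseline=0.5, ibi_drop=0.3)
        with pytest.raises(ValueError, match="non-physiological"):
            simulate_ibi(single_event_schedule(), p, seed=0)

    def test_baseline_range_enforced(self):
        p = dataclasses.replace(ParticipantProfile(), ibi_baseline=2.0)
        with pytest.raises(ValueError, match="ibi_baseline"):
            simulate_ibi(StressorSchedule([], 60), p, seed=0)


class TestBlinks:
    def test_zero_rate_gives_silence(self):
        p = dataclasses.replace(ParticipantProfile(), blink_base_rate=0.0)
        b = simulate_blinks(StressorSchedule([], 300), p, seed=0)
        assert np.all(b.values == 0)

    def test_count_matches_poisson_expectation(self):
        p = dataclasses.replace(ParticipantProfile(), blink_base_rate=0.2)
        counts = [
            len(detect_blink_events(simulate_blinks(StressorSchedule([], 600), p, seed=s)))
            for s in range(5)
        ]
        # 600 s at 0.2 Hz: ~120 expected, allow 4 sigma on the mean of 5 runs
        assert abs(np.mean(counts) - 120) < 4 * np.sqrt(120 / 5) + 3

    def test_strength_range_clamped(self, schedule, profile):
        b = simulate_blinks(schedule, profile, seed=2)
        assert b.values.min() >= 0 and b.values.max() <= 255


class TestLeverJoystickMeditation:
    def test_empty_schedule_zero_lever(self, profile):
        lev = simulate_lever(StressorSchedule([], 120), profile, seed=0)
        assert np.allclose(lev.values, 0)

    def test_lever_plateau_amplitude(self, profile):
        sched = single_event_schedule(onset=50, duration=10, intensity=0.8)
        lev = simulate_lever(sched, profile, seed=0)
        mid = (lev.timestamps > 52) & (lev.timestamps < 58)
        assert np.allclose(lev.values[mid], -0.8, atol=1e-9)

    def test_lever_onsets_match_schedule(self, schedule, profile):
        lev = simulate_lever(schedule, profile, seed=0)
        active = np.abs(lev.values) > 0.05
        rising = np.flatnonzero(active[1:] & ~active[:-1]) + 1
        onsets = lev.timestamps[rising]
        for e in schedule.events:
            assert np.min(np.abs(onsets - e.onset)) <= 0.5

    def test_joystick_jitter_is_event_locked(self, schedule, profile):
        from stressense.behavior import joystick_r2

        joy = simulate_joystick(schedule, profile, seed=3)
        r2 = joystick_r2(joy)
        state = schedule.state(r2.timestamps)
        assert r2.values[state == 0].mean() > 0.9
        assert r2.values[state > 0].mean() < r2.values[state == 0].mean() - 0.2

    def test_meditation_inverse_arousal_range(self, schedule, profile):
        med = simulate_meditation(schedule, profile, seed=0)
        assert med.values.min() >= 0 and med.values.max() <= 100
        state = schedule.state(med.timestamps)
        assert med.values[state > 0].mean() < med.values[state == 0].mean()


class TestEeg:
    def test_no_asymmetry_when_gain_zero(self, schedule):
        from stressense.shortterm import alpha_asymmetry

        p = dataclasses.replace(ParticipantProfile(), asymmetry_gain=0.0, beta_gain=0.0)
        eeg = simulate_eeg(schedule, p, seed=4)
        asym = alpha_asymmetry(eeg)
        # mean asymmetry indistinguishable from 0 relative to alpha power scale
        assert abs(np.mean(asym.values)) < 0.05 * p.alpha_amp ** 2

    def test_right_alpha_dominates_during_events(self, schedule, profile):
        from stressense.shortterm import alpha_asymmetry

        eeg = simulate_eeg(schedule, profile, seed=4)
        asym = alpha_asymmetry(eeg)
        state = schedule.state(asym.timestamps)
        assert asym.values[state > 0].mean() > asym.values[state == 0].mean() + 1.0

    def test_band_power_stable_across_seeds(self, schedule, profile):
        from stressense.shortterm import _sliding_band_power

        means = []
        for seed in (0, 1):
            eeg = simulate_eeg(schedule, profile, seed=seed)
            x = eeg["F3"].values
            means.append(_sliding_band_power(x, 256.0, 512, 256, (8, 13)).mean())
        assert means[0] == pytest.approx(means[1], rel=0.15)


class TestCohort:
    def test_same_config_identical_serialization(self, tmp_path):
        cfg = SimConfig(n_participants=1, trials=1, loops=1, seed=9,
                        session_duration=60.0, n_events=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            for s in simulate_cohort(cfg):
                write_session(align_streams(s), d)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_rest_modality_has_no_lever_or_joystick(self):
        cfg = SimConfig(n_participants=1, trials=1, loops=1, seed=1,
                        modality="rest", condition="none",
                        session_duration=60.0, n_events=0)
        s = simulate_cohort(cfg)[0]
        assert "lever" not in s.streams and "joystick_y" not in s.streams
        assert len(s.schedule.events) == 0

    def test_habituation_monotone_in_exposure(self):
        sched = single_event_schedule(onset=60, duration=6, total=150)
        prof = ParticipantProfile()  # habituation_rate 0.8 < 1
        amps = []
        for exposure in range(4):
            g = simulate_gsr(sched, prof, exposure, seed=3, noise_sd=0.0)
            amps.append(np.max(g.values - gsr_scl(g).values))
        assert all(a >= b for a, b in zip(amps, amps[1:]))


class TestDelayRecovery:
    def test_gsr_and_heart_delays_recovered(self):
        from stressense.characterize import midpoint_tachogram

        prof = ParticipantProfile()
        gsr_sess, heart_sess = [], []
        for seed in range(8):
            sched = make_schedule(300, 8, 12, seed=seed)
            evs = [(e.onset, e.duration) for e in sched.events]
            g = simulate_gsr(sched, prof, 0, seed=seed + 100)
            gsr_sess.append((evs, g.timestamps, g.values))
            ibi = simulate_ibi(sched, prof, seed=seed + 200)
            tg, hr = midpoint_tachogram(ibi, t_end=300)
            heart_sess.append((evs, tg, hr))
        assert estimate_response_delay(gsr_sess) == pytest.approx(2.0, abs=0.2)
        assert estimate_response_delay(heart_sess) == pytest.approx(6.5, abs=0.2)

    def test_blink_rate_step_delay_within_information_limit(self):
        # a 0.25 Hz Poisson channel carries ~0.3 s of timing uncertainty
        # even pooled over tens of sessions; assert the honest bound
        prof = ParticipantProfile()
        sess = []
        for seed in range(30):
            sched = make_schedule(300, 8, 12, seed=seed)
            onsets = np.array([e.onset for e in sched.events])
            durs = np.array([e.duration for e in sched.events])
            ev = detect_blink_events(simulate_blinks(sched, prof, seed=seed + 300))
            sess.append((onsets, durs, ev.timestamps))
        assert estimate_rate_step_delay(sess) == pytest.approx(4.65, abs=0.5)
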