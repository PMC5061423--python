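"""Synthetic multimodal biosignal cohorts with known stressor structure.

Every downstream stage of the pipeline (characterization, correlation
mapping, time-frequency analysis, classification) is validated against
sessions generated here, because the generator embeds the exact
stimulus-response structure the analyses assume:

* tonic + phasic electrodermal activity with a difference-of-exponentials
  SCR kernel and a ~2 s device/physiology lag,
* inter-beat intervals carrying LF (0.1 Hz) and HF (0.3 Hz) modulation
  plus an event-locked IBI drop lagging the stressor by ~6.5 s,
* 1/f EEG with 10 Hz alpha whose hemispheric asymmetry is modulated by
  stressor state (right up, left down) and a left-lateralized 18 Hz
  beta bump during stress,
* Poisson blink pulses whose rate rises inside (lagged) event windows,
* a continuous evaluation-lever trace, a smooth-vs-jerky joystick
  trace, and an inverse-arousal "meditation" score,
* multiplicative habituation of autonomic response amplitudes across
  repeated exposures.

Determinism: every stream draws from a ``numpy`` generator seeded by a
``SeedSequence`` keyed on (seed, participant, trial, loop, channel), so
an identical :class:`SimConfig` reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from stressense.streams import EEG_CHANNELS, SensorStream, Session, SessionMeta

LEFT_CHANNELS = ("F3", "FC3", "C3")
RIGHT_CHANNELS = ("F4", "FC4", "C4")

_CHANNEL_IDS = {
    "schedule": 0, "gsr": 1, "ibi": 2, "eeg": 3, "blink": 4,
    "lever": 5, "joystick": 6, "meditation": 7, "profile": 8,
}


@dataclass(frozen=True)
class StressorEvent:
    onset: float
    duration: float
    intensity: float
    valence_sign: int = -1


@dataclass
class StressorSchedule:
    """Non-overlapping, time-limited stressor events within a session."""

    events: list[StressorEvent]
    session_duration: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(self.events, self.events[1:]):
            if a.onset + a.duration > b.onset:
                raise ValueError("stressor events overlap")
        for e in self.events:
            if not 0 <= e.onset < self.session_duration:
                raise ValueError("event onset outside session")
            if not 0 <= e.intensity <= 1:
                raise ValueError("intensity must lie in [0, 1]")

    def state(self, t: np.ndarray, delay: float = 0.0, weight_intensity: bool = False) -> np.ndarray:
        """Indicator (or intensity-weighted) trace of stressor presence
        at times ``t``, with event windows shifted later by ``delay``."""
        out = np.zeros_like(np.asarray(t, dtype=float))
        for e in self.events:
            m = (t >= e.onset + delay) & (t < e.onset + e.duration + delay)
            out[m] = e.intensity if weight_intensity else 1.0
        return out

    @property
    def event_time_fraction(self) -> float:
        return sum(e.duration for e in self.events) / self.session_duration


@dataclass
class ParticipantProfile:
    """Physiological response parameters for one simulated participant.

    Units: SCL/SCR in µS, IBI in seconds, alpha amplitude in µV.  The
    per-channel response delays default to the lags observed between
    the evaluation lever and each autonomic channel: GSR ~2 s, heart
    ~6.5 s, blink ~4.65 s.  ``habituation_rate`` multiplies autonomic
    response amplitudes once per prior exposure.
    """

    scl_baseline: float = 5.0
    scr_gain: float = 1.0
    ibi_baseline: float = 0.85
    ibi_drop: float = 0.12
    lf_amp: float = 0.02
    hf_amp: float = 0.02
    alpha_amp: float = 10.0
    asymmetry_gain: float = 0.5
    alpha_suppression: float = 0.2
    beta_gain: float = 0.3
    blink_base_rate: float = 0.25
    habituation_rate: float = 0.8
    joystick_jitter: float = 0.15
    delays: dict = field(
        default_factory=lambda: {"gsr": 2.0, "heart": 6.5, "blink": 4.65, "lever": 0.0}
    )

    def __post_init__(self) -> None:
        for name in ("scr_gain", "ibi_drop", "alpha_amp", "blink_base_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.habituation_rate <= 1:
            raise ValueError("habituation_rate must lie in (0, 1]")


@dataclass
class SimConfig:
    """Cohort-level simulation settings; ``seed`` fixes all randomness."""

    n_participants: int = 15
    trials: int = 3
    loops: int = 1
    modality: str = "autonomous"
    condition: str = "wide"
    session_duration: float = 300.0
    n_events: int = 8
    min_gap: float = 12.0
    seed: int = 0
    grid_rate: float = 10.0
    eeg_rate: float = 256.0
    blink_rate_hz: float = 128.0
    noise: dict = field(
        default_factory=lambda: {"gsr": 0.005, "eeg": 25.0, "joystick": 0.01}
    )
    vary_profiles: bool = True


def _rng(config_seed: int, participant: int, trial: int, loop: int, channel: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config_seed,
        spawn_key=(participant, trial, loop, _CHANNEL_IDS[channel]),
    )
    return np.random.default_rng(ss)


def scr_kernel(t: np.ndarray, tau_rise: float = 0.75, tau_decay: float = 4.0) -> np.ndarray:
    """Difference-of-exponentials skin-conductance-response shape,
    normalized to unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def _box_exp(t: np.ndarray, dur: float, tau: float) -> np.ndarray:
    """∫_0^min(t,dur) exp(-(t-u)/τ) du, vectorized, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    rising = tau * (1.0 - np.exp(-np.clip(t, 0, None) / tau))
    decayed = tau * (np.exp(-np.clip(t - dur, 0, None) / tau) - np.exp(-np.clip(t, 0, None) / tau))
    out = np.where(t < dur, rising, decayed)
    return np.where(t >= 0, out, 0.0)


def sustained_kernel(t: np.ndarray, dur: float, tau_rise: float = 0.75,
                     tau_decay: float = 4.0) -> np.ndarray:
    """SCR kernel convolved with the stressor's on-window, unit peak.

    A sustained stressor sustains its autonomic response: the response
    rises over the event window and decays after it, so the period of
    increasing signal tracks the stressor duration rather than the
    kernel's fixed rise time.  For ``dur -> 0`` this converges to
    :func:`scr_kernel`.
    """
    t = np.asarray(t, dtype=float)
    raw = _box_exp(t, dur, tau_decay) - _box_exp(t, dur, tau_rise)
    # unit peak: the maximum lies at the window end (monotone rise)
    probe = np.linspace(0, dur + 3 * tau_rise, 64)
    peak = float(np.max(_box_exp(probe, dur, tau_decay) - _box_exp(probe, dur, tau_rise)))
    return raw / peak if peak > 0 else raw


# ---------------------------------------------------------------------------
# schedule


def make_schedule(
    duration: float,
    n_events: int,
    min_gap: float,
    seed: int | np.random.Generator,
    event_duration: tuple[float, float] = (5.0, 10.0),
    intensity: tuple[float, float] = (0.5, 1.0),
) -> StressorSchedule:
    """Scatter ``n_events`` non-overlapping events uniformly over the session.

    Onsets are drawn by placing the events' total occupied time plus
    gaps into the free time uniformly (stick-breaking), which is exact
    and never rejects, so feasible packings always succeed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_events == 0:
        return StressorSchedule([], duration)
    durs = rng.uniform(*event_duration, size=n_events)
    occupied = float(np.sum(durs)) + min_gap * (n_events - 1)
    # keep a guard band at the end so delayed responses stay in-session
    tail = min(15.0, 0.05 * duration)
    free = duration - tail - occupied
    if free < 0:
        raise ValueError(
            f"infeasible packing: {n_events} events x (duration+gap) exceed {duration} s"
        )
    cuts = np.sort(rng.uniform(0, free, size=n_events))
    onsets = np.empty(n_events)
    acc = 0.0
    for i in range(n_events):
        onsets[i] = cuts[i] + acc
        acc += durs[i] + min_gap
    events = [
        StressorEvent(float(o), float(d), float(rng.uniform(*intensity)))
        for o, d in zip(onsets, durs)
    ]
    return StressorSchedule(events, duration)


# ---------------------------------------------------------------------------
# channel simulators


def simulate_gsr(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    exposure_index: int = 0,
    seed: int | np.random.Generator = 0,
    grid_rate: float = 10.0,
    noise_sd: float = 0.005,
) -> SensorStream:
    """Tonic + phasic skin conductance at the grid rate.

    Each stressor event adds one SCR (kernel of :func:`scr_kernel`)
    delayed by the GSR lag, with amplitude
    ``scr_gain * intensity * habituation_rate ** exposure_index``.
    """
    if grid_rate < 4:
        raise ValueError("grid_rate must be >= 4 Hz for SCR shapes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(round(schedule.session_duration * grid_rate))) / grid_rate
    # slow tonic drift: a few very slow sinusoids with random phase, ~0.1 uS
    # scale; smooth with bounded slope, so it never mimics a phasic rise
    drift = np.zeros_like(t)
    for period, amp in ((307.0, 0.05), (173.0, 0.03), (59.0, 0.02)):
        drift += amp * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    x = profile.scl_baseline + drift
    hab = profile.habituation_rate ** exposure_index
    for e in schedule.events:
        amp = profile.scr_gain * e.intensity * hab
        x = x + amp * sustained_kernel(t - e.onset - profile.delays["gsr"], e.duration)
    x = x + rng.normal(0, noise_sd, t.size)
    return SensorStream("gsr", t, x, nominal_rate=grid_rate, units="uS")


def simulate_ibi(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    exposure_index: int = 0,
    jitter_sd: float = 0.005,
) -> SensorStream:
    """Inter-beat intervals by integrate-and-fire on the instantaneous
    IBI trace; stressors shorten IBI after the ~6.5 s cardiac lag."""
    if not 0.5 <= profile.ibi_baseline <= 1.5:
        raise ValueError("ibi_baseline must lie in [0.5, 1.5] s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hab = profile.habituation_rate ** exposure_index

    # precompute unit-peak normalization per event for the sustained drop
    peaks = []
    for e in schedule.events:
        probe = np.linspace(0, e.duration + 3 * 0.75, 64)
        peaks.append(float(np.max(_box_exp(probe, e.duration, 4.0)
                                  - _box_exp(probe, e.duration, 0.75))))

    def ibi_inst(tt: float) -> float:
        v = profile.ibi_baseline * (
            1.0
            + profile.lf_amp * np.sin(2 * np.pi * 0.1 * tt)
            + profile.hf_amp * np.sin(2 * np.pi * 0.3 * tt)
        )
        for e, pk in zip(schedule.events, peaks):
            dt = tt - e.onset - profile.delays["heart"]
            if dt >= 0 and pk > 0:
                raw = (_box_exp(np.array([dt]), e.duration, 4.0)
                       - _box_exp(np.array([dt]), e.duration, 0.75))[0]
                v -= profile.ibi_drop * e.intensity * hab * raw / pk
        return v

    lo = profile.ibi_baseline * (1 - profile.lf_amp - profile.hf_amp) - profile.ibi_drop
    if lo <= 0.3:
        raise ValueError("parameters drive IBI below 0.3 s (non-physiological)")

    # each RR reflects the instantaneous IBI at the interval midpoint
    # (one fixed-point pass) and is stamped at the beat that ends it,
    # when it becomes observable
    beats, rrs = [], []
    t = ibi_inst(0.0)
    while True:
        rr = ibi_inst(t + ibi_inst(t) / 2)
        if jitter_sd > 0:
            rr += rng.normal(0, jitter_sd)
        if t + rr >= schedule.session_duration:
            break
        beats.append(t + rr)
        rrs.append(rr)
        t += rr
    return SensorStream("ibi_event", np.array(beats), np.array(rrs), nominal_rate=0.0, units="s")


def _one_over_f(n: int, rate: float, rng: np.random.Generator, rms: float) -> np.ndarray:
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return rms * x / (np.std(x) + 1e-12)


def simulate_eeg(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    rate: float = 256.0,
    noise_rms: float = 25.0,
    exposure_index: int = 0,
) -> dict[str, SensorStream]:
    """Six-channel EEG: 1/f background + asymmetric stressor-modulated alpha.

    Alpha (10 Hz) amplitude per channel is
    ``alpha_amp * (1 ± asymmetry_gain * state(t) / 2)`` with ``+`` on
    right-hemisphere channels and ``-`` on left; left channels also gain
    an 18 Hz beta bump during stressor state.  The central response has
    no lag (unlike the autonomic channels), but its stressor modulation
    habituates with exposure like the autonomic responses do.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(schedule.session_duration * rate))
    t = np.arange(n) / rate
    state = schedule.state(t)
    hab = profile.habituation_rate ** exposure_index
    out: dict[str, SensorStream] = {}
    for ch in EEG_CHANNELS:
        sign = +1.0 if ch in RIGHT_CHANNELS else -1.0
        # bilateral alpha blocking under stress plus the hemispheric shift;
        # hemisphere differences cancel the common suppression, so
        # all-channel features carry strictly more stressor information
        amp = profile.alpha_amp * (1.0 - profile.alpha_suppression * hab * state) * (
            1.0 + sign * profile.asymmetry_gain * hab * state / 2.0
        )
        phase = rng.uniform(0, 2 * np.pi)
        x = _one_over_f(n, rate, rng, noise_rms)
        x = x + amp * np.sin(2 * np.pi * 10.0 * t + phase)
        if ch in LEFT_CHANNELS and profile.beta_gain > 0:
            x = x + profile.beta_gain * hab * profile.alpha_amp * state * np.sin(
                2 * np.pi * 18.0 * t + rng.uniform(0, 2 * np.pi)
            )
        out[ch] = SensorStream(ch, t, x, nominal_rate=rate, units="uV")
    return out


def simulate_blinks(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    rate: float = 128.0,
) -> SensorStream:
    """128 Hz blink-strength trace: Poisson blink pulses in [0, 255].

    The blink rate is ``blink_base_rate * (1 + intensity)`` inside
    event windows shifted by the blink lag.  Each blink is a short
    raised-cosine pulse whose peak strength is drawn in [100, 255].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(schedule.session_duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    if profile.blink_base_rate > 0:
        lam = profile.blink_base_rate * (
            1.0 + schedule.state(t, delay=profile.delays["blink"], weight_intensity=True)
        )
        fires = rng.random(n) < lam / rate
        pulse_len = int(0.15 * rate)
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(pulse_len) / pulse_len))
        idx = np.flatnonzero(fires)
        # refractory 0.25 s between blink onsets
        keep, last = [], -np.inf
        for i in idx:
            if t[i] - last >= 0.25:
                keep.append(i)
                last = t[i]
        for i in keep:
            strength = rng.uniform(100, 255)
            end = min(n, i + pulse_len)
            x[i:end] = np.maximum(x[i:end], strength * pulse[: end - i])
    x = np.clip(x, 0, 255)
    return SensorStream("blink_strength", t, x, nominal_rate=rate, units="a.u.")


def simulate_lever(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    grid_rate: float = 10.0,
) -> SensorStream:
    """Continuous self-report lever: ``intensity * valence_sign`` inside
    event windows, rise/fall smoothed over 0.5 s, zero elsewhere."""
    n = int(round(schedule.session_duration * grid_rate))
    t = np.arange(n) / grid_rate
    x = np.zeros(n)
    for e in schedule.events:
        m = (t >= e.onset) & (t < e.onset + e.duration)
        x[m] = e.intensity * e.valence_sign
    win = max(1, int(0.5 * grid_rate))
    x = np.convolve(x, np.ones(win) / win, mode="same")
    return SensorStream("lever", t, x, nominal_rate=grid_rate, units="a.u.")


def simulate_joystick(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    grid_rate: float = 10.0,
    base_noise: float = 0.01,
) -> SensorStream:
    """Joystick y-position: smooth slow steering plus high-frequency
    jitter whose SD grows with stressor state (jerky under stress)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(schedule.session_duration * grid_rate))
    t = np.arange(n) / grid_rate
    base = np.zeros(n)
    for f, a in ((0.05, 0.4), (0.11, 0.25), (0.19, 0.15)):
        base += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    sd = base_noise + profile.joystick_jitter * schedule.state(t)
    x = base + rng.normal(0, 1, n) * sd
    return SensorStream("joystick_y", t, x, nominal_rate=grid_rate, units="a.u.")


def simulate_meditation(
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    rate: float = 1.0,
    smooth_s: float = 4.0,
    noise_sd: float = 2.0,
) -> SensorStream:
    """Relaxation score in [0, 100] emulated as inverse smoothed arousal.

    The smoothing span mimics the sluggish update of a consumer
    relaxation score while keeping each stressor window visible (a span
    longer than an event would smear it below half depth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(schedule.session_duration * rate))
    t = np.arange(n) / rate
    state = schedule.state(t, weight_intensity=True)
    win = max(1, int(smooth_s * rate))
    smooth = np.convolve(state, np.ones(win) / win, mode="same")
    x = 100.0 * (1.0 - smooth) + rng.normal(0, noise_sd, n)
    return SensorStream("meditation", t, np.clip(x, 0, 100), nominal_rate=rate, units="score")


# ---------------------------------------------------------------------------
# sessions and cohorts


def draw_profile(rng: np.random.Generator, vary: bool = True) -> ParticipantProfile:
    """Participant profile with mild between-subject variation around defaults."""
    p = ParticipantProfile()
    if not vary:
        return p
    return replace(
        p,
        scl_baseline=float(rng.uniform(3.0, 8.0)),
        scr_gain=float(p.scr_gain * rng.uniform(0.8, 1.2)),
        ibi_baseline=float(rng.uniform(0.7, 1.0)),
        alpha_amp=float(p.alpha_amp * rng.uniform(0.8, 1.2)),
        blink_base_rate=float(p.blink_base_rate * rng.uniform(0.7, 1.3)),
    )


def simulate_session(
    meta: SessionMeta,
    schedule: StressorSchedule,
    profile: ParticipantProfile,
    config: SimConfig,
    exposure_index: int = 0,
) -> Session:
    """Generate all channels for one session from one schedule.

    ``rest`` sessions get an empty schedule upstream and carry neither
    lever nor joystick; ``autonomous`` carries the lever, ``self_drive``
    the joystick.
    """
    pid = zlib.crc32(meta.participant_id.encode()) % 1_000_000
    key = (config.seed, pid, meta.trial, meta.loop)
    streams: dict[str, SensorStream] = {}
    streams["gsr"] = simulate_gsr(
        schedule, profile, exposure_index, _rng(*key, "gsr"),
        grid_rate=config.grid_rate, noise_sd=config.noise.get("gsr", 0.01),
    )
    streams["ibi_event"] = simulate_ibi(
        schedule, profile, _rng(*key, "ibi"), exposure_index
    )
    streams.update(
        simulate_eeg(schedule, profile, _rng(*key, "eeg"), rate=config.eeg_rate,
                     noise_rms=config.noise.get("eeg", 25.0),
                     exposure_index=exposure_index)
    )
    streams["blink_strength"] = simulate_blinks(
        schedule, profile, _rng(*key, "blink"), rate=config.blink_rate_hz
    )
    streams["meditation"] = simulate_meditation(schedule, profile, _rng(*key, "meditation"))
    if meta.modality == "autonomous":
        streams["lever"] = simulate_lever(schedule, profile, _rng(*key, "lever"),
                                          grid_rate=config.grid_rate)
    elif meta.modality == "self_drive":
        streams["joystick_y"] = simulate_joystick(
            schedule, profile, _rng(*key, "joystick"), grid_rate=config.grid_rate,
            base_noise=config.noise.get("joystick", 0.01),
        )
    return Session(meta, streams, grid_rate=config.grid_rate)


def simulate_cohort(config: SimConfig) -> list[Session]:
    """Generate the full cohort: participants x trials x loops sessions.

    The exposure index increments over (trial, loop) so autonomic
    response amplitudes habituate across repeated sessions.
    """
    sessions: list[Session] = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        prof_rng = _rng(config.seed, p + 1, 0, 0, "profile")
        profile = draw_profile(prof_rng, vary=config.vary_profiles)
        for trial in range(1, config.trials + 1):
            for loop in range(1, config.loops + 1):
                exposure = (trial - 1) * config.loops + (loop - 1)
                meta = SessionMeta(
                    participant_id=pid, modality=config.modality,
                    condition=config.condition, trial=trial, loop=loop,
                )
                if config.modality == "rest":
                    schedule = StressorSchedule([], config.session_duration)
                else:
                    schedule = make_schedule(
                        config.session_duration, config.n_events, config.min_gap,
                        _rng(config.seed, p + 1, trial, loop, "schedule"),
                    )
                session = simulate_session(meta, schedule, profile, config, exposure)
                session.schedule = schedule  # ground truth rides along
                session.profile = profile
                sessions.append(session)
    return sessions
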