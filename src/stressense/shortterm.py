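"""Short-term characterizations: moment-to-moment emotional changes.

The centerpiece is the square-wave encoder: runs of significant slope
increase in a smoothed signal become rectangular events whose width is
the run duration and whose height is the peak signal amplitude inside
the run.  Applied to skin conductance (``GSRsiginc``) and to a smoothed
blink-rate proxy (``Blinksiginc``).  The module also provides the
sliding reciprocal-median RR series (``medianRRI``) and frontal alpha
asymmetry (``alphaAsym``, right minus left hemisphere alpha power).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stressense.series import ParameterSeries

logger = logging.getLogger(__name__)

LEFT_CHANNELS = ("F3", "FC3", "C3")
RIGHT_CHANNELS = ("F4", "FC4", "C4")


@dataclass
class SlopeDetectorConfig:
    """Knobs of the significant-slope-increase detector.

    ``slope_threshold_k`` is in multiples of the robust SD
    (1.4826 x MAD) of the smoothed signal's first-difference slope;
    candidate runs closer than ``merge_gap_s`` are merged and runs
    shorter than ``min_event_s`` are discarded.
    """

    smooth_window_s: float = 1.0
    slope_threshold_k: float = 3.0
    min_event_s: float = 0.5
    merge_gap_s: float = 0.3

    def __post_init__(self) -> None:
        if self.smooth_window_s <= 0 or self.slope_threshold_k <= 0:
            raise ValueError("smooth_window_s and slope_threshold_k must be positive")


@dataclass
class SquareWaveEvent:
    onset: float
    width: float
    height: float


@dataclass
class SquareWaveSeries:
    """Detected slope-increase events plus their grid encoding."""

    events: list[SquareWaveEvent]
    timestamps: np.ndarray
    name: str = "siginc"

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if a.onset + a.width > b.onset:
                raise ValueError("square-wave events overlap")

    def __len__(self) -> int:
        return len(self.events)

    def grid_encoding(self) -> ParameterSeries:
        """Height inside each event's interval, zero elsewhere."""
        out = np.zeros_like(self.timestamps, dtype=float)
        for e in self.events:
            m = (self.timestamps >= e.onset) & (self.timestamps < e.onset + e.width)
            out[m] = e.height
        return ParameterSeries(self.name, self.timestamps, out)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])


def smooth_running_mean(timestamps: np.ndarray, values: np.ndarray, window_s: float,
                        rate: float | None = None) -> np.ndarray:
    """Centered running mean; edges use shrinking windows."""
    timestamps = np.asarray(timestamps, dtype=float)
    rate = rate or 1.0 / np.median(np.diff(timestamps))
    n = int(round(window_s * rate))
    if n < 2:
        raise ValueError("smoothing window must span >= 2 samples")
    if n % 2 == 0:
        n += 1
    return pd.Series(values).rolling(n, center=True, min_periods=1).mean().to_numpy()


def detect_sig_slope_increases(
    timestamps: np.ndarray,
    smoothed: np.ndarray,
    cfg: SlopeDetectorConfig | None = None,
    name: str = "siginc",
) -> SquareWaveSeries:
    """Encode runs of significantly increasing slope as square waves.

    The slope is the first difference of the smoothed signal divided by
    the sample step; samples whose slope exceeds
    ``k * 1.4826 * MAD(slope)`` are merged into maximal runs (gaps below
    ``merge_gap_s`` bridged); runs of at least ``min_event_s`` become
    events with width = run duration and height = max signal value in
    the run.  Samples outside events encode zero.
    """
    cfg = cfg or SlopeDetectorConfig()
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(smoothed, dtype=float)
    dt = float(np.median(np.diff(t)))
    slope = np.diff(x) / dt
    finite = np.isfinite(slope)
    if not finite.any():
        return SquareWaveSeries([], t, name)
    mad = np.median(np.abs(slope[finite] - np.median(slope[finite])))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        # sparse pulse trains (e.g. blink strength) are mostly flat, so the
        # MAD collapses; fall back to the plain SD of the slope
        robust_sd = float(np.std(slope[finite]))
    if robust_sd == 0:
        logger.warning("slope scale is zero (flat signal); no events detected")
        return SquareWaveSeries([], t, name)
    thresh = cfg.slope_threshold_k * robust_sd
    hot = np.zeros(t.size, dtype=bool)
    hot[1:] = finite & (slope > thresh)

    # maximal runs of hot samples
    idx = np.flatnonzero(hot)
    if idx.size == 0:
        return SquareWaveSeries([], t, name)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))

    # bridge short gaps
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if t[s] - t[merged[-1][1]] < cfg.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        onset = t[max(s - 1, 0)]  # slope[i] spans (i-1, i]
        width = t[e] - onset
        if width + dt / 2 < cfg.min_event_s:
            continue
        height = float(np.nanmax(x[max(s - 1, 0): e + 1]))
        events.append(SquareWaveEvent(float(onset), float(width), height))
    return SquareWaveSeries(events, t, name)


def gsr_siginc(gsr, cfg: SlopeDetectorConfig | None = None) -> SquareWaveSeries:
    """Square-wave encoding of significant slope increases in skin
    conductance (1 s running-mean smoothing by default)."""
    cfg = cfg or SlopeDetectorConfig(smooth_window_s=1.0)
    sm = smooth_running_mean(gsr.timestamps, gsr.values, cfg.smooth_window_s,
                             rate=gsr.nominal_rate or None)
    return detect_sig_slope_increases(gsr.timestamps, sm, cfg, name="GSRsiginc")


def blink_siginc(blink_strength, cfg: SlopeDetectorConfig | None = None) -> SquareWaveSeries:
    """Square-wave encoding of blink-rate surges.

    The blink-rate proxy is the 0.1 s running mean of the 0-255 blink
    strength trace; slope events are then encoded exactly as for GSR.
    """
    cfg = cfg or SlopeDetectorConfig(smooth_window_s=0.1, min_event_s=0.05)
    rate = blink_strength.nominal_rate or 1.0 / np.median(np.diff(blink_strength.timestamps))
    if cfg.smooth_window_s * rate >= 2:
        sm = smooth_running_mean(blink_strength.timestamps, blink_strength.values,
                                 cfg.smooth_window_s, rate=rate)
    else:  # already coarser than the smoothing span (e.g. 10 Hz binned form)
        sm = np.asarray(blink_strength.values, dtype=float)
    return detect_sig_slope_increases(blink_strength.timestamps, sm, cfg, name="Blinksiginc")


def median_rri(ibi, window_s: float = 5.0, step_s: float = 0.1,
               t_end: float | None = None) -> ParameterSeries:
    """Reciprocal of the windowed median RR interval (1/s).

    A centered sliding window of ``window_s`` steps along the grid; the
    reciprocal standardizes the sign convention so that higher values
    mean more arousal (faster heart).  Empty windows are
    missing-flagged.
    """
    beats, rr = ibi.timestamps, ibi.values
    if beats.size == 0:
        raise ValueError("median_rri: empty IBI series")
    t_end = t_end if t_end is not None else beats[-1]
    grid = np.arange(0.0, t_end, step_s)
    half = window_s / 2
    left = np.searchsorted(beats, grid - half, side="left")
    right = np.searchsorted(beats, grid + half, side="left")
    out = np.full(grid.size, np.nan)
    for i, (l, r) in enumerate(zip(left, right)):
        if r > l:
            out[i] = 1.0 / np.median(rr[l:r])
    return ParameterSeries("medianRRI", grid, out)


def _sliding_band_power(x: np.ndarray, rate: float, win: int, step: int,
                        band: tuple[float, float]) -> np.ndarray:
    """Rectangular-window periodogram band power per sliding window."""
    n_win = (x.size - win) // step + 1
    starts = np.arange(n_win) * step
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n_win, win), strides=(x.strides[0] * step, x.strides[0])
    )
    spec = np.fft.rfft(windows, axis=1)
    f = np.fft.rfftfreq(win, d=1.0 / rate)
    psd = (np.abs(spec) ** 2) * (2.0 / (rate * win))
    m = (f >= band[0]) & (f <= band[1])
    df = rate / win
    return psd[:, m].sum(axis=1) * df


def alpha_asymmetry(eeg: dict, window_s: float = 2.0, step_s: float = 0.1,
                    band: tuple[float, float] = (8.0, 13.0)) -> ParameterSeries:
    """Right-minus-left hemispheric alpha power on a sliding window.

    Per window, each hemisphere's power is the mean over its three
    channels of the periodogram power integrated over ``band``; the
    value is right minus left, so positive values indicate relatively
    greater right-hemisphere alpha.
    """
    for ch in LEFT_CHANNELS + RIGHT_CHANNELS:
        if ch not in eeg:
            raise ValueError(f"alpha_asymmetry: missing EEG channel '{ch}'")
    any_ch = eeg[LEFT_CHANNELS[0]]
    rate = any_ch.nominal_rate or 1.0 / np.median(np.diff(any_ch.timestamps))
    win = int(round(window_s * rate))
    step = max(1, int(round(step_s * rate)))
    powers = {}
    for ch in LEFT_CHANNELS + RIGHT_CHANNELS:
        x = np.nan_to_num(eeg[ch].values, nan=0.0)
        powers[ch] = _sliding_band_power(x, rate, win, step, band)
    left = np.mean([powers[c] for c in LEFT_CHANNELS], axis=0)
    right = np.mean([powers[c] for c in RIGHT_CHANNELS], axis=0)
    n_win = left.size
    centers = any_ch.timestamps[0] + (np.arange(n_win) * step + win / 2) / rate
    return ParameterSeries("alphaAsym", centers, right - left)
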