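"""Long-term characterizations: slow emotional-state trends.

Four series, one per sensor family:

* ``Blinkcount`` — blink events counted in 2 s bins,
* ``GSRSCL`` — tonic skin-conductance level (running median),
* ``LFHF`` — Welch-based LF/HF spectral power ratio of the IBI series
  per 20 s window (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz),
* ``Meditation`` — the relaxation score passed through onto the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from stressense.series import ParameterSeries
from stressense.streams import SensorStream, resample_to_grid

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class WelchConfig:
    """Spectral settings for the LF/HF ratio.

    The IBI event series is linearly resampled to ``resample_rate``
    (uniform sampling is required for Welch), detrended, Hamming
    tapered, and split into half-window segments at ``overlap``
    fractional overlap inside each 20 s analysis window.
    """

    window_s: float = 20.0
    overlap: float = 0.5
    resample_rate: float = 4.0
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND

    def __post_init__(self) -> None:
        nyq = self.resample_rate / 2
        for lo, hi in (self.lf_band, self.hf_band):
            if not 0 < lo < hi <= nyq:
                raise ValueError("bands must lie within (0, resample_rate/2]")


def detect_blink_events(blink_strength: SensorStream, threshold: float = 50.0,
                        refractory_s: float = 0.2) -> SensorStream:
    """Blink event times from the 0-255 strength trace.

    An event is an upward crossing of ``threshold`` separated from the
    previous event by at least ``refractory_s``.  The Mindwave's own
    event criterion is proprietary; this thresholding recovers the
    pulse onsets the simulator (and any pulse-like trace) produces.
    """
    x = blink_strength.values
    t = blink_strength.timestamps
    above = x >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times, last = [], -np.inf
    for i in crossings:
        if t[i] - last >= refractory_s:
            times.append(t[i])
            last = t[i]
    times = np.asarray(times)
    return SensorStream("blink_event", times, np.ones(times.size), nominal_rate=0.0)


def blink_count(blink_events: SensorStream, bin_s: float = 2.0) -> ParameterSeries:
    """Count of blink events per half-open ``bin_s`` bin."""
    t = blink_events.timestamps
    end = t[-1] if t.size else 0.0
    n_bins = int(np.floor(end / bin_s)) + 1 if t.size else 0
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(t, bins=edges) if n_bins else (np.array([]), None)
    centers = edges[:-1] + bin_s / 2 if n_bins else np.array([])
    return ParameterSeries("Blinkcount", centers, counts.astype(float))


def gsr_scl(gsr: SensorStream, window_s: float = 30.0) -> ParameterSeries:
    """Tonic skin-conductance level: running median over ``window_s``.

    The median rejects the brief phasic responses riding on the tonic
    level, so the output tracks the slow baseline.
    """
    if not np.isfinite(gsr.values).any():
        raise ValueError("gsr_scl: all samples missing")
    rate = gsr.nominal_rate or 1.0 / np.median(np.diff(gsr.timestamps))
    n = max(1, int(round(window_s * rate)))
    med = (
        pd.Series(gsr.values)
        .rolling(n, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return ParameterSeries("GSRSCL", gsr.timestamps, med)


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    # trapezoid over the exact band, PSD interpolated at the band edges;
    # the shared 0.15 Hz boundary then contributes half-weight to each band
    lo, hi = band
    interior = f[(f > lo) & (f < hi)]
    fi = np.concatenate(([lo], interior, [hi]))
    pi = np.interp(fi, f, psd)
    return float(np.trapezoid(pi, fi))


def welch_psd(x: np.ndarray, fs: float, overlap: float = 0.5,
              nperseg: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-tapered Welch PSD.

    The segment defaults to the full analysis window: a 20 s window is
    already at the resolution floor of the 0.04-0.15 Hz band (a shorter
    segment's mainlobe leaks LF power into HF), so splitting it would
    destroy the LF/HF contrast.  Longer inputs are averaged over
    ``nperseg``-sample segments at ``overlap`` fractional overlap.
    """
    nperseg = min(len(x), nperseg or len(x))
    noverlap = int(nperseg * overlap) if nperseg < len(x) else 0
    return signal.welch(x, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
                        detrend="constant")


def lfhf(ibi: SensorStream, cfg: WelchConfig | None = None) -> ParameterSeries:
    """LF/HF power ratio of the IBI series, one value per 20 s window.

    Each window's beat-wise RR values are linearly resampled to a
    uniform grid, linearly detrended, and Welch-analysed; the ratio of
    the integrated LF and HF band powers is returned at the window
    center.  Windows with fewer than 2 beats, or with HF power at
    machine tolerance, are missing-flagged.
    """
    cfg = cfg or WelchConfig()
    beats, rr = ibi.timestamps, ibi.values
    if beats.size == 0:
        raise ValueError("lfhf: empty IBI series")
    duration = beats[-1]
    n_win = int(np.floor(duration / cfg.window_s))
    centers, ratios = [], []
    for k in range(n_win):
        w0, w1 = k * cfg.window_s, (k + 1) * cfg.window_s
        m = (beats >= w0) & (beats < w1)
        centers.append(w0 + cfg.window_s / 2)
        if m.sum() < 2:
            logger.warning("lfhf: window [%g, %g) has < 2 beats", w0, w1)
            ratios.append(np.nan)
            continue
        grid = np.arange(w0, w1, 1.0 / cfg.resample_rate)
        x = np.interp(grid, beats[m], rr[m])
        x = signal.detrend(x, type="linear")
        f, psd = welch_psd(x, cfg.resample_rate, cfg.overlap)
        lf = _band_power(f, psd, cfg.lf_band)
        hf = _band_power(f, psd, cfg.hf_band)
        if hf <= np.finfo(float).tiny * 1e6:
            ratios.append(np.nan)
        else:
            ratios.append(lf / hf)
    return ParameterSeries("LFHF", np.asarray(centers), np.asarray(ratios))


def meditation_series(meditation: SensorStream, grid_rate: float = 10.0) -> ParameterSeries:
    """Relaxation score passed through onto the analysis grid (hold
    resampling); out-of-range values are clamped with a warning."""
    if len(meditation) == 0:
        raise ValueError("meditation_series: empty stream")
    values = meditation.values
    if np.nanmin(values) < 0 or np.nanmax(values) > 100:
        logger.warning("meditation values outside [0, 100]; clamping")
        values = np.clip(values, 0, 100)
    stream = SensorStream(meditation.name, meditation.timestamps, values,
                          nominal_rate=meditation.nominal_rate)
    out = resample_to_grid(stream, grid_rate, method="hold")
    return ParameterSeries("Meditation", out.timestamps, out.values)
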