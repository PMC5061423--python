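"""EEG time-frequency analysis and significant-channel counting.

Band-passed (8-25 Hz) EEG is turned into a 0.1 Hz-resolution
spectrogram, condensed into three bands of interest (α1 8-12 Hz,
α2 13-15 Hz, β 16-20 Hz), and each band's power-over-time series is
summarized by its linear slope and variance.  Across a set of
recordings, channel variances are standardized per condition x band
(z-scores over the N datasets) and counted against a z-rule to find
which channels show significant activation — the machinery behind the
counted-frequencies-per-channel table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from stressense.streams import EEG_CHANNELS, SensorStream

logger = logging.getLogger(__name__)

BANDS = {"alpha1": (8.0, 12.0), "alpha2": (13.0, 15.0), "beta": (16.0, 20.0)}
LEFT = ("F3", "FC3", "C3")
RIGHT = ("F4", "FC4", "C4")


@dataclass
class Spectrogram:
    channel: str
    times: np.ndarray   # window centers, s
    freqs: np.ndarray   # Hz, 0.1 Hz spacing over [8, 25]
    power: np.ndarray   # time x freq, uV^2/Hz


@dataclass
class BandSeries:
    channel: str
    band: str
    times: np.ndarray
    power: np.ndarray
    slope: float
    variance: float


def eeg_bandpass(eeg: SensorStream, lo: float = 8.0, hi: float = 25.0,
                 order: int = 4, artifact_uv: float = 100.0) -> SensorStream:
    """Zero-phase Butterworth band-pass with amplitude artifact masking.

    Samples whose raw amplitude exceeds ``artifact_uv`` are NaN-masked
    in the output (the filter runs on the unmasked trace).
    """
    rate = eeg.nominal_rate
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, eeg.values)
    mask = np.abs(eeg.values) > artifact_uv
    if mask.any():
        y = y.copy()
        y[mask] = np.nan
    return SensorStream(eeg.name, eeg.timestamps, y, nominal_rate=rate, units=eeg.units)


def spectrogram_01hz(eeg: SensorStream, window_s: float = 10.0, step_s: float = 1.0,
                     f_lo: float = 8.0, f_hi: float = 25.0,
                     max_masked_frac: float = 0.2) -> Spectrogram:
    """Short-time periodogram matrix at 0.1 Hz frequency spacing.

    Rectangular-window periodograms, zero-padded to 0.1 Hz resolution
    when the window is shorter than 10 s.  Windows with more than
    ``max_masked_frac`` artifact-masked samples are dropped (NaN row);
    surviving masked samples are zero-filled.
    """
    rate = eeg.nominal_rate
    win = int(round(window_s * rate))
    if window_s < 10.0:
        logger.warning("spectrogram window %.1f s gives < 0.1 Hz native resolution; "
                       "zero-padding", window_s)
    step = int(round(step_s * rate))
    nfft = int(round(rate / 0.1))
    x = eeg.values
    n_win = (x.size - win) // step + 1
    freqs_all = np.fft.rfftfreq(nfft, d=1.0 / rate)
    sel = (freqs_all >= f_lo - 1e-9) & (freqs_all <= f_hi + 1e-9)
    freqs = freqs_all[sel]
    power = np.full((n_win, freqs.size), np.nan)
    times = np.empty(n_win)
    for i in range(n_win):
        seg = x[i * step: i * step + win]
        times[i] = eeg.timestamps[i * step] + window_s / 2
        bad = ~np.isfinite(seg)
        if bad.mean() > max_masked_frac:
            continue
        seg = np.where(bad, 0.0, seg)
        spec = np.fft.rfft(seg, n=nfft)
        psd = (np.abs(spec) ** 2) * (2.0 / (rate * win))
        power[i] = psd[sel]
    return Spectrogram(eeg.name, times, freqs, power)


def condense_bands(spec: Spectrogram, bands: dict | None = None) -> dict[str, BandSeries]:
    """Mean power per band per time step, with slope and variance.

    Slope is the least-squares linear coefficient of band power over
    time; variance is the sample variance of the band-power series.
    """
    bands = bands or BANDS
    out: dict[str, BandSeries] = {}
    valid = np.isfinite(spec.power).all(axis=1)
    for name, (lo, hi) in bands.items():
        m = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
        series = spec.power[:, m].mean(axis=1)
        t, s = spec.times[valid], series[valid]
        if t.size >= 2:
            slope = float(np.polyfit(t, s, 1)[0])
            var = float(np.var(s, ddof=1))
        else:
            slope, var = np.nan, np.nan
        out[name] = BandSeries(spec.channel, name, spec.times, series, slope, var)
    return out


def standardized_z(r: np.ndarray) -> np.ndarray:
    """|z| = |(r − mean(r)) / std(r)| with population SD; an all-equal
    vector (zero SD) yields NaN for every entry."""
    r = np.asarray(r, dtype=float)
    sd = r.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return np.full(r.shape, np.nan)
    return np.abs((r - r.mean()) / sd)


def variance_count_table(
    datasets: list[tuple[str, dict[str, dict[str, float]]]],
    z_rule: str = "ge2",
    z_thresh: float = 2.0,
    axis: str = "channels",
) -> pd.DataFrame:
    """Count significantly activated channels per condition and band.

    ``datasets`` is a list of ``(condition, {channel: {band: variance}})``
    records, one per recording.  With ``axis="channels"`` (default) the
    six channel variances of each dataset are standardized together and
    a channel is counted for that dataset when the z-rule holds, so a
    channel with systematically large variance accumulates counts
    across datasets — this is the reading that makes hemispheric
    activation patterns visible, since standardizing each channel
    against its own across-dataset distribution (``axis="datasets"``)
    removes between-channel differences by construction.

    ``z_rule="ge2"`` counts ``|z| >= t`` (outlier-large variances, the
    conventional significance reading); ``z_rule="lt2"`` counts
    ``|z| < t`` (the literal alternative).  Degenerate groups (zero SD)
    contribute no counts, with a warning.
    """
    if z_rule not in ("ge2", "lt2"):
        raise ValueError("z_rule must be 'ge2' or 'lt2'")
    if axis not in ("channels", "datasets"):
        raise ValueError("axis must be 'channels' or 'datasets'")
    conditions = sorted({c for c, _ in datasets})
    rows = []
    for cond in conditions:
        group = [rec for c, rec in datasets if c == cond]
        if len(group) < 3:
            raise ValueError(f"condition {cond!r} has < 3 datasets")
        for band in BANDS:
            mat = np.array([[rec[ch][band] for ch in EEG_CHANNELS] for rec in group])
            z = np.empty_like(mat)
            if axis == "channels":
                for k in range(mat.shape[0]):
                    z[k] = standardized_z(mat[k])
            else:
                for j in range(mat.shape[1]):
                    z[:, j] = standardized_z(mat[:, j])
            if np.isnan(z).any():
                logger.warning("degenerate variance spread in %s/%s", cond, band)
            with np.errstate(invalid="ignore"):
                hit = (z >= z_thresh) if z_rule == "ge2" else (z < z_thresh)
            hit &= np.isfinite(z)
            counts = dict(zip(EEG_CHANNELS, hit.sum(axis=0).astype(int)))
            rows.append({"condition": cond, "band": band, **counts})
    return pd.DataFrame(rows).set_index(["condition", "band"])


def hemisphere_pattern_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Left-vs-right count sums and dominance flag per condition/band."""
    out = []
    for (cond, band), row in table.iterrows():
        left = int(sum(row[c] for c in LEFT))
        right = int(sum(row[c] for c in RIGHT))
        dominance = "left" if left > right else "right" if right > left else "none"
        out.append({"condition": cond, "band": band, "left": left, "right": right,
                    "dominance": dominance})
    return pd.DataFrame(out).set_index(["condition", "band"])
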