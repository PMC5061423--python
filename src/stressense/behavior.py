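"""Behavioral scoring and stressor-interval label construction.

Joystick smoothness is scored by the coefficient of determination R²
between the raw y-position and its (2M+1)-point running mean (M = 5):
smooth driving gives R² near 1, jerky driving under stress pulls it
down.  Labels assign each fixed-length stressor-interval either
1 (presence of a stressor) or 2 (absence), by comparing the interval
mean of a preprocessed characterization against a per-source cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stressense.series import ParameterSeries

#: (source -> allowed stressor-interval durations in seconds)
ALLOWED_INTERVALS = {
    "GSRsiginc": (2, 4),
    "medianRRI": (2, 5),
    "GSRSCL": (2, 5),
    "Meditation": (2, 5),
    "Joystick": (5,),
}

#: Default cutoff rule per label source.
DEFAULT_CUTOFFS = {
    "GSRsiginc": "mean",     # mean of the preprocessed series (~0.3)
    "medianRRI": "median",   # median of the preprocessed series
    "GSRSCL": "mean",        # mean of the preprocessed series (~0.5)
    "Meditation": "fixed:50",
    "Joystick": "mean",      # mean of the R^2 series
}

PRESENT, ABSENT = 1, 2


@dataclass
class JoystickSmoothingParams:
    """One-sided half-length M of the (2M+1)-point running mean."""

    M: int = 5

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class LabelSpec:
    source: str
    interval_s: int
    cutoff_rule: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ALLOWED_INTERVALS:
            raise ValueError(f"unknown label source {self.source!r}")
        if self.interval_s not in ALLOWED_INTERVALS[self.source]:
            raise ValueError(
                f"interval {self.interval_s} s not allowed for {self.source} "
                f"(allowed: {ALLOWED_INTERVALS[self.source]})"
            )
        if self.cutoff_rule is None:
            self.cutoff_rule = DEFAULT_CUTOFFS[self.source]


@dataclass
class LabelSeries:
    """Per-interval stressor labels: 1 = presence, 2 = absence."""

    interval_starts: np.ndarray
    labels: np.ndarray
    interval_s: float
    source: str
    cutoff_used: float

    def __post_init__(self) -> None:
        self.interval_starts = np.asarray(self.interval_starts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (PRESENT, ABSENT)).all():
            raise ValueError("labels must be 1 (presence) or 2 (absence)")

    def __len__(self) -> int:
        return self.labels.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval_start_s": self.interval_starts,
            "label": self.labels,
            "source": self.source,
            "interval_s": self.interval_s,
            "cutoff_used": self.cutoff_used,
        })


def joystick_r2(
    y,
    params: JoystickSmoothingParams | None = None,
    window_s: float = 5.0,
    step_s: float = 0.1,
) -> ParameterSeries:
    """Sliding-window R² between raw and running-mean joystick traces.

    R² = 1 − Σ(x − x̂)² / Σ(x − x̄)² per window, clipped to [0, 1];
    x̂ is the (2M+1)-point running mean and x̄ the window mean of the
    raw trace.  Windows with zero variance are perfectly smooth by
    convention (R² = 1) and are flagged in ``meta['degenerate']``.
    """
    params = params or JoystickSmoothingParams()
    t, x = y.timestamps, np.asarray(y.values, dtype=float)
    k = 2 * params.M + 1
    if x.size < k:
        raise ValueError(f"stream shorter than 2M+1 = {k} samples")
    xhat = pd.Series(x).rolling(k, center=True, min_periods=1).mean().to_numpy()

    rate = y.nominal_rate or 1.0 / np.median(np.diff(t))
    win = max(2, int(round(window_s * rate)))
    step = max(1, int(round(step_s * rate)))
    d2 = (x - xhat) ** 2
    n_win = (x.size - win) // step + 1
    starts = np.arange(n_win) * step
    r2 = np.empty(n_win)
    degen = np.zeros(n_win, dtype=bool)
    csum_d2 = np.concatenate(([0.0], np.cumsum(d2)))
    csum_x = np.concatenate(([0.0], np.cumsum(x)))
    csum_x2 = np.concatenate(([0.0], np.cumsum(x * x)))
    for i, s in enumerate(starts):
        e = s + win
        ss_res = csum_d2[e] - csum_d2[s]
        sx = csum_x[e] - csum_x[s]
        ss_tot = (csum_x2[e] - csum_x2[s]) - sx * sx / win
        if ss_tot <= 1e-12 * win * (1.0 + (sx / win) ** 2):
            r2[i] = 1.0
            degen[i] = True
        else:
            r2[i] = 1.0 - ss_res / ss_tot
    r2 = np.clip(r2, 0.0, 1.0)
    centers = t[0] + (starts + win / 2) / rate
    return ParameterSeries("JoystickR2", centers, r2, meta={"degenerate": degen})


def normalize_series(p: ParameterSeries) -> ParameterSeries:
    """Min-max normalization onto [0, 1] (per participant-session)."""
    v = p.values
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError(f"normalize_series: '{p.name}' has no finite values")
    lo, hi = np.min(v[finite]), np.max(v[finite])
    if hi == lo:
        raise ValueError(f"normalize_series: '{p.name}' is constant")
    return ParameterSeries(p.name, p.timestamps, (v - lo) / (hi - lo), dict(p.meta))


def _cutoff(values: np.ndarray, rule: str) -> float:
    if rule == "mean":
        return float(np.nanmean(values))
    if rule == "median":
        return float(np.nanmedian(values))
    if rule.startswith("fixed:"):
        return float(rule.split(":", 1)[1])
    raise ValueError(f"unknown cutoff rule {rule!r}")


def build_labels(p: ParameterSeries, spec: LabelSpec) -> LabelSeries:
    """Stressor-interval labels from a preprocessed characterization.

    The series is split into equal successive ``interval_s`` intervals
    (trailing partial interval dropped); an interval whose mean exceeds
    the cutoff is labelled 2 (absence of a stressor), otherwise
    1 (presence); ties go to 1.
    """
    t, v = p.timestamps, p.values
    t0 = t[0]
    duration = t[-1] - t0
    n_int = int(np.floor((duration + 1e-9) / spec.interval_s))
    if n_int < 1:
        raise ValueError("series shorter than one stressor-interval")
    cutoff = _cutoff(v, spec.cutoff_rule)
    starts = t0 + np.arange(n_int) * spec.interval_s
    labels = np.empty(n_int, dtype=int)
    for i, s in enumerate(starts):
        m = (t >= s) & (t < s + spec.interval_s)
        mean = np.nanmean(v[m]) if m.any() else np.nan
        labels[i] = ABSENT if mean > cutoff else PRESENT
    return LabelSeries(starts, labels, spec.interval_s, spec.source, cutoff)


def lever_preprocess(lever) -> ParameterSeries:
    """Arousal magnitude of the evaluation lever: absolute value,
    normalized to [0, 1] (an all-zero lever stays zero)."""
    x = np.abs(np.asarray(lever.values, dtype=float))
    peak = np.nanmax(x) if np.isfinite(x).any() else 0.0
    if peak > 0:
        x = x / peak
    return ParameterSeries("lever", lever.timestamps, x)
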