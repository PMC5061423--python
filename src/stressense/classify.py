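"""Stressor-presence classification from EEG alpha-ratio features.

EEG is band-pass filtered 3-50 Hz, detrended, epoched by the
stressor-interval grid of a label series (per-epoch 0-1 s baseline
correction), and reduced to alpha-ratio features: power in 8-13 Hz
divided by power in 4-30 Hz, either per channel (6 features) or as
left-minus-right differences (3 features).  Stratified ten-fold
cross-validation with LDA, linear SVM, or logistic regression yields
per-fold accuracies in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from stressense.behavior import LabelSeries
from stressense.streams import EEG_CHANNELS, SensorStream

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 13.0)
BROAD_BAND = (4.0, 30.0)
LEFT = ("F3", "FC3", "C3")
RIGHT = ("F4", "FC4", "C4")


@dataclass
class EpochSet:
    """Channel x sample EEG segments aligned with stressor-interval labels."""

    data: np.ndarray          # (n_epochs, 6, n_samples)
    labels: np.ndarray        # (n_epochs,), values in {1, 2}
    interval_s: float
    rate: float

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class CVResult:
    method: str
    fold_accuracies: np.ndarray  # percent

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def eeg_preprocess_cls(eeg: dict[str, SensorStream], lo: float = 3.0, hi: float = 50.0,
                       order: int = 5) -> dict[str, SensorStream]:
    """Zero-phase 3-50 Hz band-pass and linear detrend per loop segment."""
    out = {}
    for ch, stream in eeg.items():
        rate = stream.nominal_rate
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
        y = signal.sosfiltfilt(sos, np.nan_to_num(stream.values, nan=0.0))
        y = signal.detrend(y, type="linear")
        out[ch] = SensorStream(ch, stream.timestamps, y, nominal_rate=rate,
                               units=stream.units)
    return out


def epoch_by_labels(eeg: dict[str, SensorStream], labels: LabelSeries,
                    baseline_s: float = 1.0, max_masked_frac: float = 0.2) -> EpochSet:
    """One epoch per stressor-interval, baseline-corrected over 0-1 s.

    Epoch boundaries sit at exact multiples of the interval length from
    the segment start; epochs with more than ``max_masked_frac``
    non-finite samples are dropped together with their labels.
    """
    missing = [ch for ch in EEG_CHANNELS if ch not in eeg]
    if missing:
        raise ValueError(f"epoch_by_labels: missing EEG channels {missing}")
    rate = eeg[EEG_CHANNELS[0]].nominal_rate
    n_samp = int(round(labels.interval_s * rate))
    t0 = eeg[EEG_CHANNELS[0]].timestamps[0]
    epochs, kept = [], []
    for i, start in enumerate(labels.interval_starts):
        i0 = int(round((start - t0) * rate))
        i1 = i0 + n_samp
        seg = np.stack([eeg[ch].values[i0:i1] for ch in EEG_CHANNELS])
        if seg.shape[1] < n_samp:
            continue
        if (~np.isfinite(seg)).mean() > max_masked_frac:
            continue
        nb = max(1, int(round(baseline_s * rate)))
        seg = seg - np.nanmean(seg[:, :nb], axis=1, keepdims=True)
        epochs.append(np.nan_to_num(seg, nan=0.0))
        kept.append(labels.labels[i])
    if not epochs:
        raise ValueError("epoch_by_labels: no surviving epochs")
    return EpochSet(np.stack(epochs), np.asarray(kept), labels.interval_s, rate)


def _band_power(psd: np.ndarray, f: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    m = (f >= band[0]) & (f <= band[1])
    return psd[..., m].sum(axis=-1)


def alpha_ratio_features(epochs: EpochSet, mode: str = "all_channels"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-ratio feature matrix and the surviving labels.

    Per epoch and channel the feature is periodogram power in 8-13 Hz
    divided by power in 4-30 Hz (always in (0, 1]).  ``all_channels``
    yields 6 features ordered F3, FC3, C3, F4, FC4, C4;
    ``left_minus_right`` yields the 3 differences F3−F4, FC3−FC4,
    C3−C4 of those ratios.  Silent epochs (zero broadband power) are
    dropped with their labels.
    """
    if mode not in ("all_channels", "left_minus_right"):
        raise ValueError(f"unknown feature mode {mode!r}")
    x = epochs.data
    n = x.shape[-1]
    f = np.fft.rfftfreq(n, d=1.0 / epochs.rate)
    psd = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    alpha = _band_power(psd, f, ALPHA_BAND)
    broad = _band_power(psd, f, BROAD_BAND)
    ok = (broad > 0).all(axis=1)
    if not ok.all():
        logger.warning("dropping %d silent epochs", int((~ok).sum()))
    ratios = alpha[ok] / broad[ok]
    if mode == "all_channels":
        X = ratios
    else:
        li = [EEG_CHANNELS.index(c) for c in LEFT]
        ri = [EEG_CHANNELS.index(c) for c in RIGHT]
        X = ratios[:, li] - ratios[:, ri]
    return X, epochs.labels[ok]


def _make_model(method: str, seed: int):
    method = method.upper()
    if method == "LDA":
        return LinearDiscriminantAnalysis()
    if method == "SVM":
        return SVC(kernel="linear", C=1.0)
    if method == "SLR":
        return LogisticRegression(C=1000.0, max_iter=5000)
    raise ValueError(f"unknown method {method!r} (LDA, SVM, SLR)")


def crossval_classify(X: np.ndarray, y: np.ndarray, method: str = "LDA",
                      n_folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validated accuracy (percent per fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("degenerate labels: only one class present")
    n_folds = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        model = _make_model(method, seed)
        model.fit(X[train], y[train])
        accs.append(100.0 * float(np.mean(model.predict(X[test]) == y[test])))
    return CVResult(method.upper(), np.asarray(accs))


def build_accuracy_table(records: list[dict]) -> pd.DataFrame:
    """Mean/SD accuracy over participants per label x mode x trial.

    ``records`` carry keys participant, source, interval_s, mode,
    trial, accuracy (a participant-level CV mean, percent).  The
    output mirrors the published layout: one row per
    (label(interval), feature mode), mean and SD columns per trial.
    """
    df = pd.DataFrame(records)
    df["label"] = df["source"] + "(" + df["interval_s"].astype(int).astype(str) + ")"
    rows = []
    for (label, mode), grp in df.groupby(["label", "mode"], sort=True):
        row = {"label": label, "mode": mode}
        for trial, tg in grp.groupby("trial"):
            vals = tg["accuracy"].to_numpy()
            row[f"trial{trial}_mean"] = float(np.mean(vals))
            row[f"trial{trial}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index(["label", "mode"])
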