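"""Sensor-stream containers, CSV serialization, resampling, alignment.

All devices in the recording rig run at different native rates (10 Hz
ROS-integrated channels, 128 Hz blink strength, 256 Hz EEG, event-based
inter-beat intervals), so a session bundles heterogeneous streams and
provides the machinery to place them on one analysis clock.

Time convention: seconds (float) from session start; every window and
bin in the package is half-open ``[t, t + w)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: EEG channel names: left hemisphere then right hemisphere.
EEG_CHANNELS = ("F3", "FC3", "C3", "F4", "FC4", "C4")

#: 10 Hz grid channels in deterministic column order for the grid CSV.
GRID_CHANNELS = ("gsr", "lever", "joystick_y", "meditation", "blink_strength_binned")

#: Channels required per modality (EEG is always required).
REQUIRED_CHANNELS = {
    "autonomous": ("gsr", "ibi_event", "lever", "meditation", "blink_strength"),
    "self_drive": ("gsr", "ibi_event", "joystick_y", "meditation", "blink_strength"),
    "rest": ("gsr", "ibi_event", "meditation", "blink_strength"),
}

Modality = Literal["autonomous", "self_drive", "rest"]
Condition = Literal["wide", "narrow", "none"]


@dataclass
class SensorStream:
    """One uniformly- or event-sampled channel.

    ``nominal_rate`` is the device rate in Hz, with 0 denoting an event
    series (e.g. inter-beat intervals, where each sample is the RR
    interval preceding the beat at its timestamp).  ``NaN`` values are
    explicit missing flags and are never silently interpolated.
    """

    name: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError(
                f"stream '{self.name}': len(timestamps) != len(values) "
                f"({self.timestamps.size} vs {self.values.size})"
            )
        if self.timestamps.size > 1:
            diffs = np.diff(self.timestamps)
            if not np.all(diffs > 0):
                idx = int(np.argmax(diffs <= 0))
                raise ValueError(
                    f"stream '{self.name}': timestamps not strictly increasing "
                    f"at index {idx + 1}"
                )

    def __len__(self) -> int:
        return self.values.size

    @property
    def is_event_series(self) -> bool:
        return self.nominal_rate == 0

    def shifted(self, offset_s: float) -> "SensorStream":
        """Return a copy with ``offset_s`` subtracted from timestamps."""
        return replace(self, timestamps=self.timestamps - offset_s)


@dataclass(frozen=True)
class SessionMeta:
    """Identity and clock bookkeeping for one recording session."""

    participant_id: str
    modality: Modality
    condition: Condition
    trial: int = 1
    loop: int = 1
    clock_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("autonomous", "self_drive", "rest"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.condition not in ("wide", "narrow", "none"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.modality == "rest" and self.condition != "none":
            raise ValueError("rest sessions have condition 'none'")
        if self.modality != "rest" and self.condition == "none":
            raise ValueError(f"{self.modality} sessions require a corridor condition")
        if self.trial < 1 or self.loop < 1:
            raise ValueError("trial and loop are 1-based")

    @property
    def stem(self) -> str:
        return (
            f"{self.participant_id}_{self.modality}_{self.condition}"
            f"_t{self.trial}_l{self.loop}"
        )


@dataclass
class Session:
    """Aligned bundle of all streams for one participant/condition/trial/loop."""

    meta: SessionMeta
    streams: dict[str, SensorStream]
    grid_rate: float = 10.0

    def __getitem__(self, name: str) -> SensorStream:
        try:
            return self.streams[name]
        except KeyError:
            raise KeyError(f"session {self.meta.stem} has no stream '{name}'") from None

    def eeg(self) -> dict[str, SensorStream]:
        return {ch: self.streams[ch] for ch in EEG_CHANNELS if ch in self.streams}

    def validate_channels(self) -> None:
        required = REQUIRED_CHANNELS[self.meta.modality]
        for name in required:
            if name not in self.streams or len(self.streams[name]) == 0:
                raise ValueError(
                    f"session {self.meta.stem}: required channel '{name}' missing or empty"
                )


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(
    stream: SensorStream,
    rate: float,
    method: Literal["hold", "linear", "bin_mean"] = "linear",
    grid: np.ndarray | None = None,
) -> SensorStream:
    """Resample a stream onto the uniform grid ``k / rate`` over its span.

    ``hold`` carries the last observation forward, ``linear``
    interpolates, and ``bin_mean`` averages the samples in each
    half-open bin ``[t, t + 1/rate)`` (empty bins are NaN-flagged).
    An explicit ``grid`` overrides the span-derived one (values beyond
    the stream's span clamp to the edge samples for hold/linear).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(stream) == 0:
        raise ValueError(f"stream '{stream.name}' is empty")
    if method == "linear" and len(stream) < 2:
        raise ValueError(f"stream '{stream.name}': linear resampling needs >= 2 samples")

    t = stream.timestamps
    if grid is None:
        k0 = int(np.ceil(t[0] * rate - 1e-9))
        k1 = int(np.floor(t[-1] * rate + 1e-9))
        grid = np.arange(k0, k1 + 1) / rate

    if method == "hold":
        idx = np.searchsorted(t, grid + 1e-12, side="right") - 1
        idx = np.clip(idx, 0, len(t) - 1)
        out = stream.values[idx]
    elif method == "linear":
        out = np.interp(grid, t, stream.values)
    elif method == "bin_mean":
        bins = np.searchsorted(grid, t + 1e-12, side="right") - 1
        out = np.full(grid.size, np.nan)
        valid = (bins >= 0) & (bins < grid.size) & np.isfinite(stream.values)
        if valid.any():
            sums = np.bincount(bins[valid], weights=stream.values[valid], minlength=grid.size)
            counts = np.bincount(bins[valid], minlength=grid.size)
            nz = counts > 0
            out[nz] = sums[nz] / counts[nz]
    else:
        raise ValueError(f"unknown resample method {method!r}")

    return SensorStream(stream.name, grid, out, nominal_rate=rate, units=stream.units)


def align_streams(session: Session) -> Session:
    """Correct per-device clock offsets and unify the analysis grid.

    Each stream is shifted by its device's ``clock_offsets`` entry
    (seconds the device clock runs ahead of the session clock).  EEG
    channels stay at their native rate; the uniform low-rate channels
    are resampled onto the common ``grid_rate`` grid; event series keep
    their (shifted) event times.
    """
    offsets = session.meta.clock_offsets or {}
    duration = max(
        (s.timestamps[-1] for s in session.streams.values() if len(s)), default=0.0
    )
    rate = session.grid_rate
    shifted_streams: dict[str, SensorStream] = {}
    grid_names: list[str] = []
    for name, stream in session.streams.items():
        off = float(offsets.get(name, 0.0))
        if abs(off) > duration:
            raise ValueError(
                f"clock offset {off} s for '{name}' exceeds session duration {duration} s"
            )
        shifted_streams[name] = stream.shifted(off)
        if name not in EEG_CHANNELS and not stream.is_event_series and name != "blink_strength":
            grid_names.append(name)

    aligned = dict(shifted_streams)
    if grid_names:
        # one shared grid spanning the union of the low-rate channels
        t0 = min(shifted_streams[n].timestamps[0] for n in grid_names)
        t1 = max(shifted_streams[n].timestamps[-1] for n in grid_names)
        k0 = int(np.ceil(t0 * rate - 1e-9))
        k1 = int(np.floor(t1 * rate + 1e-9))
        grid = np.arange(k0, k1 + 1) / rate
        for name in grid_names:
            method = "hold" if name == "meditation" else "linear"
            aligned[name] = resample_to_grid(shifted_streams[name], rate, method, grid=grid)
    return Session(session.meta, aligned, grid_rate=session.grid_rate)


# ---------------------------------------------------------------------------
# CSV serialization
#
# Layout: one grid CSV for the 10 Hz channels (+ IBI events as paired
# time/value columns), one EEG CSV at 256 Hz, one manifest.json listing
# file -> channel mapping.  UTF-8, header row, comma separated, one "t"
# column in seconds.


def _bin_max(stream: SensorStream, rate: float) -> SensorStream:
    """Per-bin maximum onto the grid: preserves pulse peaks of the
    128 Hz blink-strength channel when storing it at the grid rate."""
    t = stream.timestamps
    k0 = int(np.ceil(t[0] * rate - 1e-9))
    k1 = int(np.floor(t[-1] * rate + 1e-9))
    grid = np.arange(k0, k1 + 1) / rate
    bins = np.searchsorted(grid, t + 1e-12, side="right") - 1
    out = np.zeros(grid.size)
    valid = (bins >= 0) & (bins < grid.size) & np.isfinite(stream.values)
    np.maximum.at(out, bins[valid], stream.values[valid])
    return SensorStream("blink_strength_binned", grid, out, nominal_rate=rate, units=stream.units)


def write_session(session: Session, root_path: str | Path) -> dict:
    """Write a session to CSV files; return the manifest.

    Grid channels share one ``t`` column; IBI beats are stored as
    paired ``ibi_event_t`` / ``ibi_event`` columns (exact beat times,
    padded with empty cells).  A session carrying the native 128 Hz
    ``blink_strength`` stream has it binned (per-bin max) to the grid
    as ``blink_strength_binned``.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    stem = session.meta.stem

    streams = dict(session.streams)
    if "blink_strength" in streams and "blink_strength_binned" not in streams:
        streams["blink_strength_binned"] = _bin_max(streams.pop("blink_strength"), session.grid_rate)

    manifest: dict = {
        "meta": {
            "participant_id": session.meta.participant_id,
            "modality": session.meta.modality,
            "condition": session.meta.condition,
            "trial": session.meta.trial,
            "loop": session.meta.loop,
            "clock_offsets": dict(session.meta.clock_offsets),
        },
        "grid_rate": session.grid_rate,
        "files": {},
    }

    grid_present = [c for c in GRID_CHANNELS if c in streams]
    has_ibi = "ibi_event" in streams
    if grid_present or has_ibi:
        cols: dict[str, np.ndarray] = {}
        if grid_present:
            t_grid = streams[grid_present[0]].timestamps
            for c in grid_present:
                if not np.array_equal(streams[c].timestamps, t_grid):
                    raise ValueError(
                        f"grid channel '{c}' not on the common grid; align the session first"
                    )
            n = t_grid.size
        else:
            t_grid = streams["ibi_event"].timestamps
            n = t_grid.size
        cols["t"] = t_grid
        for c in grid_present:
            cols[c] = streams[c].values
        if has_ibi:
            ibi = streams["ibi_event"]
            if len(ibi) > n:
                raise ValueError("more IBI events than grid rows; cannot serialize")
            pad = np.full(n, np.nan)
            col_t, col_v = pad.copy(), pad.copy()
            col_t[: len(ibi)] = ibi.timestamps
            col_v[: len(ibi)] = ibi.values
            cols["ibi_event_t"] = col_t
            cols["ibi_event"] = col_v
        grid_file = f"{stem}_grid.csv"
        pd.DataFrame(cols).to_csv(root / grid_file, index=False, float_format="%.17g")
        manifest["files"][grid_file] = grid_present + (["ibi_event"] if has_ibi else [])

    eeg_present = [c for c in EEG_CHANNELS if c in streams]
    if eeg_present:
        t_eeg = streams[eeg_present[0]].timestamps
        cols = {"t": t_eeg}
        for c in eeg_present:
            cols[c] = streams[c].values
        eeg_file = f"{stem}_eeg.csv"
        pd.DataFrame(cols).to_csv(root / eeg_file, index=False, float_format="%.17g")
        manifest["files"][eeg_file] = eeg_present

    with open(root / f"{stem}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


_RATES = {
    "gsr": 10.0,
    "lever": 10.0,
    "joystick_y": 10.0,
    "meditation": 10.0,
    "blink_strength_binned": 10.0,
}
_UNITS = {"gsr": "uS", "ibi_event": "s", "joystick_y": "a.u."}


def read_session(root_path: str | Path, meta: SessionMeta) -> Session:
    """Read a session previously written by :func:`write_session`.

    Unparseable rows are skipped with a logged count; a missing
    mandatory file is a hard error naming the file.
    """
    root = Path(root_path)
    stem = meta.stem
    manifest_path = root / f"{stem}_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing mandatory file: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    grid_rate = float(manifest.get("grid_rate", 10.0))

    streams: dict[str, SensorStream] = {}
    for fname, channels in manifest["files"].items():
        path = root / fname
        if not path.exists():
            raise FileNotFoundError(f"missing mandatory file: {path}")
        df = pd.read_csv(path, on_bad_lines="skip")
        n_bad = df["t"].isna().sum()
        if n_bad:
            logger.warning("%s: skipped %d unparseable rows", fname, n_bad)
            df = df[df["t"].notna()]
        t = df["t"].to_numpy(dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            idx = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(f"{fname}: non-monotone timestamps at index {idx + 1}")
        for c in channels:
            if c == "ibi_event":
                et = df["ibi_event_t"].to_numpy(dtype=float)
                ev = df["ibi_event"].to_numpy(dtype=float)
                m = np.isfinite(et)
                streams[c] = SensorStream(c, et[m], ev[m], nominal_rate=0.0, units="s")
            else:
                rate = 256.0 if c in EEG_CHANNELS else _RATES.get(c, grid_rate)
                streams[c] = SensorStream(
                    c, t, df[c].to_numpy(dtype=float), nominal_rate=rate,
                    units=_UNITS.get(c, "a.u."),
                )

    session = Session(meta, streams, grid_rate=grid_rate)
    required = REQUIRED_CHANNELS[meta.modality]
    for name in required:
        key = "blink_strength_binned" if name == "blink_strength" else name
        if key not in streams or len(streams[key]) == 0 or (
            key != "ibi_event" and not np.isfinite(streams[key].values).any()
        ):
            raise ValueError(f"session {stem}: required channel '{name}' missing or empty")
    return session
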