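"""Named time series of derived characterizations.

A :class:`ParameterSeries` is the common currency between the
characterization stages and the downstream correlation / labelling
stages: one named, time-stamped vector of real values with NaN marking
missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed set of characterization names used throughout the pipeline.
PARAMETER_NAMES = (
    "Blinkcount",
    "GSRSCL",
    "LFHF",
    "Meditation",
    "GSRsiginc",
    "Blinksiginc",
    "medianRRI",
    "alphaAsym",
)


@dataclass
class ParameterSeries:
    """One derived characterization sampled on a time grid.

    Parameters
    ----------
    name
        Characterization identifier.  Canonical names live in
        :data:`PARAMETER_NAMES`; free-form names (e.g. ``"lever"``,
        ``"JoystickR2"``) are accepted for auxiliary series.
    timestamps
        Seconds from session start, strictly increasing.
    values
        Real values; ``NaN`` flags a missing sample.
    """

    name: str
    timestamps: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError(
                f"{self.name}: timestamps and values length mismatch "
                f"({self.timestamps.size} vs {self.values.size})"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"{self.name}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def dropna(self) -> "ParameterSeries":
        m = self.valid_mask
        return ParameterSeries(self.name, self.timestamps[m], self.values[m], dict(self.meta))
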