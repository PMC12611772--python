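"""Core data containers shared across the analysis modules.

The containers are deliberately thin: numpy arrays plus identifiers, with
validation at construction. Tabular interchange (CSV) lives in :mod:`nucleokin.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrapCurve",
    "CellTrack",
    "GrowthCurve",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no usable signal
    (e.g. an all-constant fluorescence trace)."""


@dataclass
class FrapCurve:
    """One cell's photobleach-recovery trace.

    ``times`` and ``intensities`` include the single pre-bleach sample, flagged
    by ``is_prebleach``. Times are seconds and must be strictly increasing.
    ``normalized`` records whether intensities have been divided by the
    pre-bleach value (and the time origin moved to the first post-bleach frame).
    """

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray
    is_prebleach: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.is_prebleach = np.asarray(self.is_prebleach, dtype=bool)
        if not (self.times.shape == self.intensities.shape == self.is_prebleach.shape):
            raise ValueError("times, intensities and is_prebleach must have equal length")
        if self.times.ndim != 1:
            raise ValueError("FrapCurve arrays must be one-dimensional")
        if int(self.is_prebleach.sum()) != 1:
            raise ValueError("exactly one pre-bleach sample is required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def prebleach_intensity(self) -> float:
        return float(self.intensities[self.is_prebleach][0])

    @property
    def postbleach_times(self) -> np.ndarray:
        return self.times[~self.is_prebleach]

    @property
    def postbleach_intensities(self) -> np.ndarray:
        return self.intensities[~self.is_prebleach]

    @property
    def n_postbleach(self) -> int:
        return int((~self.is_prebleach).sum())

    def replace(self, **changes) -> "FrapCurve":
        return replace(self, **changes)


@dataclass
class CellTrack:
    """Per-cell time series of position and/or intensity.

    Positions are micrometres (pixel scaling applied upstream); ``times`` are in
    the acquisition's native unit (minutes for migration movies, hours for
    accumulation series) and must be strictly increasing.
    """

    track_id: str
    times: np.ndarray
    intensity: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")
        for name in ("intensity", "x", "y"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
                setattr(self, name, arr)
        if self.intensity is not None and np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    @property
    def has_positions(self) -> bool:
        return self.x is not None and self.y is not None

    def replace(self, **changes) -> "CellTrack":
        return replace(self, **changes)


@dataclass
class GrowthCurve:
    """One animal's caliper tumour-volume series (mm^3 against days)."""

    animal_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape:
            raise ValueError("days and volumes must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")
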