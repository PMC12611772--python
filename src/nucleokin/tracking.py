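"""Cell-migration velocimetry from positional tracks.

Mean velocity is the average over consecutive frames of the Euclidean step
length divided by the frame interval — a per-cell quantity; cohort values are
the mean over cells (not over pooled steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellTrack

__all__ = ["VelocityResult", "mean_velocity", "cohort_velocity"]


@dataclass
class VelocityResult:
    track_id: str
    mean_velocity: float     # um / min
    n_steps: int
    path_length: float       # um


def mean_velocity(track: CellTrack, frame_interval: float,
                  allow_gaps: bool = False) -> VelocityResult:
    """Mean migration speed of one track, um/min.

    Positions must be micrometres. With ``allow_gaps=False`` (default) the
    track must be uniformly sampled at ``frame_interval`` minutes; with
    ``allow_gaps=True`` each step is divided by its own elapsed time instead.
    """
    if not track.has_positions:
        raise ValueError(f"track {track.track_id} has no positions")
    if len(track) < 2:
        raise ValueError(f"track {track.track_id}: need >= 2 positions")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    dt = np.diff(track.times)
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    if allow_gaps:
        v = float(np.mean(steps / dt))
    else:
        if not np.allclose(dt, frame_interval, rtol=1e-6, atol=1e-9):
            raise ValueError(
                f"track {track.track_id}: non-uniform time stamps "
                "(pass allow_gaps=True for per-step division)")
        v = float(np.mean(steps) / frame_interval)
    return VelocityResult(track.track_id, v, n_steps=steps.size, path_length=path)


def cohort_velocity(tracks, frame_interval: float, allow_gaps: bool = False):
    """Per-track velocities plus cohort mean ± SEM (per-cell-then-cohort)."""
    results = [mean_velocity(t, frame_interval, allow_gaps=allow_gaps) for t in tracks]
    table = pd.DataFrame([r.__dict__ for r in results])
    v = table["mean_velocity"]
    summary = {
        "n_tracks": len(table),
        "mean_velocity": {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
        },
    }
    return table, summary
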