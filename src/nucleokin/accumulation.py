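"""Nuclear protein accumulation kinetics from single-cell intensity tracks.

Tracks are normalized to fold change over their initial sample, screened with a
line-fit outlier filter (a track is rejected when more than ``max_deviating``
points sit further than ``tolerance`` fold units from its least-squares line),
and the per-track OLS slope gives the accumulation rate in fold per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellTrack
from .stats import anova_tukey, two_sample_t

__all__ = [
    "to_fold_change",
    "line_filter",
    "AccumulationResult",
    "cohort_rates",
    "compare_rates",
    "EmptyCohortError",
]


class EmptyCohortError(ValueError):
    """All tracks were rejected by the quality filter."""


def to_fold_change(track: CellTrack) -> CellTrack:
    """Divide every intensity by the first sample (which becomes exactly 1.0)."""
    if track.intensity is None:
        raise ValueError("track has no intensity channel")
    first = track.intensity[0]
    if first <= 0:
        raise ValueError(f"track {track.track_id}: non-positive initial intensity")
    return track.replace(intensity=track.intensity / first)


def _ols_line(t: np.ndarray, y: np.ndarray):
    tbar = t.mean()
    ybar = y.mean()
    denom = ((t - tbar) ** 2).sum()
    slope = ((t - tbar) * (y - ybar)).sum() / denom
    intercept = ybar - slope * tbar
    return slope, intercept


@dataclass
class AccumulationResult:
    track_id: str
    slope: float            # fold per hour
    intercept: float        # fold
    kept: bool
    n_deviating_points: int
    final_fold: float
    n_points: int


def line_filter(track: CellTrack, tolerance: float = 0.2, max_deviating: int = 4,
                times_in_hours: bool = True) -> AccumulationResult:
    """Line-of-best-fit outlier screen for a fold-change track.

    An OLS line is fitted to (time, fold); a point "deviates" when its absolute
    residual exceeds ``tolerance``. The track is rejected iff strictly more
    than ``max_deviating`` points deviate (a track with exactly
    ``max_deviating`` deviating points is kept).
    """
    if len(track) < 3:
        raise ValueError(f"track {track.track_id}: need >= 3 points for the line filter")
    t = track.times if times_in_hours else track.times / 60.0
    y = track.intensity
    slope, intercept = _ols_line(t, y)
    resid = y - (intercept + slope * t)
    n_dev = int((np.abs(resid) > tolerance).sum())
    return AccumulationResult(
        track_id=track.track_id,
        slope=float(slope),
        intercept=float(intercept),
        kept=n_dev <= max_deviating,
        n_deviating_points=n_dev,
        final_fold=float(y[-1]),
        n_points=len(track),
    )


def cohort_rates(tracks, duration_h: float | None = None, tolerance: float = 0.2,
                 max_deviating: int = 4, window_h: float | None = None,
                 times_in_hours: bool = True, already_fold: bool = False):
    """Filter a cohort of tracks and summarize accumulation rate and endpoint.

    Parameters
    ----------
    tracks
        CellTracks with intensity. Normalized to fold change here unless
        ``already_fold``.
    duration_h
        If given, samples beyond this time are dropped before any analysis.
    window_h
        Optional rate-estimation window: the filter and the OLS slope use only
        samples with t <= window_h (the linear rise of a saturating series),
        while ``final_fold`` always comes from the track's last retained sample.
        Default ``None`` analyses the full track.

    Returns ``(table, summary)``: per-track results and a cohort dict with
    mean ± SEM slope (fold/h) and final fold over kept tracks.
    """
    rows = []
    for track in tracks:
        ft = track if already_fold else to_fold_change(track)
        t = ft.times if times_in_hours else ft.times / 60.0
        y = ft.intensity
        if duration_h is not None:
            keep = t <= duration_h + 1e-9
            t, y = t[keep], y[keep]
        final_fold = float(y[-1])
        if window_h is not None:
            win = t <= window_h + 1e-9
            tw, yw = t[win], y[win]
        else:
            tw, yw = t, y
        res = line_filter(CellTrack(ft.track_id, tw, intensity=yw),
                          tolerance=tolerance, max_deviating=max_deviating)
        res.final_fold = final_fold
        rows.append(res)

    table = pd.DataFrame([r.__dict__ for r in rows])
    kept = table[table["kept"]]
    if len(kept) < 2:
        raise EmptyCohortError(
            f"only {len(kept)} of {len(table)} tracks survive the line filter")

    def _ms(col):
        v = kept[col]
        return {"mean": float(v.mean()), "sem": float(v.std(ddof=1) / np.sqrt(len(v)))}

    summary = {
        "n_input": len(table),
        "n_kept": int(len(kept)),
        "n_rejected": int(len(table) - len(kept)),
        "rate_fold_per_h": _ms("slope"),
        "final_fold": _ms("final_fold"),
    }
    return table, summary


def compare_rates(groups, labels=None):
    """Compare per-track accumulation rates across conditions.

    Two groups: Welch t-test. Three or more: one-way ANOVA with Tukey HSD.
    """
    if len(groups) == 2:
        lab = tuple(labels) if labels is not None else ("a", "b")
        res = two_sample_t(groups[0], groups[1], variant="welch", labels=lab)
        return res, [res]
    return anova_tukey(groups, labels=labels)
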