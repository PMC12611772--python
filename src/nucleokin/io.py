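"""Readers/writers for the tabular and image interchange formats, plus the
serializable run configuration.

Canonical formats: CSV for tracks/curves/measurements/growth tables, TIFF for
label masks and intensity channels, JSON for result summaries, YAML for
configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import CellTrack, FrapCurve, GrowthCurve

__all__ = [
    "RunConfig",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_frap_csv",
    "write_frap_csv",
    "read_growth_csv",
    "read_image_pair",
    "write_image_pair",
    "write_json",
]

# header synonyms per dialect -> canonical names
_TRACK_DIALECTS = {
    "generic": {
        "track_id": "track_id", "time": "time", "x": "x", "y": "y",
        "intensity": "intensity", "frame": "frame",
    },
    "trackmate-like": {
        "TRACK_ID": "track_id", "POSITION_T": "time", "POSITION_X": "x",
        "POSITION_Y": "y", "MEAN_INTENSITY": "intensity", "FRAME": "frame",
    },
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run, serializable to YAML."""

    seed: int = 0
    bleach_depth_max: float = 0.25
    line_filter_tolerance: float = 0.2
    line_filter_max_deviating: int = 4
    tau_bounds: tuple = (0.05, 100.0)
    n_starts: int = 5
    pixel_size_um: float = 1.0
    frame_interval_min: float = 5.0
    channel_map: dict = field(default_factory=dict)
    output_dir: str = "results"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tau_bounds"] = list(d["tau_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "tau_bounds" in d:
            d["tau_bounds"] = tuple(d["tau_bounds"])
        return cls(**d)


def read_tracks_csv(path, dialect: str = "generic") -> list:
    """Read a tracker-style CSV into :class:`CellTrack` objects.

    Requires a track-id column, a time column, and at least one of
    (x and y) or intensity. Rows are sorted by time within each track;
    duplicate (track, time) pairs are an error.
    """
    if dialect not in _TRACK_DIALECTS:
        raise ValueError(f"unknown dialect: {dialect}")
    mapping = _TRACK_DIALECTS[dialect]
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    if "track_id" not in df.columns:
        raise ValueError(f"{path}: missing track-id column")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing time column")
    has_xy = "x" in df.columns and "y" in df.columns
    if not has_xy and "intensity" not in df.columns:
        raise ValueError(f"{path}: need x/y or intensity columns")
    if df.duplicated(subset=["track_id", "time"]).any():
        dup = df[df.duplicated(subset=["track_id", "time"], keep=False)]
        raise ValueError(
            f"{path}: duplicate (track, time) pairs at rows "
            f"{(dup.index + 2).tolist()[:10]}")
    tracks = []
    for tid, g in df.sort_values("time").groupby("track_id", sort=True):
        tracks.append(CellTrack(
            str(tid),
            g["time"].to_numpy(dtype=float),
            intensity=g["intensity"].to_numpy(dtype=float) if "intensity" in g else None,
            x=g["x"].to_numpy(dtype=float) if has_xy else None,
            y=g["y"].to_numpy(dtype=float) if has_xy else None,
        ))
    return tracks


def write_tracks_csv(tracks, path, dialect: str = "trackmate-like") -> None:
    inverse = {v: k for k, v in _TRACK_DIALECTS[dialect].items()}
    rows = []
    for track in tracks:
        for i in range(len(track)):
            row = {"track_id": track.track_id, "frame": i, "time": track.times[i]}
            if track.x is not None:
                row["x"] = track.x[i]
                row["y"] = track.y[i]
            if track.intensity is not None:
                row["intensity"] = track.intensity[i]
            rows.append(row)
    df = pd.DataFrame(rows).rename(columns=inverse)
    df.to_csv(path, index=False)


def read_frap_csv(path) -> list:
    """Read long-format FRAP curves: cell_id, t_seconds, intensity, is_prebleach."""
    df = pd.read_csv(path)
    required = {"cell_id", "t_seconds", "intensity", "is_prebleach"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for cid, g in df.sort_values("t_seconds").groupby("cell_id", sort=True):
        curves.append(FrapCurve(
            str(cid), g["t_seconds"].to_numpy(dtype=float),
            g["intensity"].to_numpy(dtype=float),
            g["is_prebleach"].to_numpy().astype(bool),
        ))
    return curves


def write_frap_csv(curves, path) -> None:
    rows = []
    for c in curves:
        for i in range(c.times.size):
            rows.append({"cell_id": c.cell_id, "t_seconds": c.times[i],
                         "intensity": c.intensities[i],
                         "is_prebleach": int(c.is_prebleach[i])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_csv(path) -> list:
    """Read a caliper table into :class:`GrowthCurve` objects.

    Columns: animal_id, arm, day plus either volume_mm3 or length_mm/width_mm.
    """
    from .growth import caliper_volume

    df = pd.read_csv(path)
    for col in ("animal_id", "arm", "day"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "volume_mm3" not in df.columns:
        if not {"length_mm", "width_mm"} <= set(df.columns):
            raise ValueError(f"{path}: need volume_mm3 or length_mm/width_mm")
        df = df.copy()
        df["volume_mm3"] = caliper_volume(df["length_mm"].to_numpy(),
                                          df["width_mm"].to_numpy())
    curves = []
    for animal, g in df.sort_values("day").groupby("animal_id", sort=True):
        curves.append(GrowthCurve(str(animal), str(g["arm"].iloc[0]),
                                  g["day"].to_numpy(dtype=float),
                                  g["volume_mm3"].to_numpy(dtype=float)))
    return curves


def read_image_pair(label_path, channel_paths):
    """Read a label mask TIFF and a channel-name -> path map of intensity TIFFs.

    Images must be 2-D; the label image must be integer-typed and shapes must
    match. Returns ``(label_array, {name: array})``.
    """
    labels = tifffile.imread(label_path)
    if labels.ndim != 2:
        raise ValueError(f"{label_path}: expected a 2-D label image, got {labels.ndim}-D")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{label_path}: label image must be integer-typed, "
                         f"got {labels.dtype}")
    channels = {}
    for name, p in dict(channel_paths).items():
        img = tifffile.imread(p)
        if img.shape != labels.shape:
            raise ValueError(f"{p}: shape {img.shape} does not match label "
                             f"image {labels.shape}")
        channels[name] = img
    return labels, channels


def write_image_pair(label_image, channels, directory, prefix: str = "synthetic"):
    """Write a label mask plus intensity channels as 16-bit grayscale TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label_path = directory / f"{prefix}_labels.tif"
    tifffile.imwrite(label_path, np.asarray(label_image, dtype=np.uint16))
    paths = {"labels": label_path}
    for name, img in channels.items():
        p = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, np.asarray(img, dtype=np.uint16))
        paths[name] = p
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path) -> None:
    """Atomic-ish JSON dump (write then rename) with numpy-type coercion."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    tmp.replace(path)
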