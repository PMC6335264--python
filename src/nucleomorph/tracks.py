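"""Comet-trajectory analysis: nuclear entry and speed statistics.

Growing microtubule plus ends are visualized as fluorescent comets (EB3);
an external tracker turns movies into per-frame coordinate tables. This
module consumes those tables and answers the downstream questions: does any
trajectory of a cell cross into the nucleus, and how fast do comets move.
Comet detection and linking are deliberately not implemented — the input
contract is the track table.

Coordinates follow the track-table convention ``(x_px, y_px)`` = (column,
row); masks are indexed ``mask[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError
from .masks import LabelMask

__all__ = [
    "Track",
    "TrackSet",
    "track_enters_nucleus",
    "track_speeds",
    "summarize_cells",
    "read_tracks_csv",
    "write_tracks_csv",
]

#: sub-pixel sampling step (px) when testing segments against a mask
SEGMENT_STEP_PX = 0.25


@dataclass
class Track:
    track_id: int
    frames: np.ndarray  # strictly increasing integer frame indices
    xy: np.ndarray      # (n, 2) float, columns (x_px, y_px)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise InputError("track coordinates must be an (n, 2) array")
        if len(self.frames) != len(self.xy):
            raise InputError("frames and coordinates must have equal length")
        if len(self.frames) < 2:
            raise InputError("a track needs at least 2 points")
        d = np.diff(self.frames)
        if np.any(d == 0):
            raise InputError(f"track {self.track_id} has duplicate frames")
        if np.any(d < 0):
            raise InputError(f"track {self.track_id} frames are not increasing")


@dataclass
class TrackSet:
    """Trajectories of one cell with acquisition metadata."""

    tracks: list[Track]
    frame_interval_s: float
    pixel_size_um: float
    cell_id: int = 0
    meta: dict = field(default_factory=dict)


def _segment_points(p0: np.ndarray, p1: np.ndarray, step_px: float) -> np.ndarray:
    """Points along [p0, p1] at sub-pixel spacing, endpoints included."""
    dist = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(dist / step_px)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _as_bool_mask(nucleus_mask, label_id: int | None) -> np.ndarray:
    if isinstance(nucleus_mask, LabelMask):
        if label_id is None:
            return nucleus_mask.labels > 0
        return nucleus_mask.labels == int(label_id)
    return np.asarray(nucleus_mask) > 0


def track_enters_nucleus(
    track: Track,
    nucleus_mask,
    label_id: int | None = None,
    step_px: float = SEGMENT_STEP_PX,
) -> bool:
    """True iff the polyline of the track intersects the nucleus mask.

    Consecutive points are joined by straight segments sampled every
    ``step_px`` pixels, so a comet that crosses the nucleus between two
    sampled frames is still counted.
    """
    m = _as_bool_mask(nucleus_mask, label_id)
    if not m.any():
        raise GeometryError("nucleus mask is empty")
    h, w = m.shape
    for i in range(len(track.xy) - 1):
        pts = _segment_points(track.xy[i], track.xy[i + 1], step_px)
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        if m[rows, cols].any():
            return True
    return False


def track_speeds(
    track: Track, frame_interval_s: float, pixel_size_um: float
) -> tuple[np.ndarray, float]:
    """Per-step speeds (um/s) and their mean.

    Each step speed is the Euclidean displacement converted to micrometres
    divided by the elapsed time (frame gaps are honoured).
    """
    if frame_interval_s <= 0 or pixel_size_um <= 0:
        raise InputError("frame_interval_s and pixel_size_um must be > 0")
    steps_px = np.hypot(*np.diff(track.xy, axis=0).T)
    dt = np.diff(track.frames) * frame_interval_s
    speeds = steps_px * pixel_size_um / dt
    return speeds, float(speeds.mean())


def summarize_cells(
    tracksets: list[TrackSet], nuclei: LabelMask
) -> tuple[pd.DataFrame, dict]:
    """Per-cell nuclear-entry table and overall entry fraction.

    For each cell: whether any trajectory intersects that cell's nucleus,
    the number of tracks, and the mean comet speed. The overall summary
    counts cells with at least one nuclear growth track — the statistic
    reported as "neurons with nuclear growth tracks".
    """
    rows = []
    for ts in tracksets:
        nuc = _as_bool_mask(nuclei, ts.cell_id)
        if not nuc.any():
            raise GeometryError(f"cell {ts.cell_id} has no nucleus in the mask")
        entered = any(track_enters_nucleus(t, nuc) for t in ts.tracks)
        mean_speed = float(
            np.mean([track_speeds(t, ts.frame_interval_s, ts.pixel_size_um)[1] for t in ts.tracks])
        ) if ts.tracks else float("nan")
        rows.append(
            {
                "cell_id": ts.cell_id,
                "has_nuclear_track": bool(entered),
                "n_tracks": len(ts.tracks),
                "mean_speed_um_s": mean_speed,
            }
        )
    table = pd.DataFrame(rows)
    n_cells = len(table)
    n_pos = int(table["has_nuclear_track"].sum()) if n_cells else 0
    overall = {
        "n_cells": n_cells,
        "n_with_nuclear_tracks": n_pos,
        "fraction_with_nuclear_tracks": (n_pos / n_cells) if n_cells else float("nan"),
    }
    return table, overall


# -- CSV interface --------------------------------------------------------

def write_tracks_csv(tracksets: list[TrackSet], path: str | Path) -> None:
    rows = []
    for ts in tracksets:
        for t in ts.tracks:
            for f, (x, y) in zip(t.frames, t.xy):
                rows.append((ts.cell_id, t.track_id, int(f), float(x), float(y)))
    pd.DataFrame(rows, columns=["cell_id", "track_id", "frame", "x_px", "y_px"]).to_csv(
        path, index=False
    )


def read_tracks_csv(
    path: str | Path, frame_interval_s: float, pixel_size_um: float
) -> list[TrackSet]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"track CSV is missing columns: {sorted(missing)}")
    if "cell_id" not in df.columns:
        df = df.assign(cell_id=0)
    out = []
    for cell_id, cdf in df.groupby("cell_id"):
        tracks = []
        for tid, tdf in cdf.groupby("track_id"):
            tdf = tdf.sort_values("frame")
            tracks.append(
                Track(int(tid), tdf["frame"].to_numpy(), tdf[["x_px", "y_px"]].to_numpy())
            )
        out.append(TrackSet(tracks, frame_interval_s, pixel_size_um, cell_id=int(cell_id)))
    return out
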