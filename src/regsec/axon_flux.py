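"""Kymograph analysis of puncta entering a photobleached axon segment.

A kymograph (position along the axon path x time) is sampled from the
movie; moving puncta appear as diagonal lines. Tracks are extracted by
per-frame peak detection followed by nearest-neighbor linking, velocities
come from a least-squares line fit, and the axonal influx is the number of
tracks entering from the soma-side end per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import AnalysisError
from .imaging import MovieStack

__all__ = [
    "Kymograph",
    "TrackSegment",
    "build_kymograph",
    "detect_tracks",
    "flux",
    "tracks_to_frame",
]


@dataclass
class Kymograph:
    """Position x time intensity map sampled along an axon path.

    Rows are equal-arc-length (1 px) samples along the path — row 0 is the
    soma-side end — and columns are frames.
    """

    data: np.ndarray
    pixel_size: float
    dt: float

    @property
    def path_length_um(self) -> float:
        return (self.data.shape[0] - 1) * self.pixel_size

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class TrackSegment:
    """One linked particle trajectory on the kymograph."""

    positions_px: np.ndarray       # sample index along the path, per point
    frames: np.ndarray
    velocity_um_s: float
    direction: str                 # "anterograde" (away from soma) or "retrograde"

    @property
    def start_px(self) -> float:
        return float(self.positions_px[0])

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])


def _resample_path(path: np.ndarray) -> np.ndarray:
    """Equal arc-length (1 px) samples of a (row, col) polyline."""
    path = np.asarray(path, dtype=np.float64)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise AnalysisError("path must be an (n>=2, 2) polyline of (row, col)")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise AnalysisError("degenerate path")
    samples = np.arange(0.0, total + 1e-9, 1.0)
    rows = np.interp(samples, arclen, path[:, 0])
    cols = np.interp(samples, arclen, path[:, 1])
    return np.column_stack([rows, cols])


def build_kymograph(stack: MovieStack, path: np.ndarray, width_px: int = 3
                    ) -> Kymograph:
    """Sample intensity along a polyline path, averaging over ``width_px``
    perpendicular to it, for every frame."""
    if width_px < 1:
        raise AnalysisError("width must be >= 1 px")
    pts = _resample_path(path)
    h, w = stack.frame_shape
    if pts[:, 0].min() < 0 or pts[:, 1].min() < 0 \
            or pts[:, 0].max() > h - 1 or pts[:, 1].max() > w - 1:
        raise AnalysisError("path outside the frame")

    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = tangents / np.where(norms > 0, norms, 1.0)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    offsets = np.arange(width_px, dtype=np.float64) - (width_px - 1) / 2.0
    # (n_samples, width, 2) sampling coordinates
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = coords.reshape(-1, 2).T        # (2, n_samples*width)

    n_samples = len(pts)
    kymo = np.empty((n_samples, stack.n_frames), dtype=np.float64)
    for f in range(stack.n_frames):
        vals = ndimage.map_coordinates(stack.data[f], coords, order=1,
                                       mode="nearest")
        kymo[:, f] = vals.reshape(n_samples, width_px).mean(axis=1)
    return Kymograph(data=kymo, pixel_size=stack.pixel_size, dt=stack.dt)


def detect_tracks(kymo: Kymograph, min_length_frames: int = 3,
                  max_jump_px: float = 7.0, threshold: float | None = None,
                  max_gap_frames: int = 2) -> list[TrackSegment]:
    """Extract straight-ish particle traces from a kymograph.

    Per frame (column), peaks above an absolute threshold (default: column
    median + 3x robust SD of the whole kymograph) are found; peaks in
    consecutive frames are linked to the nearest active track within
    ``max_jump_px`` (tracks tolerate ``max_gap_frames`` missed frames).
    Tracks shorter than ``min_length_frames`` are discarded; the velocity
    is the absolute slope of a least-squares line fit.
    """
    data = kymo.data
    med = float(np.median(data))
    sd = float(1.4826 * np.median(np.abs(data - med)))
    if threshold is None:
        threshold = med + 3.0 * max(sd, 1e-12)

    active: list[dict] = []
    done: list[dict] = []
    for f in range(kymo.n_frames):
        col = data[:, f]
        # pad so maxima at the path ends (a punctum just entering) count
        padded = np.concatenate([[col.min() - 1.0], col, [col.min() - 1.0]])
        raw, _ = signal.find_peaks(padded, height=threshold, distance=3)
        peaks = []
        for p in raw - 1:
            # parabolic sub-pixel refinement around the integer peak
            if 1 <= p <= len(col) - 2:
                denom = col[p - 1] - 2 * col[p] + col[p + 1]
                if denom < 0:
                    p = p + 0.5 * (col[p - 1] - col[p + 1]) / denom
            peaks.append(float(p))
        # extend existing tracks greedily, nearest first
        assignments = []
        for tr in active:
            if not peaks:
                break
            dists = [abs(p - tr["pos"][-1]) for p in peaks]
            j = int(np.argmin(dists))
            gap = f - tr["frames"][-1]
            if dists[j] <= max_jump_px * gap:
                assignments.append((tr, peaks.pop(j)))
        for tr, p in assignments:
            tr["pos"].append(float(p))
            tr["frames"].append(f)
        # retire stale tracks
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        for p in peaks:
            active.append({"pos": [float(p)], "frames": [f]})
    done.extend(active)

    segments: list[TrackSegment] = []
    for tr in done:
        if len(tr["frames"]) < min_length_frames:
            continue
        frames = np.asarray(tr["frames"])
        pos = np.asarray(tr["pos"])
        slope = np.polyfit(frames * kymo.dt, pos * kymo.pixel_size, 1)[0]
        direction = "anterograde" if slope >= 0 else "retrograde"
        segments.append(TrackSegment(positions_px=pos, frames=frames,
                                     velocity_um_s=float(abs(slope)),
                                     direction=direction))
    segments.sort(key=lambda s: (s.start_frame, s.start_px))
    return segments


def flux(segments: list[TrackSegment], recording_duration_s: float,
         entry_margin_px: float = 3.0) -> float:
    """Puncta entering from the soma-side end (path start) per minute.

    A segment counts as entering when its first detected point lies within
    ``entry_margin_px`` of the soma-side end of the bleached path.
    """
    if recording_duration_s <= 0:
        raise AnalysisError("recording duration must be positive")
    entering = sum(1 for s in segments if s.start_px <= entry_margin_px)
    return 60.0 * entering / recording_duration_s


def tracks_to_frame(segments: list[TrackSegment], dt: float = 1.0) -> pd.DataFrame:
    rows = [{"t0_s": s.start_frame * dt, "start_px": s.start_px,
             "n_points": len(s.frames), "velocity_um_s": s.velocity_um_s,
             "direction": s.direction} for s in segments]
    return pd.DataFrame(rows)
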