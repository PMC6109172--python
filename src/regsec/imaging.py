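"""Core imaging layer shared by every fluorescence analysis stage.

Provides the calibrated movie container (:class:`MovieStack`) with its
stimulation-protocol sidecar, punctum detection on single frames or
projections, square ROI construction with a fixed rounding convention,
ROI-mean trace extraction and dF/F0 normalization.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; subpixel centroids are floats.
* Frame ``i`` is assigned the timestamp ``t = i * dt`` seconds.
* All time windows are half-open ``[start, end)`` seconds.
* dF/F0 uses ``F0 = mean of the first 10 s of frames`` unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import (
    AnalysisError,
    ClippedRoiError,
    DegenerateBaselineError,
    ProtocolError,
)

__all__ = [
    "StimulusProtocol",
    "MovieStack",
    "Roi",
    "Trace",
    "PunctumDetection",
    "read_stack",
    "write_stack",
    "read_protocol",
    "write_protocol",
    "detect_puncta",
    "make_roi",
    "extract_trace",
    "compute_dff",
    "max_projection",
    "is_mobile",
]


# --------------------------------------------------------------------------
# protocol sidecar
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical/chemical stimulation annotations for a time-lapse movie.

    Parameters
    ----------
    train_onsets
        Onset times (s) of the field-stimulation trains, sorted ascending.
    aps_per_train, train_freq
        Number of action potentials per train and their frequency (Hz);
        together they define the train duration.
    nh4_window
        Half-open window (s) of NH4+ superfusion, which dequenches the
        whole labeled vesicle pool.
    biotin_time
        Time (s) of biotin addition in cargo-release (RUSH) recordings.
    """

    train_onsets: tuple[float, ...] = ()
    aps_per_train: int = 0
    train_freq: float = 0.0
    nh4_window: tuple[float, float] | None = None
    biotin_time: float | None = None

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.train_onsets)
        object.__setattr__(self, "train_onsets", onsets)
        if list(onsets) != sorted(onsets):
            raise ProtocolError("train_onsets must be sorted ascending")

    @property
    def train_duration(self) -> float:
        if self.aps_per_train and self.train_freq > 0:
            return self.aps_per_train / self.train_freq
        return 0.0

    @property
    def hfs_window(self) -> tuple[float, float] | None:
        """Half-open window spanning the whole stimulation period."""
        if not self.train_onsets:
            return None
        return (self.train_onsets[0], self.train_onsets[-1] + max(self.train_duration, 1e-9))

    def validate(self, duration_s: float) -> None:
        hfs = self.hfs_window
        if hfs is not None and hfs[1] > duration_s + 1e-9:
            raise ProtocolError(
                f"stimulation window {hfs} exceeds recording duration {duration_s} s"
            )
        if self.nh4_window is not None:
            lo, hi = self.nh4_window
            if not (0 <= lo < hi):
                raise ProtocolError(f"malformed nh4_window {self.nh4_window}")
            if hi > duration_s + 1e-9:
                raise ProtocolError(
                    f"nh4_window {self.nh4_window} exceeds recording duration {duration_s} s"
                )
        if self.biotin_time is not None and self.biotin_time > duration_s:
            raise ProtocolError("biotin_time beyond the end of the recording")


def write_protocol(path: str | Path, protocol: StimulusProtocol,
                   dt: float, pixel_size: float) -> None:
    """Write the flat ``key=value`` protocol sidecar."""
    lines = [f"dt={dt!r}", f"pixel_size={pixel_size!r}"]
    if protocol.train_onsets:
        lines.append("train_onsets=" + ",".join(repr(t) for t in protocol.train_onsets))
    if protocol.aps_per_train:
        lines.append(f"aps_per_train={protocol.aps_per_train}")
    if protocol.train_freq:
        lines.append(f"train_freq={protocol.train_freq!r}")
    if protocol.nh4_window is not None:
        lines.append("nh4_window=%r,%r" % protocol.nh4_window)
    if protocol.biotin_time is not None:
        lines.append(f"biotin_time={protocol.biotin_time!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_protocol(path: str | Path) -> tuple[StimulusProtocol, float, float]:
    """Parse a sidecar; returns ``(protocol, dt, pixel_size)``."""
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ProtocolError(f"unparseable sidecar line: {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def floats(key: str) -> tuple[float, ...]:
        return tuple(float(v) for v in kv[key].split(",") if v)

    try:
        dt = float(kv["dt"])
        pixel_size = float(kv.get("pixel_size", "1.0"))
    except (KeyError, ValueError) as exc:
        raise ProtocolError(f"sidecar missing/invalid dt or pixel_size: {exc}") from exc
    nh4 = floats("nh4_window") if "nh4_window" in kv else None
    if nh4 is not None and len(nh4) != 2:
        raise ProtocolError("nh4_window must have two values")
    protocol = StimulusProtocol(
        train_onsets=floats("train_onsets") if "train_onsets" in kv else (),
        aps_per_train=int(kv.get("aps_per_train", 0)),
        train_freq=float(kv.get("train_freq", 0.0)),
        nh4_window=(nh4[0], nh4[1]) if nh4 is not None else None,
        biotin_time=float(kv["biotin_time"]) if kv.get("biotin_time") else None,
    )
    return protocol, dt, pixel_size


# --------------------------------------------------------------------------
# movie container
# --------------------------------------------------------------------------

@dataclass
class MovieStack:
    """A calibrated T x Y x X fluorescence time-lapse.

    ``data`` is stored as float64 internally; ``dt`` is seconds/frame and
    ``pixel_size`` micrometres/pixel.
    """

    data: np.ndarray
    dt: float
    pixel_size: float = 1.0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ProtocolError(f"expected T x Y x X stack, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ProtocolError("a movie needs at least two frames")
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def frame_range(self, window: tuple[float, float]) -> tuple[int, int]:
        """Frame indices covering the half-open window ``[start, end)``."""
        start, end = window
        i0 = max(0, int(np.ceil(start / self.dt - 1e-9)))
        i1 = min(self.n_frames, int(np.ceil(end / self.dt - 1e-9)))
        if i1 <= i0:
            raise AnalysisError(f"window {window} contains no frames")
        return i0, i1

    def with_gain(self, c: float) -> "MovieStack":
        return replace(self, data=self.data * c)


def read_stack(path: str | Path, protocol_path: str | Path) -> MovieStack:
    """Load a multi-page TIFF and its protocol sidecar into a MovieStack."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:            # single page: not a movie
        raise ProtocolError(f"{path} holds a single frame, not a time-lapse")
    protocol, dt, pixel_size = read_protocol(protocol_path)
    stack = MovieStack(np.asarray(data, dtype=np.float64), dt=dt,
                       pixel_size=pixel_size, protocol=protocol)
    protocol.validate(stack.duration_s)
    return stack


def write_stack(path: str | Path, stack: MovieStack,
                protocol_path: str | Path | None = None,
                dtype: np.dtype | str | None = None) -> None:
    """Write a MovieStack as a multi-page TIFF (plus optional sidecar).

    ``dtype`` defaults to uint16 when the data are non-negative integers,
    float32 otherwise; uint16 round-trips 16-bit data exactly.
    """
    data = stack.data
    if dtype is None:
        is_int = np.allclose(data, np.round(data))
        dtype = np.uint16 if (is_int and data.min() >= 0 and data.max() < 2**16) else np.float32
    tifffile.imwrite(str(path), np.asarray(data, dtype=dtype))
    if protocol_path is not None:
        write_protocol(protocol_path, stack.protocol, stack.dt, stack.pixel_size)


# --------------------------------------------------------------------------
# ROIs and traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Roi:
    """Square pixel ROI; ``center`` is the rounded centroid, ``size`` the side."""

    center: tuple[int, int]
    size: int

    @property
    def rows(self) -> tuple[int, int]:
        r0 = self.center[0] - (self.size // 2 if self.size % 2 else self.size // 2 - 1)
        return r0, r0 + self.size

    @property
    def cols(self) -> tuple[int, int]:
        c0 = self.center[1] - (self.size // 2 if self.size % 2 else self.size // 2 - 1)
        return c0, c0 + self.size

    def slices(self) -> tuple[slice, slice]:
        (r0, r1), (c0, c1) = self.rows, self.cols
        return slice(r0, r1), slice(c0, c1)

    def pixel_coords(self) -> np.ndarray:
        """(n, 2) array of every (row, col) the ROI covers."""
        (r0, r1), (c0, c1) = self.rows, self.cols
        rr, cc = np.mgrid[r0:r1, c0:c1]
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclass
class Trace:
    """Per-frame mean ROI intensity with optional dF/F0 normalization."""

    values: np.ndarray
    dt: float
    f0: float | None = None
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


@dataclass(frozen=True)
class PunctumDetection:
    """One detected fluorescent punctum on a frame or projection."""

    centroid: tuple[float, float]
    intensity: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_roi(detection: PunctumDetection | tuple[float, float], size: int,
             frame_shape: tuple[int, int] | None = None) -> Roi:
    """Square ROI centered on the rounded centroid.

    For even sizes the rounded centroid sits at the upper-left pixel of the
    central 2x2 block (so a 4x4 ROI at (10, 10) spans rows/cols 9..12).
    Raises :class:`ClippedRoiError` when the ROI would cross the border of
    ``frame_shape`` (if given).
    """
    centroid = detection.centroid if isinstance(detection, PunctumDetection) else detection
    center = (_round_half_up(centroid[0]), _round_half_up(centroid[1]))
    roi = Roi(center=center, size=int(size))
    if frame_shape is not None:
        (r0, r1), (c0, c1) = roi.rows, roi.cols
        if r0 < 0 or c0 < 0 or r1 > frame_shape[0] or c1 > frame_shape[1]:
            raise ClippedRoiError(
                f"{size}x{size} ROI at {center} crosses the border of {frame_shape}"
            )
    return roi


def extract_trace(stack: MovieStack, roi: Roi) -> Trace:
    """Mean ROI intensity per frame."""
    sr, sc = roi.slices()
    if sr.start < 0 or sc.start < 0 or sr.stop > stack.frame_shape[0] \
            or sc.stop > stack.frame_shape[1]:
        raise ClippedRoiError(f"ROI {roi} outside frame {stack.frame_shape}")
    values = stack.data[:, sr, sc].mean(axis=(1, 2))
    return Trace(values=values, dt=stack.dt)


def compute_dff(trace: Trace, f0_seconds: float = 10.0) -> Trace:
    """Normalize a trace to dF/F0.

    F0 is the mean of the first ``round(f0_seconds / dt)`` frames (the first
    10 s of the recording by default).
    """
    n0 = int(round(f0_seconds / trace.dt))
    if n0 < 1:
        raise DegenerateBaselineError("baseline window holds no frames")
    f0 = float(trace.values[:n0].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(f"non-positive baseline F0={f0}")
    return Trace(values=trace.values, dt=trace.dt, f0=f0,
                 dff=(trace.values - f0) / f0)


def max_projection(stack: MovieStack, window: tuple[float, float]) -> np.ndarray:
    """Pixelwise maximum over the frames inside the half-open window."""
    i0, i1 = stack.frame_range(window)
    return stack.data[i0:i1].max(axis=0)


# --------------------------------------------------------------------------
# punctum detection
# --------------------------------------------------------------------------

def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def _local_background(image: np.ndarray, center: tuple[int, int],
                      inner: int = 4, outer: int = 6) -> float:
    """Median of a square annulus ``inner < max(|dr|,|dc|) <= outer``."""
    r, c = center
    h, w = image.shape
    r0, r1 = max(0, r - outer), min(h, r + outer + 1)
    c0, c1 = max(0, c - outer), min(w, c + outer + 1)
    patch = image[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    ring = np.maximum(np.abs(rr - r), np.abs(cc - c)) > inner
    if not ring.any():
        return float(np.median(patch))
    return float(np.median(patch[ring]))


def detect_puncta(image: np.ndarray, min_sigma: float = 1.0, max_sigma: float = 3.0,
                  threshold: float | None = None, intensity: str = "integrated",
                  min_distance: int | None = None,
                  intensity_radius_px: int = 3) -> list[PunctumDetection]:
    """Detect diffraction-limited puncta on a 2D image.

    The image is smoothed at ``min_sigma``, local maxima above an absolute
    threshold are kept (default: background median + 3x robust background
    SD), and centroids are refined to subpixel precision by an
    intensity-weighted mean over a small window after local background
    subtraction.

    Parameters
    ----------
    intensity
        ``"integrated"`` (default) sums the background-subtracted pixels of
        a (2*intensity_radius_px+1)^2 window; ``"peak"`` reports the
        background-subtracted peak pixel.
    intensity_radius_px
        Half-width of the integration window. Kept tight (7x7 by default
        for ~1.5 px spots) so neighboring puncta leak negligibly into each
        other's integrated intensity.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise AnalysisError(f"detect_puncta expects a 2D image, got shape {image.shape}")
    if intensity not in ("integrated", "peak"):
        raise AnalysisError(f"unknown intensity mode {intensity!r}")

    smooth = ndimage.gaussian_filter(image, min_sigma)
    bg = float(np.median(smooth))
    if threshold is None:
        sd = _robust_sd(smooth)
        threshold = bg + 3.0 * max(sd, 1e-12)
    if min_distance is None:
        min_distance = max(2, int(np.ceil(2 * min_sigma)))

    peaks = peak_local_max(smooth, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=False)
    win = int(intensity_radius_px)
    detections: list[PunctumDetection] = []
    h, w = image.shape
    for r, c in peaks:
        local_bg = _local_background(image, (r, c), inner=win, outer=win + 2)
        r0, r1 = max(0, r - win), min(h, r + win + 1)
        c0, c1 = max(0, c - win), min(w, c + win + 1)
        patch = np.clip(image[r0:r1, c0:c1] - local_bg, 0, None)
        total = patch.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centroid = (float((rr * patch).sum() / total), float((cc * patch).sum() / total))
        value = float(total) if intensity == "integrated" \
            else float(image[r, c] - local_bg)
        detections.append(PunctumDetection(centroid=centroid, intensity=max(value, 0.0)))
    detections.sort(key=lambda d: d.centroid)
    return detections


# --------------------------------------------------------------------------
# mobility
# --------------------------------------------------------------------------

def is_mobile(stack: MovieStack, roi: Roi, max_displacement_px: float = 2.0,
              window: tuple[float, float] | None = None,
              block_s: float = 5.0) -> bool | None:
    """Whether a punctum drifts more than ``max_displacement_px`` at baseline.

    The baseline window (default: from t=0 to the first stimulation onset,
    or the full movie when unstimulated) is split into blocks of
    ``block_s`` seconds; each block is averaged to suppress frame noise
    and the intensity-weighted centroid computed within the ROI padded by
    2 px. The punctum is mobile when any block centroid deviates from the
    first by more than the threshold. Blocks without significant contrast
    (peak < 3 robust SDs above the local median — e.g. a quenched
    pHluorin punctum) are skipped; if fewer than two blocks are trackable
    the result is indeterminate: ``None`` with a warning.
    """
    if window is None:
        end = stack.protocol.train_onsets[0] if stack.protocol.train_onsets \
            else stack.duration_s
        window = (0.0, end)
    i0, i1 = stack.frame_range(window)
    sr, sc = roi.slices()
    pad = 2
    r0, r1 = max(0, sr.start - pad), min(stack.frame_shape[0], sr.stop + pad)
    c0, c1 = max(0, sc.start - pad), min(stack.frame_shape[1], sc.stop + pad)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    block = max(1, int(round(block_s / stack.dt)))

    centroids: list[tuple[float, float]] = []
    for b0 in range(i0, i1, block):
        patch = stack.data[b0:min(b0 + block, i1), r0:r1, c0:c1].mean(axis=0)
        med = np.median(patch)
        contrast = patch - med
        rsd = _robust_sd(patch)
        if contrast.max() < 3.0 * max(rsd, 1e-12):
            continue
        weights = np.clip(contrast, 0, None)
        total = weights.sum()
        centroids.append(((rr * weights).sum() / total,
                          (cc * weights).sum() / total))
    if len(centroids) < 2:
        warnings.warn("punctum not trackable at baseline; mobility indeterminate",
                      stacklevel=2)
        return None
    ref = centroids[0]
    return bool(any(np.hypot(c[0] - ref[0], c[1] - ref[1]) > max_displacement_px
                    for c in centroids[1:]))
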