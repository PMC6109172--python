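"""Single-image quantification: neurite length, puncta density and
intensity distributions, Sholl analysis and colocalization.

Neurite length comes from a one-pixel-wide morphological skeleton, summing
inter-pixel steps (1 for 4-neighbors, sqrt(2) for diagonals, diagonals
skipped when an orthogonal path already connects the pair). Colocalization
offers both mask-overlap percentages and a masked Spearman rank
correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr
from skimage.morphology import skeletonize

from .errors import AnalysisError
from .imaging import PunctumDetection

__all__ = [
    "NeuriteSkeleton",
    "neurite_length",
    "puncta_density",
    "sholl",
    "overlap_fraction",
    "masked_spearman",
    "intensity_histogram",
]


@dataclass
class NeuriteSkeleton:
    """One-pixel-wide skeleton of a neurite mask with its total length."""

    pixels: np.ndarray             # (n, 2) (row, col) skeleton coordinates
    total_length_um: float
    pixel_size: float
    soma_centroid: tuple[float, float] | None = None


def _skeleton_length_px(sk: np.ndarray) -> float:
    """Sum of inter-pixel steps over a boolean skeleton.

    Diagonal links are only counted when neither of the two orthogonal
    pixels that would bridge them is present, so an L-corner contributes
    two unit steps rather than an extra sqrt(2).
    """
    length = 0.0
    length += float((sk[:, :-1] & sk[:, 1:]).sum())                 # horizontal
    length += float((sk[:-1, :] & sk[1:, :]).sum())                 # vertical
    diag1 = sk[:-1, :-1] & sk[1:, 1:] \
        & ~(sk[:-1, 1:] | sk[1:, :-1])
    diag2 = sk[:-1, 1:] & sk[1:, :-1] \
        & ~(sk[:-1, :-1] | sk[1:, 1:])
    length += math.sqrt(2.0) * float(diag1.sum() + diag2.sum())
    return length


def neurite_length(mask: np.ndarray, pixel_size: float,
                   soma_centroid: tuple[float, float] | None = None
                   ) -> NeuriteSkeleton:
    """Skeletonize a binary neurite mask and measure its total length."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise AnalysisError("neurite mask must be 2D")
    if not mask.any():
        raise AnalysisError("empty neurite mask")
    sk = skeletonize(mask)
    pixels = np.column_stack(np.nonzero(sk))
    total = _skeleton_length_px(sk) * pixel_size
    return NeuriteSkeleton(pixels=pixels, total_length_um=total,
                           pixel_size=pixel_size, soma_centroid=soma_centroid)


def puncta_density(detections: list[PunctumDetection], skeleton: NeuriteSkeleton,
                   radius_px: float = 2.0) -> float:
    """Detections within ``radius_px`` of the skeleton, per micrometre."""
    if skeleton.total_length_um <= 0:
        raise AnalysisError("zero neurite length")
    if not detections:
        return 0.0
    tree = cKDTree(skeleton.pixels)
    centroids = np.array([d.centroid for d in detections])
    dists, _ = tree.query(centroids)
    return float((dists <= radius_px).sum() / skeleton.total_length_um)


def sholl(detections: list[PunctumDetection], soma_centroid: tuple[float, float],
          bin_um: float, max_um: float, pixel_size: float = 1.0) -> np.ndarray:
    """Percentage of puncta per distance bin from the soma centroid.

    Bins are half-open ``[k*bin, (k+1)*bin)`` micrometres out to
    ``max_um``; percentages are normalized over the puncta within range and
    sum to 100 (all-zero when no punctum is in range).
    """
    if bin_um <= 0:
        raise AnalysisError("bin width must be positive")
    edges = np.arange(0.0, max_um + bin_um * 0.5, bin_um)
    if len(edges) < 2:
        raise AnalysisError("max_um smaller than one bin")
    if not detections:
        return np.zeros(len(edges) - 1)
    centroids = np.array([d.centroid for d in detections])
    d_um = np.hypot(centroids[:, 0] - soma_centroid[0],
                    centroids[:, 1] - soma_centroid[1]) * pixel_size
    counts, _ = np.histogram(d_um, bins=edges)
    total = counts.sum()
    return 100.0 * counts / total if total else counts.astype(float)


def overlap_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Percentage of mask A's pixels also covered by mask B."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise AnalysisError("masks must have the same shape")
    na = a.sum()
    if na == 0:
        raise AnalysisError("mask A is empty")
    return float(100.0 * (a & b).sum() / na)


def masked_spearman(image_a: np.ndarray, image_b: np.ndarray,
                    mask: np.ndarray) -> float:
    """Spearman rank correlation of two channels over the mask pixels.

    Ties are mid-ranked. Returns NaN (with a warning) when either channel
    is constant within the mask, where the correlation is undefined.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise AnalysisError("images and mask must share a shape")
    if m.sum() < 3:
        raise AnalysisError("need at least 3 mask pixels")
    xa, xb = a[m], b[m]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn("constant image within mask; correlation undefined",
                      stacklevel=2)
        return math.nan
    rho = spearmanr(xa, xb).statistic
    return float(rho)


def intensity_histogram(intensities: np.ndarray | list[float],
                        bin_edges: np.ndarray | list[float]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of punctum intensities plus its normalized distribution.

    Returns ``(counts, fractions)``; fractions sum to 1 when any punctum
    falls inside the edges.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise AnalysisError("bin edges must be ascending")
    arr = np.asarray(intensities, dtype=np.float64)
    counts, _ = np.histogram(arr, bins=edges)
    total = counts.sum()
    fractions = counts / total if total else counts.astype(float)
    return counts, fractions
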