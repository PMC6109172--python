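"""Synaptic-vesicle (SypHy) fusion analysis.

Synapses are identified as non-mobile puncta whose dF/F0 during NH4+
superfusion exceeds 3 standard deviations of the baseline; responsive vs
silent classification, the fusion fraction (peak stimulation response over
the NH4+ response) and the half-decay time of the stimulation response are
computed per synapse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ClippedRoiError, ProtocolError
from .imaging import (
    MovieStack, Roi, Trace, compute_dff, detect_puncta, extract_trace,
    is_mobile, make_roi, max_projection,
)

__all__ = [
    "SynapseRecord",
    "identify_synapses",
    "classify_responsive",
    "fusion_fraction",
    "half_decay_time",
    "percent_silent",
    "records_to_frame",
]

_SD_FLOOR = np.finfo(float).eps


@dataclass
class SynapseRecord:
    """Per-synapse measurements from one SypHy recording."""

    roi: Roi
    trace: Trace
    baseline_sd: float
    nh4_peak_dff: float
    hfs_peak_dff: float
    responsive: bool
    fusion_fraction: float = math.nan
    half_decay_s: float = math.nan
    half_decay_censored: bool = False


def _window_peak(trace: Trace, window: tuple[float, float]) -> tuple[float, int]:
    i0 = max(0, int(np.ceil(window[0] / trace.dt - 1e-9)))
    i1 = min(len(trace.values), int(np.ceil(window[1] / trace.dt - 1e-9)))
    if i1 <= i0:
        raise AnalysisError(f"window {window} outside trace")
    seg = trace.dff[i0:i1]
    k = int(np.argmax(seg))
    return float(seg[k]), i0 + k


def baseline_sd(trace: Trace, f0_seconds: float = 10.0) -> float:
    """SD of the dF/F0 samples over the F0 (first 10 s) window."""
    n0 = max(1, int(round(f0_seconds / trace.dt)))
    return float(np.std(trace.dff[:n0]))


def classify_responsive(trace: Trace, hfs_window: tuple[float, float],
                        sd: float | None = None, criterion_sd: float = 3.0) -> bool:
    """True iff the peak dF/F0 inside the stimulation window exceeds
    ``criterion_sd`` baseline standard deviations (SD floored at machine
    epsilon, so any positive deflection of a noise-free trace counts)."""
    if sd is None:
        sd = baseline_sd(trace)
    peak, _ = _window_peak(trace, hfs_window)
    return bool(peak > criterion_sd * max(sd, _SD_FLOOR))


def fusion_fraction(record: SynapseRecord) -> float:
    """Peak stimulation dF/F0 over peak NH4+ dF/F0."""
    if record.nh4_peak_dff <= 0:
        raise AnalysisError("NH4+ response must be positive")
    return record.hfs_peak_dff / record.nh4_peak_dff


def half_decay_time(trace: Trace, hfs_window: tuple[float, float]
                    ) -> tuple[float, bool]:
    """Time for the stimulation response to fall to half its peak.

    Measured from the dF/F0 peak inside the stimulation window until the
    trace first reaches half the peak-above-baseline level (baseline
    dF/F0 = 0), linearly interpolated between the bracketing frames.
    Returns ``(seconds, censored)``; censored means the trace never decays
    to half within the recording (the time is then NaN).
    """
    peak, peak_idx = _window_peak(trace, hfs_window)
    if peak <= 0:
        return math.nan, True
    half = peak / 2.0
    post = trace.dff[peak_idx:]
    below = np.flatnonzero(post <= half)
    if len(below) == 0:
        return math.nan, True
    k = int(below[0])
    if k == 0:
        return 0.0, False
    y0, y1 = post[k - 1], post[k]
    frac = (y0 - half) / (y0 - y1) if y1 != y0 else 1.0
    return float((k - 1 + frac) * trace.dt), False


def identify_synapses(stack: MovieStack, roi_size: int = 4,
                      criterion_sd: float = 3.0,
                      mobility_threshold_px: float = 2.0,
                      hfs_peak_margin_s: float = 2.0,
                      detect_kwargs: dict | None = None) -> list[SynapseRecord]:
    """Find synapses in a SypHy movie and measure each.

    Puncta are detected on the NH4+ maximum projection; each gets a square
    ROI (4x4 by default), a dF/F0 trace, and is kept when it is non-mobile
    at baseline and its NH4+ peak dF/F0 exceeds ``criterion_sd`` baseline
    SDs. Puncta whose ROI would cross the border are skipped.
    """
    protocol = stack.protocol
    if protocol.nh4_window is None:
        raise ProtocolError("SypHy analysis needs an NH4+ window")
    if protocol.hfs_window is None:
        raise ProtocolError("SypHy analysis needs stimulation onsets")
    # the stimulation response peaks at the end of the train; measure its
    # maximum over the train plus a short margin — a window running all
    # the way to NH4+ would let the maximum of hundreds of noise frames
    # defeat the 3-SD criterion
    hfs = (protocol.hfs_window[0],
           min(protocol.hfs_window[1] + hfs_peak_margin_s,
               protocol.nh4_window[0]))

    projection = max_projection(stack, protocol.nh4_window)
    detections = detect_puncta(projection, **(detect_kwargs or {}))
    records: list[SynapseRecord] = []
    for det in detections:
        try:
            roi = make_roi(det, roi_size, frame_shape=stack.frame_shape)
        except ClippedRoiError:
            continue
        trace = compute_dff(extract_trace(stack, roi))
        sd = baseline_sd(trace)
        nh4_peak, _ = _window_peak(trace, protocol.nh4_window)
        if nh4_peak <= criterion_sd * max(sd, _SD_FLOOR):
            continue
        mobile = is_mobile(stack, roi, max_displacement_px=mobility_threshold_px)
        if mobile:          # True, or None (indeterminate) stays included
            continue
        hfs_peak, _ = _window_peak(trace, hfs)
        responsive = classify_responsive(trace, hfs, sd=sd, criterion_sd=criterion_sd)
        rec = SynapseRecord(roi=roi, trace=trace, baseline_sd=sd,
                            nh4_peak_dff=nh4_peak, hfs_peak_dff=hfs_peak,
                            responsive=responsive)
        if responsive:
            rec.fusion_fraction = fusion_fraction(rec)
            rec.half_decay_s, rec.half_decay_censored = half_decay_time(trace, hfs)
        records.append(rec)
    if not records:
        warnings.warn("no NH4+-responsive puncta found", stacklevel=2)
    return records


def percent_silent(records: list[SynapseRecord]) -> float:
    """Percentage of identified synapses with no supra-threshold
    stimulation response."""
    if not records:
        raise AnalysisError("no synapse records")
    silent = sum(1 for r in records if not r.responsive)
    return 100.0 * silent / len(records)


def records_to_frame(records: list[SynapseRecord]) -> pd.DataFrame:
    """Tidy per-synapse table (one row per synapse)."""
    rows = [{
        "row": r.roi.center[0], "col": r.roi.center[1],
        "responsive": r.responsive, "nh4_peak_dff": r.nh4_peak_dff,
        "hfs_peak_dff": r.hfs_peak_dff, "fusion_fraction": r.fusion_fraction,
        "half_decay_s": r.half_decay_s, "half_decay_censored": r.half_decay_censored,
    } for r in records]
    return pd.DataFrame(rows)
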