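"""Whole-cell voltage-clamp secretion metrics.

Works on sampled current sweeps (pA) held in :class:`EphysSweep`:
evoked charge transfer, miniature-EPSC detection, the readily releasable
pool (RRP) as total charge during hypertonic sucrose, release probability
and the paired-pulse ratio. Sweeps travel as two-column delimited text
(time_s, current_pA); no proprietary acquisition formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import AnalysisError

__all__ = [
    "EphysSweep",
    "MiniEvent",
    "read_sweep",
    "write_sweep",
    "evoked_charge",
    "detect_minis",
    "rrp_charge",
    "release_probability",
    "paired_pulse_ratio",
]


@dataclass
class EphysSweep:
    """A uniformly sampled current trace with stimulus annotations.

    ``current`` is in pA (inward currents negative), ``fs`` the sampling
    rate in Hz, ``stim_times`` the stimulation times in seconds and
    ``sucrose_window`` the half-open application window of hypertonic
    sucrose, when present.
    """

    current: np.ndarray
    fs: float
    stim_times: tuple[float, ...] = ()
    sucrose_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.fs <= 0:
            raise AnalysisError("sampling rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration_s(self) -> float:
        return len(self.current) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.current)) / self.fs

    def sample_range(self, window: tuple[float, float]) -> tuple[int, int]:
        i0 = max(0, int(np.ceil(window[0] * self.fs - 1e-9)))
        i1 = min(len(self.current), int(np.ceil(window[1] * self.fs - 1e-9)))
        if i1 <= i0:
            raise AnalysisError(f"window {window} outside sweep")
        return i0, i1


@dataclass(frozen=True)
class MiniEvent:
    """One detected spontaneous (miniature) synaptic current."""

    onset_s: float
    amplitude_pa: float
    charge_pc: float


def write_sweep(path: str | Path, sweep: EphysSweep) -> None:
    header = f"time_s\tcurrent_pA\t# fs={sweep.fs}"
    np.savetxt(str(path), np.column_stack([sweep.times, sweep.current]),
               delimiter="\t", header=header, comments="")


def read_sweep(path: str | Path, stim_times: tuple[float, ...] = (),
               sucrose_window: tuple[float, float] | None = None) -> EphysSweep:
    arr = np.loadtxt(str(path), delimiter="\t", skiprows=1)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise AnalysisError(f"{path}: expected two columns (time_s, current_pA)")
    t, i = arr[:, 0], arr[:, 1]
    dts = np.diff(t)
    if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=1e-4, atol=1e-9):
        raise AnalysisError(f"{path}: non-uniform sampling")
    return EphysSweep(current=i, fs=1.0 / float(dts[0]), stim_times=stim_times,
                      sucrose_window=sucrose_window)


# --------------------------------------------------------------------------
# charge metrics
# --------------------------------------------------------------------------

def _baseline(sweep: EphysSweep, before_s: float, span_s: float = 0.05) -> float:
    """Median current over ``span_s`` immediately before ``before_s``."""
    i1 = int(round(before_s * sweep.fs))
    i0 = max(0, i1 - int(round(span_s * sweep.fs)))
    if i1 <= i0:
        return float(np.median(sweep.current[: max(1, int(0.05 * sweep.fs))]))
    return float(np.median(sweep.current[i0:i1]))


def _blank_artifacts(current: np.ndarray, fs: float,
                     stim_times: tuple[float, ...], half_ms: float = 1.0) -> np.ndarray:
    """Replace +-half_ms around each stimulus by linear interpolation."""
    out = current.copy()
    half = int(round(half_ms * 1e-3 * fs))
    for t in stim_times:
        k = int(round(t * fs))
        a, b = max(0, k - half), min(len(out) - 1, k + half)
        if b > a:
            out[a:b + 1] = np.linspace(out[a], out[b], b - a + 1)
    return out


def evoked_charge(sweep: EphysSweep, window_s: tuple[float, float] | None = None) -> float:
    """|integral of (I - baseline) dt| over the response window, in pC.

    Baseline is the median of the 50 ms preceding the first stimulus;
    stimulus artifacts (+-1 ms around each stimulus) are blanked by linear
    interpolation before integrating. The default window runs 500 ms from
    the first stimulus.
    """
    if window_s is None:
        if not sweep.stim_times:
            raise AnalysisError("no stimulus time and no explicit window")
        window_s = (sweep.stim_times[0], sweep.stim_times[0] + 0.5)
    i0, i1 = sweep.sample_range(window_s)
    ref = sweep.stim_times[0] if sweep.stim_times else window_s[0]
    base = _baseline(sweep, ref)
    current = _blank_artifacts(sweep.current, sweep.fs, sweep.stim_times)
    # pA * s = pC; left-Riemann sum is exact for rectangular test currents
    return float(abs(np.sum(current[i0:i1] - base) * sweep.dt))


def rrp_charge(sweep: EphysSweep) -> float:
    """Readily releasable pool as total sucrose-induced charge transfer (nC)."""
    if sweep.sucrose_window is None:
        raise AnalysisError("sweep has no sucrose application window")
    i0, i1 = sweep.sample_range(sweep.sucrose_window)
    base = _baseline(sweep, sweep.sucrose_window[0], span_s=0.5)
    pc = abs(np.sum(sweep.current[i0:i1] - base) * sweep.dt)
    return float(pc / 1000.0)


def release_probability(evoked_pc: float, rrp_nc: float) -> float:
    """Single-stimulus release probability: evoked charge over RRP, in %."""
    if rrp_nc <= 0:
        raise AnalysisError("RRP charge must be positive")
    return 100.0 * evoked_pc / (rrp_nc * 1000.0)


# --------------------------------------------------------------------------
# minis
# --------------------------------------------------------------------------

def detect_minis(sweep: EphysSweep, k: float = 4.0, lowpass_hz: float = 500.0,
                 min_interval_s: float = 0.003) -> tuple[list[MiniEvent], float]:
    """Detect spontaneous inward events by filtered threshold crossing.

    The trace is low-pass filtered (zero-phase Butterworth), the noise SD
    estimated robustly (1.4826 x MAD), and contiguous excursions below
    ``median - k x SD`` separated by more than ``min_interval_s`` become
    events. Amplitude is measured on the raw trace (baseline-referenced
    peak); charge is the integral from onset until the filtered trace
    returns to baseline. Returns ``(events, frequency_hz)``.
    """
    if sweep.stim_times:
        raise AnalysisError("mini detection requires an unstimulated segment")
    nyq = sweep.fs / 2.0
    if lowpass_hz < nyq:
        sos = signal.butter(4, lowpass_hz / nyq, output="sos")
        filt = signal.sosfiltfilt(sos, sweep.current)
    else:
        filt = sweep.current
    base = float(np.median(filt))
    sd = float(1.4826 * np.median(np.abs(filt - base)))
    thr = base - k * max(sd, 1e-12)

    below = filt < thr
    if not below.any():
        return [], 0.0
    idx = np.flatnonzero(below)
    gaps = np.flatnonzero(np.diff(idx) > int(min_interval_s * sweep.fs))
    region_starts = np.concatenate([[idx[0]], idx[gaps + 1]])
    region_ends = np.concatenate([idx[gaps], [idx[-1]]])

    events: list[MiniEvent] = []
    for s, e in zip(region_starts, region_ends):
        peak_idx = s + int(np.argmin(sweep.current[s:e + 1]))
        amplitude = base - float(sweep.current[peak_idx])
        # integrate until the filtered trace recovers to baseline
        tail = np.flatnonzero(filt[peak_idx:] >= base)
        end = peak_idx + (int(tail[0]) if len(tail) else len(filt) - peak_idx - 1)
        charge = float(-(np.sum(filt[s:end + 1] - base)) * sweep.dt)
        events.append(MiniEvent(onset_s=float(s / sweep.fs),
                                amplitude_pa=amplitude, charge_pc=max(charge, 0.0)))
    frequency = len(events) / sweep.duration_s
    return events, float(frequency)


def paired_pulse_ratio(sweep: EphysSweep, response_window_s: float = 0.03) -> float:
    """Amplitude of the second evoked response over the first.

    Each amplitude is the baseline-referenced peak inward deflection within
    ``response_window_s`` after its stimulus; artifacts are blanked first.
    """
    if len(sweep.stim_times) < 2:
        raise AnalysisError("paired-pulse ratio needs two stimulus times")
    current = _blank_artifacts(sweep.current, sweep.fs, sweep.stim_times)
    amps = []
    for t in sweep.stim_times[:2]:
        base = _baseline(sweep, t, span_s=0.005)
        i0, i1 = sweep.sample_range((t, t + response_window_s))
        amps.append(base - float(current[i0:i1].min()))
    if amps[0] <= 0:
        raise AnalysisError("no measurable first response")
    return float(amps[1] / amps[0])
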