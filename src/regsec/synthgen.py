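"""Synthetic ground-truth data for every quantification stage.

The generator emulates the statistical structure the analyses assume:

* quenched pHluorin puncta that dequench (step + exponential decay) at
  stimulation-train onsets, with an NH4+ superfusion window in which each
  punctum reports its full vesicle content (vesicle count x unit quantum);
* non-mobile synaptic-vesicle puncta whose stimulation response is a set
  fraction of the NH4+ amplitude, plus "silent" puncta responding only
  to NH4+;
* moving puncta crossing a photobleached axon segment at set speeds;
* static neuron images (skeleton of known length, puncta at known density,
  labeled Golgi/soma regions of known mean intensity);
* current sweeps (evoked, minis, sucrose, paired pulse) with analytic
  charge logged.

Noise model: optional Poisson shot noise on the clean signal plus additive
Gaussian read noise; photobleaching as a global mono-exponential. Every
simulation is driven by one ``numpy`` Generator seeded from the config, so
identical configs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import MovieStack, StimulusProtocol
from .ephys import EphysSweep
from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "StaticNeuronConfig",
    "GroundTruthLog",
    "default_dcv_config",
    "default_sv_config",
    "simulate_dcv_movie",
    "simulate_sv_movie",
    "simulate_flux_movie",
    "simulate_ephys_sweep",
    "simulate_static_neuron",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _default_vesicle_dist() -> dict[int, float]:
    # stand-in categorical with decreasing mass; the real per-punctum
    # vesicle distribution is unknown and fully configurable
    return {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.1}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic fluorescence time-lapse.

    Defaults describe a 2 Hz, 64x64 px recording with diffraction-limited
    puncta (Gaussian PSF, sigma 1.5 px), a unit single-vesicle intensity
    ``quantum`` and a constant camera offset ``baseline_offset`` that keeps
    F0 positive (pHluorin is quenched at rest).
    """

    image_shape: tuple[int, int] = (64, 64)
    n_frames: int = 600
    dt: float = 0.5                       # s/frame (2 Hz)
    pixel_size: float = 0.2               # um/px
    psf_sigma: float = 1.5                # px
    n_puncta: int = 20      # random placement at 8 px separation caps near 25 on 64x64
    quantum: float = 100.0                # AU per vesicle
    vesicles_per_punctum_dist: dict[int, float] = field(default_factory=_default_vesicle_dist)
    fusion_probability: float = 0.05      # fraction of the pool fusing during HFS
    event_decay_tau: float = 4.0          # s
    stim_onsets: tuple[float, ...] = tuple(30.0 + 2.0 * k for k in range(16))
    aps_per_train: int = 50
    train_freq: float = 50.0
    nh4_window: tuple[float, float] | None = (240.0, 270.0)
    hfs_fraction: float = 0.25            # SV movies: HFS amplitude / NH4 amplitude
    fraction_silent: float = 0.0          # SV movies: puncta with no HFS response
    baseline_offset: float = 100.0        # AU camera offset
    noise_gaussian_sd: float = 0.0        # AU
    noise_poisson: bool = False
    bleach_rate: float = 0.0              # 1/s
    min_separation_px: float = 8.0
    margin_px: int = 8
    train_weights: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(train_onsets=self.stim_onsets,
                                aps_per_train=self.aps_per_train,
                                train_freq=self.train_freq,
                                nh4_window=self.nh4_window)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0 or self.n_frames < 2:
            raise InvalidConfigError("non-positive image dimensions or too few frames")
        if self.dt <= 0:
            raise InvalidConfigError("dt must be positive")
        if self.quantum <= 0:
            raise InvalidConfigError("quantum must be positive")
        if not 0.0 <= self.fusion_probability <= 1.0:
            raise InvalidConfigError("fusion_probability must be in [0, 1]")
        if not 0.0 <= self.fraction_silent <= 1.0:
            raise InvalidConfigError("fraction_silent must be in [0, 1]")
        probs = np.array(list(self.vesicles_per_punctum_dist.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise InvalidConfigError("vesicle distribution must be a probability mass")
        if any(int(k) < 1 for k in self.vesicles_per_punctum_dist):
            raise InvalidConfigError("vesicle counts must be >= 1")
        if self.nh4_window is not None:
            lo, hi = self.nh4_window
            if not lo < hi:
                raise InvalidConfigError("empty nh4_window")
            if hi > self.duration_s + 1e-9:
                raise InvalidConfigError("nh4_window beyond end of recording")
            if self.stim_onsets:
                train_end = self.stim_onsets[-1] + self.aps_per_train / max(self.train_freq, 1e-9)
                if lo < train_end:
                    raise InvalidConfigError("nh4_window must follow the last stimulation train")


def default_dcv_config(**overrides) -> SimulationConfig:
    """Dense-core vesicle fusion protocol: 16 trains of 50 APs at 50 Hz,
    2 Hz acquisition, NH4+ superfusion late in the recording."""
    return replace(SimulationConfig(), **overrides)


def default_sv_config(**overrides) -> SimulationConfig:
    """Synaptic-vesicle fusion protocol: one train of 100 APs at 40 Hz,
    slower post-stimulus decay (endocytosis/re-acidification, tau 30 s)."""
    cfg = SimulationConfig(
        n_frames=360, stim_onsets=(30.0,), aps_per_train=100, train_freq=40.0,
        nh4_window=(120.0, 150.0), event_decay_tau=30.0, n_puncta=12,
        # spots truncate at 4*psf_sigma = 6 px; this separation keeps a
        # punctum's tail fully out of its neighbors' ROIs
        min_separation_px=12.0,
    )
    return replace(cfg, **overrides)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruthLog:
    """Everything a simulation knows about itself.

    ``puncta``/``events``/``tracks`` are tidy DataFrames (one row per
    punctum/fusion event/moving particle); ``region_means`` maps labeled
    regions to their true mean intensity; ``scalars`` holds totals such as
    the true vesicle pool or an analytic charge.
    """

    puncta: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    tracks: pd.DataFrame = field(default_factory=pd.DataFrame)
    region_means: dict[str, float] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)

    @property
    def pool_vesicles(self) -> int:
        return int(self.scalars.get("pool_vesicles", 0))

    def validate(self) -> None:
        if len(self.puncta) and self.pool_vesicles < len(self.puncta):
            raise InvalidConfigError("pool smaller than the number of puncta")
        if len(self.events) and len(self.puncta):
            if not set(self.events["punctum_id"]).issubset(set(self.puncta["id"])):
                raise InvalidConfigError("event references a non-existent punctum")

    def to_csv(self, outdir: str | Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("puncta", "events", "tracks"):
            frame = getattr(self, name)
            if len(frame):
                frame.to_csv(outdir / f"{prefix}_{name}.csv", index=False)
        extras = dict(self.scalars)
        extras.update({f"region_mean_{k}": v for k, v in self.region_means.items()})
        if extras:
            pd.DataFrame([extras]).to_csv(outdir / f"{prefix}_scalars.csv", index=False)


# --------------------------------------------------------------------------
# rendering helpers
# --------------------------------------------------------------------------

def _place_puncta(rng: np.random.Generator, shape: tuple[int, int], n: int,
                  min_sep: float, margin: int) -> np.ndarray:
    """Integer punctum positions with a hard minimum separation."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise InvalidConfigError("image too small for the placement margin")
    rows = np.empty(n, dtype=np.int64)
    cols = np.empty(n, dtype=np.int64)
    placed = 0
    for _ in range(500 * n + 1000):
        if placed == n:
            break
        r = rng.integers(margin, h - margin)
        c = rng.integers(margin, w - margin)
        if placed:
            d2 = (rows[:placed] - r) ** 2 + (cols[:placed] - c) ** 2
            if (d2 < min_sep ** 2).any():
                continue
        rows[placed], cols[placed] = r, c
        placed += 1
    if placed < n:
        raise InvalidConfigError(
            f"cannot place {n} puncta at separation {min_sep} px in {shape}"
        )
    return np.column_stack([rows, cols])


def _spot_patch(sigma: float, radius: int | None = None) -> np.ndarray:
    if radius is None:
        radius = int(np.ceil(4 * sigma))
    x = np.arange(-radius, radius + 1)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return np.outer(g, g)           # unit peak at the center pixel


def _add_timecourse_spot(stack: np.ndarray, amp_t: np.ndarray,
                         row: int, col: int, kernel: np.ndarray) -> None:
    radius = kernel.shape[0] // 2
    h, w = stack.shape[1:]
    r0, r1 = max(0, row - radius), min(h, row + radius + 1)
    c0, c1 = max(0, col - radius), min(w, col + radius + 1)
    k = kernel[r0 - row + radius: r1 - row + radius,
               c0 - col + radius: c1 - col + radius]
    stack[:, r0:r1, c0:c1] += amp_t[:, None, None] * k


def _render_moving_spot(frame: np.ndarray, row: float, col: float,
                        amplitude: float, sigma: float) -> None:
    radius = int(np.ceil(4 * sigma))
    h, w = frame.shape
    r0, r1 = max(0, int(row) - radius), min(h, int(row) + radius + 2)
    c0, c1 = max(0, int(col) - radius), min(w, int(col) + radius + 2)
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    frame[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma ** 2))


def _apply_noise(clean: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = clean
    if config.noise_poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if config.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, config.noise_gaussian_sd, size=out.shape)
    return out


def _bleach_factor(config: SimulationConfig) -> np.ndarray:
    t = np.arange(config.n_frames) * config.dt
    return np.exp(-config.bleach_rate * t)


# --------------------------------------------------------------------------
# DCV fusion movies
# --------------------------------------------------------------------------

def simulate_dcv_movie(config: SimulationConfig) -> tuple[MovieStack, GroundTruthLog]:
    """Quenched puncta; a known subset dequenches at train onsets and the
    NH4+ window reveals every punctum at its full vesicle content.

    The number of fusion events is ``round(fusion_probability x pool)``
    (capped at one event per punctum, assigned to distinct puncta), so the
    ground-truth fusion probability is exact up to rounding.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = _place_puncta(rng, config.image_shape, config.n_puncta,
                              config.min_separation_px, config.margin_px)
    ks = np.array(sorted(config.vesicles_per_punctum_dist), dtype=np.int64)
    pk = np.array([config.vesicles_per_punctum_dist[int(k)] for k in ks])
    counts = rng.choice(ks, p=pk / pk.sum(), size=config.n_puncta)
    pool = int(counts.sum())

    n_events = int(round(config.fusion_probability * pool))
    n_events = min(n_events, config.n_puncta)
    event_ids = np.sort(rng.choice(config.n_puncta, size=n_events, replace=False))

    n_trains = len(config.stim_onsets)
    if n_events and n_trains == 0:
        raise InvalidConfigError("fusion events require stimulation trains")
    if config.train_weights is not None:
        tw = np.asarray(config.train_weights, dtype=float)
        if len(tw) != n_trains:
            raise InvalidConfigError("train_weights length mismatch")
        tw = tw / tw.sum()
    else:
        tw = np.full(n_trains, 1.0 / n_trains) if n_trains else None

    train_dur = config.aps_per_train / max(config.train_freq, 1e-9)
    times = np.arange(config.n_frames) * config.dt
    bleach = _bleach_factor(config)
    nh4 = config.nh4_window
    nh4_mask = (times >= nh4[0]) & (times < nh4[1]) if nh4 is not None else None

    stack = np.full((config.n_frames, *config.image_shape),
                    config.baseline_offset, dtype=np.float64)
    kernel = _spot_patch(config.psf_sigma)

    event_rows = []
    for pid in event_ids:
        tr = int(rng.choice(n_trains, p=tw))
        onset_t = config.stim_onsets[tr] + rng.uniform(0.0, max(train_dur, config.dt))
        onset_frame = int(round(onset_t / config.dt))
        onset_frame = min(onset_frame, config.n_frames - 1)
        event_rows.append({"punctum_id": int(pid), "onset_frame": onset_frame,
                           "onset_s": onset_frame * config.dt, "train_index": tr,
                           "row": int(positions[pid, 0]), "col": int(positions[pid, 1]),
                           "amplitude": config.quantum})

    event_by_punctum = {e["punctum_id"]: e for e in event_rows}
    for pid in range(config.n_puncta):
        amp = np.zeros(config.n_frames)
        ev = event_by_punctum.get(pid)
        if ev is not None:
            f0 = ev["onset_frame"]
            amp[f0:] = config.quantum * np.exp(-(times[f0:] - times[f0])
                                               / config.event_decay_tau)
        if nh4_mask is not None:
            amp[nh4_mask] = counts[pid] * config.quantum
        amp *= bleach
        _add_timecourse_spot(stack, amp, int(positions[pid, 0]),
                             int(positions[pid, 1]), kernel)

    data = _apply_noise(stack, config, rng)
    movie = MovieStack(data, dt=config.dt, pixel_size=config.pixel_size,
                       protocol=config.protocol)
    log = GroundTruthLog(
        puncta=pd.DataFrame({"id": np.arange(config.n_puncta),
                             "row": positions[:, 0], "col": positions[:, 1],
                             "vesicles": counts,
                             "nh4_amplitude": counts * config.quantum}),
        events=pd.DataFrame(event_rows,
                            columns=["punctum_id", "onset_frame", "onset_s",
                                     "train_index", "row", "col", "amplitude"]),
        scalars={"pool_vesicles": pool, "n_events": n_events,
                 "fusion_probability_pct": 100.0 * n_events / pool if pool else 0.0,
                 "quantum": config.quantum},
    )
    log.validate()
    return movie, log


# --------------------------------------------------------------------------
# SV (SypHy) movies
# --------------------------------------------------------------------------

def simulate_sv_movie(config: SimulationConfig) -> tuple[MovieStack, GroundTruthLog]:
    """Non-mobile synaptic puncta.

    Responsive puncta ramp up during the stimulation window to
    ``hfs_fraction`` of their NH4+ amplitude and then decay exponentially;
    silent puncta (``round(fraction_silent x n_puncta)`` of them, chosen at
    random) respond only to NH4+.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if not config.stim_onsets:
        raise InvalidConfigError("SV movies need a stimulation train")
    positions = _place_puncta(rng, config.image_shape, config.n_puncta,
                              config.min_separation_px, config.margin_px)
    ks = np.array(sorted(config.vesicles_per_punctum_dist), dtype=np.int64)
    pk = np.array([config.vesicles_per_punctum_dist[int(k)] for k in ks])
    counts = rng.choice(ks, p=pk / pk.sum(), size=config.n_puncta)

    n_silent = int(round(config.fraction_silent * config.n_puncta))
    silent = np.zeros(config.n_puncta, dtype=bool)
    silent[rng.choice(config.n_puncta, size=n_silent, replace=False)] = True

    hfs_start = config.stim_onsets[0]
    hfs_end = config.stim_onsets[-1] + config.aps_per_train / max(config.train_freq, 1e-9)
    times = np.arange(config.n_frames) * config.dt
    bleach = _bleach_factor(config)
    nh4 = config.nh4_window
    nh4_mask = (times >= nh4[0]) & (times < nh4[1]) if nh4 is not None else None

    stack = np.full((config.n_frames, *config.image_shape),
                    config.baseline_offset, dtype=np.float64)
    kernel = _spot_patch(config.psf_sigma)
    for pid in range(config.n_puncta):
        a_nh4 = counts[pid] * config.quantum
        amp = np.zeros(config.n_frames)
        if not silent[pid]:
            peak = config.hfs_fraction * a_nh4
            rise = (times >= hfs_start) & (times < hfs_end)
            amp[rise] = peak * (times[rise] - hfs_start) / (hfs_end - hfs_start)
            after = times >= hfs_end
            amp[after] = peak * np.exp(-(times[after] - hfs_end) / config.event_decay_tau)
        if nh4_mask is not None:
            amp[nh4_mask] = a_nh4
        amp *= bleach
        _add_timecourse_spot(stack, amp, int(positions[pid, 0]),
                             int(positions[pid, 1]), kernel)

    data = _apply_noise(stack, config, rng)
    movie = MovieStack(data, dt=config.dt, pixel_size=config.pixel_size,
                       protocol=config.protocol)
    log = GroundTruthLog(
        puncta=pd.DataFrame({"id": np.arange(config.n_puncta),
                             "row": positions[:, 0], "col": positions[:, 1],
                             "vesicles": counts,
                             "nh4_amplitude": counts * config.quantum,
                             "responsive": ~silent,
                             "fusion_fraction": np.where(silent, 0.0, config.hfs_fraction)}),
        scalars={"pool_vesicles": int(counts.sum()),
                 "fraction_silent": n_silent / config.n_puncta if config.n_puncta else 0.0,
                 "half_decay_s": config.event_decay_tau * np.log(2.0)},
    )
    log.validate()
    return movie, log


# --------------------------------------------------------------------------
# axonal flux (FRAP) movies
# --------------------------------------------------------------------------

def simulate_flux_movie(config: SimulationConfig, speeds_um_s: list[float],
                        entry_times_s: list[float]) -> tuple[MovieStack, GroundTruthLog]:
    """Bright puncta crossing a photobleached axon segment.

    The axon runs horizontally through the frame center; the bleached
    segment spans the columns inside ``margin_px``. Each punctum enters the
    segment at its entry time on the soma side (left end) and translates
    rightward at its speed.
    """
    config.validate()
    if len(speeds_um_s) != len(entry_times_s):
        raise InvalidConfigError("speeds and entry_times must have the same length")
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    row = h // 2
    x_start, x_end = config.margin_px, w - config.margin_px
    duration = config.duration_s
    for t_entry in entry_times_s:
        if t_entry < 0 or t_entry >= duration:
            raise InvalidConfigError(
                f"entry time {t_entry} s outside the {duration} s recording")

    axon_level = 0.5 * config.quantum
    base = np.full((h, w), config.baseline_offset, dtype=np.float64)
    base[row - 1: row + 2, :x_start] += axon_level     # unbleached axon ends
    base[row - 1: row + 2, x_end:] += axon_level
    stack = np.repeat(base[None], config.n_frames, axis=0)

    track_rows = []
    for tid, (v, t_entry) in enumerate(zip(speeds_um_s, entry_times_s)):
        v_px = v / config.pixel_size * config.dt       # px/frame
        entry_frame = int(np.ceil(t_entry / config.dt - 1e-9))
        for f in range(entry_frame, config.n_frames):
            x = x_start + v_px * (f - entry_frame)
            if x > x_end:
                # past the bleached segment the punctum merges with the
                # bright unbleached axon and is no longer distinguishable
                break
            _render_moving_spot(stack[f], row, x, config.quantum, config.psf_sigma)
        track_rows.append({"track_id": tid, "speed_um_s": v,
                           "entry_time_s": entry_frame * config.dt,
                           "row": row, "col_start": x_start,
                           "px_per_frame": v_px})

    data = _apply_noise(stack, config, rng)
    movie = MovieStack(data, dt=config.dt, pixel_size=config.pixel_size,
                       protocol=StimulusProtocol())
    log = GroundTruthLog(
        tracks=pd.DataFrame(track_rows, columns=["track_id", "speed_um_s",
                                                 "entry_time_s", "row",
                                                 "col_start", "px_per_frame"]),
        scalars={"flux_per_min": 60.0 * len(track_rows) / duration,
                 "bleach_start_col": x_start, "bleach_end_col": x_end,
                 "axon_row": row},
    )
    return movie, log


# --------------------------------------------------------------------------
# electrophysiology sweeps
# --------------------------------------------------------------------------

def simulate_ephys_sweep(kind: str, *, seed: int = 0, fs: float = 10_000.0,
                         duration_s: float | None = None, noise_sd_pa: float = 0.0,
                         **params) -> tuple[EphysSweep, GroundTruthLog]:
    """Synthetic voltage-clamp sweep of one of four kinds.

    ``evoked``
        one stimulus-locked exponential transient (``stim_time``,
        ``amplitude_pa``, ``tau_s``); the analytic charge is logged.
    ``minis``
        Poisson-timed inward events (``rate_hz``, ``amplitude_pa``,
        ``tau_s``); onsets and count are logged.
    ``sucrose``
        sustained inward current over ``window`` — rectangular
        (``amplitude_pa``) or bi-exponential (``amps_pa``, ``taus_s``) —
        with its analytic integral logged in nC.
    ``paired_pulse``
        two transients at ``stim_times`` with amplitude ratio ``ratio``.
    """
    if fs <= 0:
        raise InvalidConfigError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    scalars: dict[str, float] = {}
    events = pd.DataFrame()

    if kind == "evoked":
        duration_s = duration_s or 1.0
        stim_time = float(params.pop("stim_time", 0.1))
        amp = float(params.pop("amplitude_pa", 500.0))
        tau = float(params.pop("tau_s", 0.01))
        delay = float(params.pop("delay_s", 0.0015))   # synaptic delay
        t = np.arange(int(round(duration_s * fs))) / fs
        current = np.zeros_like(t)
        onset = stim_time + delay
        m = t >= onset
        current[m] = -amp * np.exp(-(t[m] - onset) / tau)
        true_pc = amp * tau * (1.0 - np.exp(-(duration_s - onset) / tau))
        scalars["true_charge_pc"] = true_pc
        sweep = EphysSweep(current, fs=fs, stim_times=(stim_time,))

    elif kind == "minis":
        duration_s = duration_s or 60.0
        rate = float(params.pop("rate_hz", 5.0))
        amp = float(params.pop("amplitude_pa", 30.0))
        tau = float(params.pop("tau_s", 0.003))
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        current = np.zeros(n)
        onsets = []
        t_next = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        while t_next < duration_s:
            k = int(round(t_next * fs))
            span = min(n - k, int(round(8 * tau * fs)))
            current[k:k + span] += -amp * np.exp(-np.arange(span) / (tau * fs))
            onsets.append(k / fs)
            t_next += rng.exponential(1.0 / rate)
        events = pd.DataFrame({"onset_s": onsets,
                               "amplitude_pa": amp, "charge_pc": amp * tau})
        scalars.update({"n_events": len(onsets), "rate_hz": rate,
                        "true_frequency_hz": len(onsets) / duration_s})
        sweep = EphysSweep(current, fs=fs)

    elif kind == "sucrose":
        window = tuple(params.pop("window", (1.0, 6.0)))
        duration_s = duration_s or (window[1] + 1.0)
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        current = np.zeros(n)
        m = (t >= window[0]) & (t < window[1])
        shape = params.pop("shape", "rect")
        if shape == "rect":
            amp = float(params.pop("amplitude_pa", 100.0))
            current[m] = -amp
            true_nc = amp * (window[1] - window[0]) / 1000.0
        elif shape == "biexp":
            amps = params.pop("amps_pa", (400.0, 100.0))
            taus = params.pop("taus_s", (0.5, 2.0))
            rel = t[m] - window[0]
            current[m] = -sum(a * np.exp(-rel / tau) for a, tau in zip(amps, taus))
            dur = window[1] - window[0]
            true_nc = sum(a * tau * (1.0 - np.exp(-dur / tau))
                          for a, tau in zip(amps, taus)) / 1000.0
        else:
            raise InvalidConfigError(f"unknown sucrose shape {shape!r}")
        scalars["true_charge_nc"] = true_nc
        sweep = EphysSweep(current, fs=fs, sucrose_window=window)

    elif kind == "paired_pulse":
        duration_s = duration_s or 0.5
        stim_times = tuple(params.pop("stim_times", (0.1, 0.15)))
        amp = float(params.pop("amplitude_pa", 300.0))
        ratio = float(params.pop("ratio", 1.0))
        tau = float(params.pop("tau_s", 0.005))
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        current = np.zeros(n)
        for stim, a in zip(stim_times, (amp, amp * ratio)):
            m = t >= stim
            current[m] += -a * np.exp(-(t[m] - stim) / tau)
        scalars.update({"amplitude_1_pa": amp, "amplitude_2_pa": amp * ratio,
                        "true_ratio": ratio})
        sweep = EphysSweep(current, fs=fs, stim_times=stim_times)

    else:
        raise InvalidConfigError(f"unknown sweep kind {kind!r}")

    if noise_sd_pa > 0:
        sweep.current = sweep.current + rng.normal(0.0, noise_sd_pa,
                                                   size=sweep.current.shape)
    if params:
        raise InvalidConfigError(f"unknown parameters for kind {kind!r}: {sorted(params)}")
    return sweep, GroundTruthLog(events=events, scalars=scalars)


# --------------------------------------------------------------------------
# static neuron images
# --------------------------------------------------------------------------

@dataclass
class StaticNeuronConfig:
    """A single labeled neuron image with known geometry and intensities."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.2               # um/px
    path_length_um: float = 200.0
    density_per_um: float = 0.4           # puncta per um of neurite
    psf_sigma: float = 1.5
    quantum: float = 100.0
    vesicles_per_punctum_dist: dict[int, float] = field(default_factory=_default_vesicle_dist)
    soma_radius_px: int = 18
    golgi_axes_px: tuple[int, int] = (6, 10)
    golgi_mean: float = 50.0
    cell_mean: float = 10.0
    noise_gaussian_sd: float = 0.0
    margin_px: int = 12
    row_spacing_px: int = 20
    seed: int = 0


def _serpentine_path(shape: tuple[int, int], length_px: int, margin: int,
                     spacing: int) -> np.ndarray:
    """(n, 2) ordered pixel path of exactly ``length_px`` unit steps,
    snaking across the frame with only 4-neighbor moves."""
    h, w = shape
    pts = []
    r, c = margin, margin
    direction = 1
    pts.append((r, c))
    while len(pts) - 1 < length_px:
        run = 0
        while len(pts) - 1 < length_px and margin <= c + direction <= w - margin - 1:
            c += direction
            pts.append((r, c))
            run += 1
        if len(pts) - 1 >= length_px:
            break
        if run == 0 and r + spacing > h - margin - 1:
            raise InvalidConfigError("requested path length does not fit the image")
        for _ in range(spacing):
            if len(pts) - 1 >= length_px:
                break
            r += 1
            pts.append((r, c))
        if r > h - margin - 1:
            raise InvalidConfigError("requested path length does not fit the image")
        direction *= -1
    return np.array(pts, dtype=np.int64)


def simulate_static_neuron(config: StaticNeuronConfig
                           ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
                                      GroundTruthLog]:
    """Render a neuron image set with a ground-truth log.

    Returns ``(images, masks, log)`` where ``images`` holds the marker
    channel and ``masks`` binary masks for the neurite, soma, Golgi and
    whole cell. The skeleton path has a known total length, puncta sit on
    it at the requested density, and the Golgi/soma regions have the
    requested mean intensities exactly (before noise).
    """
    from skimage.morphology import dilation, disk

    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    length_px = int(round(config.path_length_um / config.pixel_size))
    path = _serpentine_path(config.image_shape, length_px,
                            config.margin_px, config.row_spacing_px)
    true_length_um = (len(path) - 1) * config.pixel_size

    soma_center = (int(path[0, 0]), int(path[0, 1]))
    n_puncta = int(round(config.density_per_um * true_length_um))
    min_sep_px = 4
    # keep puncta clear of the bright soma so region means stay exact
    dist_to_soma = np.hypot(path[:, 0] - soma_center[0], path[:, 1] - soma_center[1])
    eligible = np.flatnonzero(dist_to_soma > config.soma_radius_px + 4)
    if n_puncta * min_sep_px > len(eligible):
        raise InvalidConfigError(
            f"density {config.density_per_um}/um exceeds placement capacity")
    if n_puncta:
        step = len(eligible) / n_puncta
        idx = (np.arange(n_puncta) * step + step / 2
               + rng.uniform(-step / 4, step / 4, size=n_puncta)).astype(np.int64)
        idx = eligible[np.clip(idx, 0, len(eligible) - 1)]
    else:
        idx = np.array([], dtype=np.int64)
    punct_pos = path[idx]
    ks = np.array(sorted(config.vesicles_per_punctum_dist), dtype=np.int64)
    pk = np.array([config.vesicles_per_punctum_dist[int(k)] for k in ks])
    intensities = rng.choice(ks, p=pk / pk.sum(), size=n_puncta) * config.quantum

    skeleton = np.zeros((h, w), dtype=bool)
    skeleton[path[:, 0], path[:, 1]] = True
    neurite_mask = dilation(skeleton, disk(2)) > 0

    rr, cc = np.mgrid[0:h, 0:w]
    soma_mask = ((rr - soma_center[0]) ** 2 + (cc - soma_center[1]) ** 2
                 <= config.soma_radius_px ** 2)
    ga, gb = config.golgi_axes_px
    golgi_mask = (((rr - soma_center[0]) / ga) ** 2
                  + ((cc - soma_center[1]) / gb) ** 2) <= 1.0
    golgi_mask &= soma_mask
    cell_mask = soma_mask | neurite_mask

    image = np.zeros((h, w), dtype=np.float64)
    image[cell_mask] = config.cell_mean
    image[golgi_mask] = config.golgi_mean
    for (r, c), a in zip(punct_pos, intensities):
        _render_moving_spot(image, float(r), float(c), float(a), config.psf_sigma)
    if config.noise_gaussian_sd > 0:
        image = image + rng.normal(0.0, config.noise_gaussian_sd, size=image.shape)

    images = {"marker": image}
    masks = {"skeleton": skeleton, "neurite": neurite_mask, "soma": soma_mask,
             "golgi": golgi_mask, "cell": cell_mask}
    log = GroundTruthLog(
        puncta=pd.DataFrame({"id": np.arange(n_puncta),
                             "row": punct_pos[:, 0] if n_puncta else [],
                             "col": punct_pos[:, 1] if n_puncta else [],
                             "intensity": intensities}),
        region_means={"golgi": config.golgi_mean, "cell_rest": config.cell_mean},
        scalars={"path_length_um": true_length_um, "n_puncta": n_puncta,
                 "density_per_um": n_puncta / true_length_um if true_length_um else 0.0,
                 "soma_row": soma_center[0], "soma_col": soma_center[1],
                 "pool_vesicles": int(intensities.sum() / config.quantum) if n_puncta else 0},
    )
    return images, masks, log
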