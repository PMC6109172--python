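"""Generator: ground-truth construction, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from regsec import synthgen
from regsec.errors import InvalidConfigError


def small_dcv(**kw):
    # separation of 13 px puts every punctum beyond its neighbors'
    # truncated (4 sigma = 6 px) PSF footprints, making pixel values exact
    base = dict(image_shape=(48, 48), n_frames=120, n_puncta=3,
                stim_onsets=(12.0, 14.0, 16.0), nh4_window=(40.0, 55.0),
                min_separation_px=13.0, seed=0)
    base.update(kw)
    return synthgen.default_dcv_config(**base)


def test_noise_free_dcv_has_exact_logged_steps():
    movie, log = synthgen.simulate_dcv_movie(small_dcv(fusion_probability=1.0))
    assert len(log.events) == 3
    cfg = small_dcv()
    for ev in log.events.itertuples():
        r, c, f = int(ev.row), int(ev.col), int(ev.onset_frame)
        # step of one quantum at the logged onset, nothing the frame before
        assert movie.data[f, r, c] == pytest.approx(
            cfg.baseline_offset + cfg.quantum, rel=1e-9)
        assert movie.data[f - 1, r, c] == pytest.approx(cfg.baseline_offset)


def test_zero_fusion_probability_constant_outside_nh4():
    movie, log = synthgen.simulate_dcv_movie(small_dcv(fusion_probability=0.0))
    assert len(log.events) == 0
    i0 = movie.frame_range((40.0, 55.0))[0]
    baseline = movie.data[:i0]
    assert np.all(baseline == baseline[0])       # constant up to the NH4 window


def test_nh4_plateau_equals_vesicles_times_quantum():
    movie, log = synthgen.simulate_dcv_movie(small_dcv(fusion_probability=0.0))
    cfg = small_dcv()
    i0, i1 = movie.frame_range(cfg.nh4_window)
    for p in log.puncta.itertuples():
        plateau = movie.data[i0:i1, int(p.row), int(p.col)] - cfg.baseline_offset
        assert np.allclose(plateau, p.vesicles * cfg.quantum)


def test_pool_invariants():
    _, log = synthgen.simulate_dcv_movie(
        small_dcv(n_puncta=10, min_separation_px=8.0, seed=5))
    assert log.pool_vesicles >= len(log.puncta)
    if len(log.events):
        assert set(log.events["punctum_id"]) <= set(log.puncta["id"])


@pytest.mark.parametrize("maker", [
    lambda s: synthgen.simulate_dcv_movie(small_dcv(
        seed=s, fusion_probability=0.5, noise_gaussian_sd=10.0, noise_poisson=True)),
    lambda s: synthgen.simulate_sv_movie(synthgen.default_sv_config(
        seed=s, n_puncta=6, fraction_silent=0.5, noise_gaussian_sd=10.0,
        image_shape=(48, 48), n_frames=80, stim_onsets=(12.0,),
        nh4_window=(25.0, 35.0))),
    lambda s: synthgen.simulate_flux_movie(
        synthgen.SimulationConfig(image_shape=(32, 64), n_frames=60,
                                  nh4_window=None, stim_onsets=(), seed=s,
                                  noise_gaussian_sd=5.0),
        [1.0, 0.5], [2.0, 10.0]),
])
def test_seeded_movies_are_bit_identical(maker):
    m1, l1 = maker(7)
    m2, l2 = maker(7)
    assert np.array_equal(m1.data, m2.data)
    pd.testing.assert_frame_equal(l1.puncta, l2.puncta)
    pd.testing.assert_frame_equal(l1.events, l2.events)
    pd.testing.assert_frame_equal(l1.tracks, l2.tracks)


def test_seeded_ephys_and_static_are_bit_identical():
    s1, l1 = synthgen.simulate_ephys_sweep("minis", seed=7, duration_s=5.0,
                                           noise_sd_pa=3.0)
    s2, l2 = synthgen.simulate_ephys_sweep("minis", seed=7, duration_s=5.0,
                                           noise_sd_pa=3.0)
    assert np.array_equal(s1.current, s2.current)
    pd.testing.assert_frame_equal(l1.events, l2.events)

    cfg = synthgen.StaticNeuronConfig(seed=7, noise_gaussian_sd=2.0)
    i1, m1, g1 = synthgen.simulate_static_neuron(cfg)
    i2, m2, g2 = synthgen.simulate_static_neuron(cfg)
    assert np.array_equal(i1["marker"], i2["marker"])
    pd.testing.assert_frame_equal(g1.puncta, g2.puncta)


# ---------------------------------------------------------------- SV movies

def test_sv_silent_fraction_exact_in_log():
    cfg = synthgen.default_sv_config(n_puncta=10, fraction_silent=0.5, seed=2)
    _, log = synthgen.simulate_sv_movie(cfg)
    assert int(log.puncta["responsive"].sum()) == 5
    resp = log.puncta[log.puncta["responsive"]]
    assert np.allclose(resp["fusion_fraction"], 0.25)


# ---------------------------------------------------------------- flux movies

def test_flux_logged_pixel_speed_arithmetic():
    cfg = synthgen.SimulationConfig(image_shape=(32, 64), n_frames=40,
                                    nh4_window=None, stim_onsets=(),
                                    pixel_size=0.2, dt=0.5, seed=0)
    _, log = synthgen.simulate_flux_movie(cfg, [1.0], [2.0])
    assert log.tracks.loc[0, "px_per_frame"] == pytest.approx(2.5)


def test_flux_ground_truth_rate():
    cfg = synthgen.SimulationConfig(image_shape=(32, 64), n_frames=240,
                                    nh4_window=None, stim_onsets=(), seed=0)
    _, log = synthgen.simulate_flux_movie(cfg, [1.0] * 6,
                                          [5.0, 20.0, 40.0, 60.0, 80.0, 100.0])
    assert log.scalars["flux_per_min"] == pytest.approx(3.0)


def test_flux_empty_speed_list():
    cfg = synthgen.SimulationConfig(image_shape=(32, 64), n_frames=40,
                                    nh4_window=None, stim_onsets=(), seed=0)
    movie, log = synthgen.simulate_flux_movie(cfg, [], [])
    assert len(log.tracks) == 0
    assert np.all(movie.data == movie.data[0])


def test_flux_entry_after_end_rejected():
    cfg = synthgen.SimulationConfig(image_shape=(32, 64), n_frames=40,
                                    nh4_window=None, stim_onsets=(), seed=0)
    with pytest.raises(InvalidConfigError):
        synthgen.simulate_flux_movie(cfg, [1.0], [999.0])


# ---------------------------------------------------------------- ephys

def test_sucrose_rectangle_logs_half_nanocoulomb():
    _, log = synthgen.simulate_ephys_sweep("sucrose", window=(1.0, 6.0),
                                           amplitude_pa=100.0)
    assert log.scalars["true_charge_nc"] == pytest.approx(0.5)


def test_minis_poisson_count():
    _, log = synthgen.simulate_ephys_sweep("minis", seed=11, rate_hz=5.0,
                                           duration_s=60.0)
    n = log.scalars["n_events"]
    assert abs(n - 300) < 5 * np.sqrt(300)      # within Poisson variation


def test_paired_pulse_logged_amplitudes():
    _, log = synthgen.simulate_ephys_sweep("paired_pulse", ratio=1.5,
                                           amplitude_pa=200.0)
    assert log.scalars["amplitude_2_pa"] == pytest.approx(1.5 * 200.0)


def test_unknown_sweep_kind_rejected():
    with pytest.raises(InvalidConfigError):
        synthgen.simulate_ephys_sweep("ramp")


# ---------------------------------------------------------------- static

def test_static_density_and_region_means():
    cfg = synthgen.StaticNeuronConfig(seed=0)
    images, masks, log = synthgen.simulate_static_neuron(cfg)
    assert log.scalars["n_puncta"] == 80          # 0.4/um over 200 um
    assert log.region_means["golgi"] / log.region_means["cell_rest"] == 5.0
    rest = masks["soma"] & ~masks["golgi"]
    assert images["marker"][masks["golgi"]].mean() == pytest.approx(50.0)
    assert images["marker"][rest].mean() == pytest.approx(10.0)


def test_static_capacity_error():
    with pytest.raises(InvalidConfigError):
        synthgen.simulate_static_neuron(
            synthgen.StaticNeuronConfig(density_per_um=50.0))


# ---------------------------------------------------------------- validation

@pytest.mark.parametrize("kw", [
    {"dt": 0.0}, {"quantum": -1.0}, {"fusion_probability": 1.5},
    {"image_shape": (0, 64)},
    {"nh4_window": (14.0, 25.0)},       # overlaps the stimulation trains
])
def test_invalid_configs_rejected(kw):
    with pytest.raises(InvalidConfigError):
        synthgen.simulate_dcv_movie(small_dcv(**kw))
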