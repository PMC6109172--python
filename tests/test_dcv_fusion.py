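"""NPY-pHluorin analysis: events, pool correction, fusion probability."""

import numpy as np
import pytest

from regsec import synthgen
from regsec.dcv_fusion import (
    assign_trains, classify_synaptic, corrected_pool, detect_fusion_events,
    estimate_pool, event_duration, events_to_frame, fusion_probability,
    modal_intensity,
)
from regsec.errors import AnalysisError
from regsec.imaging import MovieStack, Roi, StimulusProtocol, make_roi


def dcv_cfg(**kw):
    base = dict(image_shape=(48, 48), n_frames=120, n_puncta=5,
                stim_onsets=(12.0, 14.0, 16.0), nh4_window=(40.0, 55.0),
                min_separation_px=10.0, seed=0)
    base.update(kw)
    return synthgen.default_dcv_config(**base)


# ------------------------------------------------------------ detection

def test_noise_free_events_at_logged_onsets():
    movie, log = synthgen.simulate_dcv_movie(dcv_cfg(fusion_probability=1.0))
    events = detect_fusion_events(movie)
    assert len(events) == len(log.events) == 5
    truth = {(int(e.row), int(e.col)): int(e.onset_frame)
             for e in log.events.itertuples()}
    for ev in events:
        key = min(truth, key=lambda p: (p[0] - ev.roi.center[0]) ** 2
                  + (p[1] - ev.roi.center[1]) ** 2)
        assert abs(ev.onset_frame - truth[key]) <= 1


def test_constant_movie_yields_no_events():
    movie, _ = synthgen.simulate_dcv_movie(dcv_cfg(fusion_probability=0.0))
    assert detect_fusion_events(movie) == []


def test_punctum_present_before_first_train_excluded():
    """A punctum that appears before stimulation is not a fusion event."""
    data = np.full((120, 48, 48), 100.0)
    data[5:, 20, 20] += 200.0                  # steps up at t = 2.5 s
    movie = MovieStack(data, dt=0.5, protocol=StimulusProtocol(
        train_onsets=(12.0,), aps_per_train=50, train_freq=50.0,
        nh4_window=(40.0, 55.0)))
    assert detect_fusion_events(movie) == []


def test_detection_recall_precision_at_snr5():
    tp = fp = fn = 0
    for seed in range(4):
        cfg = dcv_cfg(n_puncta=15, fusion_probability=0.3, seed=seed,
                      image_shape=(64, 64), min_separation_px=8.0,
                      noise_gaussian_sd=10.0, noise_poisson=True)
        movie, log = synthgen.simulate_dcv_movie(cfg)
        events = detect_fusion_events(movie)
        truth = log.events[["row", "col"]].to_numpy()
        used = set()
        for ev in events:
            if len(truth):
                d = np.hypot(truth[:, 0] - ev.roi.center[0],
                             truth[:, 1] - ev.roi.center[1])
                j = int(np.argmin(d))
                if d[j] <= 2 and j not in used:
                    used.add(j)
                    tp += 1
                    continue
            fp += 1
        fn += len(truth) - len(used)
    assert tp / (tp + fn) >= 0.9
    assert tp / (tp + fp) >= 0.9


# ------------------------------------------------------------ durations

def test_event_duration_step_widths():
    values = np.full(60, 100.0)
    values[30:34] += 100.0                    # 4 frames above criterion
    trace_stack = MovieStack(np.repeat(values[:, None, None], 9, axis=1
                                       ).reshape(60, 3, 3), dt=0.5)
    from regsec.imaging import compute_dff, extract_trace
    roi = make_roi((1.0, 1.0), 3)
    trace = compute_dff(extract_trace(trace_stack, roi))
    from regsec.dcv_fusion import FusionEvent
    ev = FusionEvent(roi=roi, trace=trace, onset_frame=30, peak_dff=1.0,
                     baseline_sd=0.0)
    assert event_duration(ev) == pytest.approx(2.0)

    values2 = np.full(60, 100.0)
    values2[30] += 100.0                      # single-frame flash
    trace2 = compute_dff(extract_trace(
        MovieStack(np.repeat(values2[:, None, None], 9, axis=1
                             ).reshape(60, 3, 3), dt=0.5), roi))
    ev2 = FusionEvent(roi=roi, trace=trace2, onset_frame=30, peak_dff=1.0,
                      baseline_sd=0.0)
    assert event_duration(ev2) == pytest.approx(0.5)


def test_event_duration_grows_with_decay_tau():
    # noise gives the 3-SD duration criterion a finite threshold
    durations = []
    for tau in (1.0, 3.0, 9.0):
        movie, log = synthgen.simulate_dcv_movie(
            dcv_cfg(fusion_probability=1.0, n_puncta=3, event_decay_tau=tau,
                    n_frames=240, nh4_window=(90.0, 110.0),
                    noise_gaussian_sd=5.0))
        events = detect_fusion_events(movie)
        durations.append(np.mean([e.duration_s for e in events]))
    assert durations[0] < durations[1] < durations[2]


# ------------------------------------------------------------ train binning

def test_assign_trains_uniform_and_conservation():
    movie, log = synthgen.simulate_dcv_movie(
        dcv_cfg(n_puncta=12, fusion_probability=1.0, image_shape=(96, 96),
                seed=3))
    events = detect_fusion_events(movie)
    hist = assign_trains(events, movie)
    assert hist["count"].sum() == len(events)              # conservation
    assert hist["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)
    # noise-free: histogram equals the ground-truth train assignment
    true_counts = log.events["train_index"].value_counts()
    for train, n in true_counts.items():
        assert hist.loc[hist["train"] == train, "count"].iloc[0] == n


def test_assign_trains_all_in_first_train():
    movie, _ = synthgen.simulate_dcv_movie(
        dcv_cfg(fusion_probability=1.0, train_weights=(1.0, 0.0, 0.0)))
    events = detect_fusion_events(movie)
    hist = assign_trains(events, movie)
    assert hist["cumulative_fraction"].iloc[0] == pytest.approx(1.0)


# ------------------------------------------------------------ synaptic flag

def test_synaptic_majority_rule_examples():
    roi = Roi(center=(10, 10), size=3)         # rows/cols 9..11
    mask = np.zeros((32, 32), bool)
    mask[9:12, 9:11] = True                    # 6 of 9 pixels
    assert classify_synaptic(roi, mask) is True
    mask2 = np.zeros((32, 32), bool)
    mask2[9:11, 9:11] = True                   # 4 of 9 pixels
    assert classify_synaptic(roi, mask2) is False


def test_synaptic_flag_matches_bruteforce_oracle(rng):
    for _ in range(1000):
        center = tuple(rng.integers(4, 28, 2))
        roi = Roi(center=(int(center[0]), int(center[1])), size=3)
        mask = rng.random((32, 32)) < rng.uniform(0.2, 0.8)
        (r0, r1), (c0, c1) = roi.rows, roi.cols
        count = int(mask[r0:r1, c0:c1].sum())
        assert classify_synaptic(roi, mask) == (count > 4.5)


# ------------------------------------------------------------ pool

def test_corrected_pool_from_given_intensities():
    intensities = np.array([100.0, 100.0, 100.0, 200.0, 300.0])
    mode = modal_intensity(intensities)
    assert mode == pytest.approx(100.0, rel=0.2)    # Silverman KDE at n=5
    assert corrected_pool(intensities, mode) == 8   # 1+1+1+2+3
    assert corrected_pool(np.full(10, 70.0), modal_intensity(np.full(10, 70.0))) == 10


def test_modal_intensity_examples():
    assert modal_intensity([42.0]) == 42.0
    assert modal_intensity([5.0, 5.0, 5.0, 9.0]) == pytest.approx(5.0, abs=1.0)
    with pytest.raises(AnalysisError):
        modal_intensity([])


def test_modal_intensity_bimodal_draw(rng):
    quantum = 120.0
    sample = np.concatenate([np.full(80, quantum), np.full(20, 2 * quantum)])
    sample = sample * rng.normal(1.0, 0.03, size=100)
    assert modal_intensity(sample) == pytest.approx(quantum, rel=0.1)


def test_pool_recovery_noise_free():
    cfg = dcv_cfg(image_shape=(192, 192), n_puncta=150, fusion_probability=0.0,
                  min_separation_px=8.0, seed=6)
    movie, log = synthgen.simulate_dcv_movie(cfg)
    pool = estimate_pool(movie)
    true = log.pool_vesicles
    assert pool.raw_puncta < true                   # multi-vesicle puncta exist
    assert abs(pool.corrected_pool - true) / true <= 0.10
    assert pool.corrected_pool >= pool.raw_puncta


def test_fusion_probability_examples():
    movie, _ = synthgen.simulate_dcv_movie(dcv_cfg(fusion_probability=0.0))
    pool = estimate_pool(movie)
    assert fusion_probability(10, 200) == pytest.approx(5.0)
    assert fusion_probability(0, pool) == 0.0
    with pytest.raises(AnalysisError):
        fusion_probability(1, 0)


def test_events_frame_columns():
    movie, _ = synthgen.simulate_dcv_movie(dcv_cfg(fusion_probability=1.0))
    events = detect_fusion_events(movie)
    frame = events_to_frame(events)
    assert {"onset_s", "peak_dff", "duration_s"} <= set(frame.columns)
    assert len(frame) == len(events)
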