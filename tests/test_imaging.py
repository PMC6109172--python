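"""Core imaging layer: ROIs, traces, dF/F0, projections, detection, I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regsec.errors import (
    AnalysisError, ClippedRoiError, DegenerateBaselineError, ProtocolError,
)
from regsec.imaging import (
    MovieStack, Roi, StimulusProtocol, Trace,
    compute_dff, detect_puncta, extract_trace, is_mobile, make_roi,
    max_projection, read_protocol, read_stack, write_protocol, write_stack,
)


def _gaussian_spot(shape, center, amplitude=100.0, sigma=1.5, offset=0.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return offset + amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma ** 2))


# ---------------------------------------------------------------- ROIs

@pytest.mark.parametrize("centroid,size,rows,cols", [
    ((10.2, 10.7), 3, (9, 12), (10, 13)),      # odd: centered on rounded centroid
    ((10.0, 10.0), 4, (9, 13), (9, 13)),       # even: upper-left of central 2x2
    ((5.0, 5.0), 3, (4, 7), (4, 7)),
])
def test_make_roi_placement(centroid, size, rows, cols):
    roi = make_roi(centroid, size, frame_shape=(64, 64))
    assert roi.rows == rows
    assert roi.cols == cols


def test_make_roi_border_clipped():
    with pytest.raises(ClippedRoiError):
        make_roi((0.0, 0.0), 3, frame_shape=(64, 64))


# ---------------------------------------------------------------- traces

def _stack(data, dt=0.5, **protocol):
    return MovieStack(np.asarray(data, float), dt=dt,
                      protocol=StimulusProtocol(**protocol))


def test_extract_trace_constant_and_mean():
    stack = _stack(np.full((5, 8, 8), 10.0))
    roi = make_roi((4.0, 4.0), 3)
    assert np.array_equal(extract_trace(stack, roi).values, np.full(5, 10.0))

    frame = np.zeros((8, 8))
    frame[3:6, 3:6] = np.arange(9).reshape(3, 3)
    stack = _stack(np.stack([frame, frame]))
    assert extract_trace(stack, make_roi((4.0, 4.0), 3)).values[0] == 4.0


def test_extract_trace_linear_ramp_in_time():
    ramp = np.arange(6, dtype=float)[:, None, None] * np.ones((6, 8, 8))
    values = extract_trace(_stack(ramp), make_roi((4, 4), 3)).values
    assert np.allclose(np.diff(values), 1.0)


def test_dff_baseline_frame_count_and_values():
    # at 2 Hz the 10-s baseline covers the first 20 frames
    values = np.concatenate([np.full(20, 10.0), np.full(10, 30.0)])
    trace = compute_dff(Trace(values=values, dt=0.5))
    assert trace.f0 == 10.0
    assert np.allclose(trace.dff[:20], 0.0)
    assert np.allclose(trace.dff[20:], 2.0)


def test_dff_constant_trace_is_zero():
    trace = compute_dff(Trace(values=np.full(40, 7.5), dt=0.5))
    assert np.all(trace.dff == 0.0)


def test_dff_rejects_nonpositive_baseline():
    with pytest.raises(DegenerateBaselineError):
        compute_dff(Trace(values=np.zeros(40), dt=0.5))


def test_dff_roundtrip_reconstructs_values():
    values = np.linspace(5, 9, 40)
    trace = compute_dff(Trace(values=values, dt=0.5))
    assert np.allclose(trace.dff * trace.f0 + trace.f0, values)


@given(st.floats(min_value=0.1, max_value=100.0))
def test_dff_gain_invariance(c):
    values = np.concatenate([np.full(20, 10.0), np.full(10, 25.0)])
    base = compute_dff(Trace(values=values, dt=0.5))
    scaled = compute_dff(Trace(values=values * c, dt=0.5))
    assert np.allclose(base.dff, scaled.dff)


# ---------------------------------------------------------------- projection

def test_max_projection_examples_and_properties(rng):
    data = rng.uniform(0, 10, size=(6, 8, 8))
    stack = _stack(data)
    proj = max_projection(stack, (0.0, 3.0))
    assert np.all(proj + 1e-12 >= data)                   # >= every frame
    single = max_projection(stack, (1.0, 1.5))            # one-frame window
    assert np.array_equal(single, data[2])
    # order invariance
    shuffled = _stack(data[rng.permutation(6)])
    assert np.allclose(max_projection(shuffled, (0.0, 3.0)), proj)
    with pytest.raises(AnalysisError):
        max_projection(stack, (2.0, 2.0))


def test_max_projection_two_frames():
    stack = _stack([np.full((4, 4), 1.0), np.full((4, 4), 5.0)])
    assert np.all(max_projection(stack, (0.0, 1.0)) == 5.0)


# ---------------------------------------------------------------- detection

def test_detect_single_spot_subpixel():
    img = _gaussian_spot((64, 64), (20.3, 30.6))
    dets = detect_puncta(img)
    assert len(dets) == 1
    assert abs(dets[0].centroid[0] - 20.3) < 0.5
    assert abs(dets[0].centroid[1] - 30.6) < 0.5


def test_detect_blank_and_two_spots():
    assert detect_puncta(np.zeros((32, 32))) == []
    img = _gaussian_spot((64, 64), (20, 20)) + _gaussian_spot((64, 64), (20, 30))
    assert len(detect_puncta(img)) == 2


def test_detect_rejects_non_2d():
    with pytest.raises(AnalysisError):
        detect_puncta(np.zeros((3, 4, 4)))


def test_detect_intensity_scales_with_amplitude():
    one = detect_puncta(_gaussian_spot((64, 64), (20, 20), amplitude=100))[0]
    three = detect_puncta(_gaussian_spot((64, 64), (20, 20), amplitude=300))[0]
    assert three.intensity == pytest.approx(3 * one.intensity, rel=0.02)


# ---------------------------------------------------------------- mobility

def _movie_with_spot(drift_px=0.0, n=40, visible=True):
    frames = []
    for f in range(n):
        c = (20.0 + drift_px * f / (n - 1), 20.0)
        amp = 100.0 if visible else 0.0
        frames.append(_gaussian_spot((48, 48), c, amplitude=amp, offset=50.0))
    return _stack(np.stack(frames))


def test_stationary_spot_not_mobile():
    stack = _movie_with_spot(0.0)
    roi = make_roi((20, 20), 4)
    assert is_mobile(stack, roi) is False


def test_translating_spot_is_mobile():
    stack = _movie_with_spot(5.0)
    roi = make_roi((20, 20), 4)
    assert is_mobile(stack, roi, max_displacement_px=2.0) is True
    assert is_mobile(stack, roi, max_displacement_px=np.inf) is False


def test_lost_punctum_indeterminate():
    stack = _movie_with_spot(0.0, visible=False)
    roi = make_roi((20, 20), 4)
    with pytest.warns(UserWarning):
        assert is_mobile(stack, roi) is None


# ---------------------------------------------------------------- I/O

def test_stack_roundtrip_16bit(tmp_path):
    data = np.arange(2 * 16 * 16, dtype=np.uint16).reshape(2, 16, 16)
    stack = MovieStack(data.astype(float), dt=0.5,
                       protocol=StimulusProtocol(nh4_window=(0.0, 1.0)))
    write_stack(tmp_path / "m.tif", stack, protocol_path=tmp_path / "p.txt")
    back = read_stack(tmp_path / "m.tif", tmp_path / "p.txt")
    assert np.array_equal(back.data, data)
    assert back.dt == 0.5
    assert back.protocol.nh4_window == (0.0, 1.0)


def test_protocol_roundtrip(tmp_path):
    proto = StimulusProtocol(train_onsets=(30.0, 32.0), aps_per_train=50,
                             train_freq=50.0, nh4_window=(240.0, 270.0),
                             biotin_time=12.5)
    write_protocol(tmp_path / "p.txt", proto, dt=0.5, pixel_size=0.2)
    back, dt, px = read_protocol(tmp_path / "p.txt")
    assert back == proto and dt == 0.5 and px == 0.2


def test_read_stack_rejects_window_beyond_recording(tmp_path):
    data = np.zeros((10, 8, 8), dtype=np.uint16)
    stack = MovieStack(data.astype(float), dt=0.5)
    write_stack(tmp_path / "m.tif", stack)
    write_protocol(tmp_path / "p.txt",
                   StimulusProtocol(nh4_window=(2.0, 99.0)), dt=0.5,
                   pixel_size=0.2)
    with pytest.raises(ProtocolError):
        read_stack(tmp_path / "m.tif", tmp_path / "p.txt")


def test_read_stack_frame_count(tmp_path):
    data = np.zeros((100, 8, 8), dtype=np.uint16)
    write_stack(tmp_path / "m.tif", MovieStack(data.astype(float), dt=0.5),
                protocol_path=tmp_path / "p.txt")
    assert read_stack(tmp_path / "m.tif", tmp_path / "p.txt").n_frames == 100
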