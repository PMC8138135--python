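import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdep.io import N_JOINTS, SkeletonRecording
from gaitdep.preprocess import (
    GAUSSIAN_KERNEL,
    GaussianKernel,
    SegmentationError,
    WalkPass,
    detect_toe_off_events,
    extract_two_cycle_segment,
    gaussian_filter,
    preprocess_recording,
    select_middle_face_toward,
    split_walk_passes,
    to_spine_relative,
)
from gaitdep.synthetic import CohortConfig, GaitParams, synthesize_recording


# ---------------------------------------------------------------- transform

def test_spine_relative_zeroes_spine(noisy_recording):
    rel, spine = to_spine_relative(noisy_recording)
    assert rel.coordinate_frame == "spine_relative"
    np.testing.assert_array_equal(rel.joint("spine"), 0.0)
    np.testing.assert_array_equal(spine, noisy_recording.joint("spine"))


def test_all_joints_at_spine_gives_zero():
    positions = np.tile(np.array([1.0, 2.0, 3.0]), (10, N_JOINTS, 1))
    rec = SkeletonRecording(positions=positions)
    rel, _ = to_spine_relative(rec)
    np.testing.assert_array_equal(rel.positions, 0.0)


def test_transform_translation_invariance(static_recording):
    rel1, _ = to_spine_relative(static_recording)
    shifted = static_recording.copy(
        positions=static_recording.positions + np.array([1.0, 2.0, 3.0])
    )
    rel2, _ = to_spine_relative(shifted)
    np.testing.assert_allclose(rel1.positions, rel2.positions, atol=1e-12)


def test_double_transform_rejected(noisy_recording):
    rel, _ = to_spine_relative(noisy_recording)
    with pytest.raises(ValueError):
        to_spine_relative(rel)


# ------------------------------------------------------------------- filter

def test_kernel_is_normalized_binomial():
    k = GaussianKernel()
    np.testing.assert_allclose(k.coefficients, np.array([1, 4, 6, 4, 1]) / 16)
    assert np.isclose(sum(k.coefficients), 1.0)


def test_filter_constant_invariance():
    x = np.full(50, 3.7)
    np.testing.assert_allclose(gaussian_filter(x), x)


def test_filter_impulse_response():
    x = np.zeros(5)
    x[2] = 1.0
    np.testing.assert_allclose(gaussian_filter(x), GAUSSIAN_KERNEL)


def test_filter_matches_direct_convolution_sum(rng):
    """Oracle: explicit O(n*5) convolution with replicated edges."""
    for _ in range(100):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        padded = np.concatenate(([x[0], x[0]], x, [x[-1], x[-1]]))
        expected = np.array([
            sum(padded[i + m] * GAUSSIAN_KERNEL[4 - m] for m in range(5))
            for i in range(n)
        ])
        np.testing.assert_allclose(gaussian_filter(x), expected, atol=1e-12)


def test_filter_rejects_short_series():
    with pytest.raises(ValueError):
        gaussian_filter(np.ones(4))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
def test_filter_linearity_interior(seed, a, b):
    r = np.random.default_rng(seed)
    x, y = r.normal(size=40), r.normal(size=40)
    lhs = gaussian_filter(a * x + b * y)
    rhs = a * gaussian_filter(x) + b * gaussian_filter(y)
    np.testing.assert_allclose(lhs[2:-2], rhs[2:-2], atol=1e-9)


def test_filter_attenuates_nyquist():
    x = np.resize([1.0, -1.0], 60)  # alternating at the Nyquist frequency
    y = gaussian_filter(x)
    assert np.ptp(y[5:-5]) < 0.3 * np.ptp(x)


# -------------------------------------------------------------------- passes

def _rec_with_spine_z(z):
    positions = np.zeros((len(z), N_JOINTS, 3))
    positions[:, :, 2] = np.asarray(z)[:, None]
    return SkeletonRecording(positions=positions, frame_rate=30.0)


def test_monotone_decrease_is_single_toward_pass():
    rec = _rec_with_spine_z(np.linspace(7, 1, 120))
    passes = split_walk_passes(rec)
    assert len(passes) == 1
    assert passes[0].direction == "toward"
    assert (passes[0].start_frame, passes[0].end_frame) == (0, 120)


def test_triangle_wave_gives_two_round_trips():
    leg = np.linspace(7, 1, 90)
    z = np.concatenate([leg, leg[::-1], leg, leg[::-1]])
    passes = split_walk_passes(_rec_with_spine_z(z))
    directions = [p.direction for p in passes]
    assert directions == ["toward", "away", "toward", "away"]
    # passes are disjoint, ordered and cover the recording
    assert passes[0].start_frame == 0
    for a, b in zip(passes, passes[1:]):
        assert a.end_frame == b.start_frame
    assert passes[-1].end_frame == len(z)


def test_no_toward_pass_raises():
    rec = _rec_with_spine_z(np.linspace(1, 7, 120))
    with pytest.raises(SegmentationError):
        split_walk_passes(rec)


def test_synthetic_pass_durations_match_protocol(noiseless_recording):
    """Each pass spans ~ path_length / walking_speed = 6 s at 30 Hz."""
    passes = split_walk_passes(noiseless_recording)
    interior = passes[1:-1]  # first/last may be clipped by the recording edges
    for p in interior:
        assert p.n_frames == pytest.approx(6.0 * 30, rel=0.1)
    directions = [p.direction for p in passes]
    assert all(a != b for a, b in zip(directions, directions[1:]))


@pytest.mark.parametrize(
    "n_toward,expected_idx",
    [(1, 0), (2, 0), (3, 1), (4, 1), (5, 2)],
)
def test_middle_toward_selection(n_toward, expected_idx):
    passes = []
    f = 0
    toward = []
    for i in range(n_toward):
        p = WalkPass(f, f + 10, "toward")
        passes.append(p)
        toward.append(p)
        f += 10
        passes.append(WalkPass(f, f + 10, "away"))
        f += 10
    assert select_middle_face_toward(passes) is toward[expected_idx]


# ------------------------------------------------------------------ toe-off

def test_toe_off_on_pure_sinusoid():
    t = np.arange(0, 8, 1 / 30)
    y = gaussian_filter(np.sin(2 * np.pi * t / 1.2))
    events = detect_toe_off_events(y, 30.0)
    assert np.all(np.diff(events) == 36)  # period 1.2 s at 30 Hz


def test_toe_off_robust_to_filtered_noise(rng):
    t = np.arange(0, 8, 1 / 30)
    clean = np.sin(2 * np.pi * t / 1.2)
    noisy = gaussian_filter(clean + rng.normal(0, 0.05, size=t.size))
    assert len(detect_toe_off_events(noisy, 30.0)) == len(
        detect_toe_off_events(gaussian_filter(clean), 30.0)
    )


def test_toe_off_flat_series_raises():
    with pytest.raises(SegmentationError):
        detect_toe_off_events(np.ones(300), 30.0)


# ------------------------------------------------------------------ segment

def test_segment_arithmetic_from_event_triple():
    rng = np.random.default_rng(0)
    positions = rng.normal(size=(120, N_JOINTS, 3))
    positions[:, 8, :] = 0.0  # spine-relative: spine at origin
    rec = SkeletonRecording(positions=positions, frame_rate=30.0,
                            coordinate_frame="spine_relative")
    seg = extract_two_cycle_segment(
        rec, WalkPass(0, 120, "toward"), [10, 46, 82],
        sensor_spine_z=np.linspace(7, 3, 120),
    )
    assert seg.n_frames == 72
    assert seg.cycle_boundaries == (0, 36, 72)
    assert seg.duration_s == pytest.approx(72 / 30)
    np.testing.assert_array_equal(seg.joint("spine"), 0.0)


def test_segment_requires_three_events():
    rec = SkeletonRecording(positions=np.zeros((120, N_JOINTS, 3)),
                            coordinate_frame="spine_relative")
    with pytest.raises(SegmentationError, match="insufficient gait cycles"):
        extract_two_cycle_segment(rec, WalkPass(0, 120, "toward"), [10, 46],
                                  sensor_spine_z=np.zeros(120))


def test_noiseless_cycle_duration_recovered_within_one_frame(short_config, rng):
    for cycle in (0.9, 1.2, 1.5):
        params = GaitParams(noise_sd=0.0, jitter_amplitude=0.0,
                            cycle_duration=cycle)
        rec = synthesize_recording(params, short_config, rng)
        seg = preprocess_recording(rec)
        measured = seg.duration_s / 2
        assert abs(measured - cycle) <= 1 / rec.frame_rate


def test_preprocessing_commutes_with_translation(noisy_recording):
    shifted = noisy_recording.copy(
        positions=noisy_recording.positions + np.array([0.5, -0.2, 0.0])
    )
    seg1 = preprocess_recording(noisy_recording)
    seg2 = preprocess_recording(shifted)
    assert seg1.cycle_boundaries == seg2.cycle_boundaries
    np.testing.assert_allclose(seg1.relative_positions, seg2.relative_positions,
                               atol=1e-9)


def test_segment_duration_matches_two_cycle_expectation(noiseless_segment):
    assert 1.6 <= noiseless_segment.duration_s <= 3.6
    assert noiseless_segment.duration_s == pytest.approx(2 * 1.185, abs=2 / 30)
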