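import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdep.features import (
    SPATIOTEMPORAL_NAMES,
    dft,
    extract_all_features,
    frequency_domain_features,
    moment_stats,
    spatiotemporal_features,
    time_domain_features,
)
from gaitdep.io import N_JOINTS, JointMap, SkeletonRecording
from gaitdep.preprocess import GaitSegment, preprocess_recording
from gaitdep.synthetic import GaitParams, synthesize_recording


def _static_segment(offset=0.0, T=72):
    """An artificial constant-pose spine-relative segment."""
    positions = np.zeros((T, N_JOINTS, 3)) + offset
    positions[:, 8, :] = 0.0
    jm = JointMap()
    positions[:, jm.index("clavicle") - 1] = (0.0, 0.50, 0.0)
    positions[:, jm.index("neck") - 1] = (0.0, 0.60, 0.0)  # exactly vertical
    return GaitSegment(
        relative_positions=positions,
        sensor_spine_z=np.full(T, 5.0),
        frame_rate=30.0,
        cycle_boundaries=(0, T // 2, T),
    )


# -------------------------------------------------------------- cardinality

def test_feature_bank_sizes(noiseless_segment):
    banks = extract_all_features(noiseless_segment)
    assert len(banks["spatiotemporal"]) == 10
    assert len(banks["time"]) == 300
    assert len(banks["frequency"]) == 825
    for fv in banks.values():
        assert len(set(fv.names)) == len(fv.names)
        assert np.all(np.isfinite(fv.values))


def test_feature_counts_invariant_to_segment_length(noiseless_recording):
    seg = preprocess_recording(noiseless_recording)
    short = GaitSegment(
        relative_positions=seg.relative_positions[:40],
        sensor_spine_z=seg.sensor_spine_z[:40],
        frame_rate=seg.frame_rate,
        cycle_boundaries=(0, 20, 40),
    )
    banks = extract_all_features(short)
    assert (len(banks["spatiotemporal"]), len(banks["time"]), len(banks["frequency"])) \
        == (10, 300, 825)


# ------------------------------------------------------------ spatiotemporal

def test_static_segment_features_vanish():
    fv = spatiotemporal_features(_static_segment(offset=0.1))
    for name in SPATIOTEMPORAL_NAMES:
        if name in ("toe_clearance_left", "toe_clearance_right"):
            continue  # clearance is a max (height), not a change
        if name == "body_sway":
            assert fv[name] == pytest.approx(0.0)
        elif name in ("head_posture",):
            assert fv[name] == pytest.approx(0.0)
        else:
            assert fv[name] == pytest.approx(0.0)


def test_head_posture_zero_when_neck_above_clavicle():
    assert spatiotemporal_features(_static_segment())["head_posture"] == 0.0


def test_parameter_recovery_on_noiseless_walker(short_config, rng):
    """Each generator amplitude reappears in its matching feature (<5%)."""
    params = GaitParams(noise_sd=0.0, jitter_amplitude=0.0,
                        arm_swing_left=0.27, arm_swing_right=0.23,
                        stride_left=0.62, stride_right=0.59,
                        body_sway=0.36, vertical_head_move=0.06,
                        head_posture_angle=1.23,
                        toe_clearance_left=-0.69, toe_clearance_right=-0.70,
                        walking_speed=0.99)
    rec = synthesize_recording(params, short_config, rng)
    fv = spatiotemporal_features(preprocess_recording(rec))
    expected = {
        "arm_swing_left": 0.27, "arm_swing_right": 0.23,
        "stride_left": 0.62, "stride_right": 0.59,
        "body_sway": 0.36, "vertical_head_move": 0.06,
        "head_posture": 1.23,
        "toe_clearance_left": -0.69, "toe_clearance_right": -0.70,
        "walking_speed": 0.99,
    }
    for name, value in expected.items():
        assert fv[name] == pytest.approx(value, rel=0.05), name


def test_arm_swing_recovery_within_filter_attenuation(short_config, rng):
    params = GaitParams(noise_sd=0.0, jitter_amplitude=0.0, arm_swing_left=0.27)
    rec = synthesize_recording(params, short_config, rng)
    fv = spatiotemporal_features(preprocess_recording(rec))
    assert fv["arm_swing_left"] == pytest.approx(0.27, rel=0.02)


def test_toe_clearance_modes(noiseless_segment):
    fv_max = spatiotemporal_features(noiseless_segment, toe_clearance_mode="max")
    fv_ptp = spatiotemporal_features(noiseless_segment, toe_clearance_mode="ptp")
    assert fv_max["toe_clearance_left"] < 0  # below the spine origin
    assert fv_ptp["toe_clearance_left"] > 0  # a change is non-negative


# ------------------------------------------------------------------ moments

def test_moment_stats_degenerate_series():
    assert moment_stats(np.array([1.0, 1.0, 1.0, 1.0])) == (1.0, 0.0, 0.0, 0.0)


def test_moment_stats_symmetric_series_has_zero_skew():
    _, _, skew, _ = moment_stats(np.array([-1.0, 0.0, 1.0, 0.0]))
    assert skew == pytest.approx(0.0, abs=1e-12)


def test_moment_stats_against_direct_central_moments():
    x = np.array([0.0, 1.0, 2.0, 9.0])
    mean, sd, skew, kurt = moment_stats(x)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    assert mean == pytest.approx(3.0)
    assert sd == pytest.approx(np.sqrt(np.sum((x - m) ** 2) / 3))
    assert skew == pytest.approx(m3 / m2**1.5)
    assert kurt == pytest.approx(m4 / m2**2 - 3)


def test_moment_stats_requires_four_samples():
    with pytest.raises(ValueError):
        moment_stats(np.array([1.0, 2.0, 3.0]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(-10, 10))
def test_time_moments_translation_behavior(seed, shift):
    x = np.random.default_rng(seed).normal(size=30)
    base = moment_stats(x)
    shifted = moment_stats(x + shift)
    assert shifted[0] == pytest.approx(base[0] + shift, abs=1e-9)
    for i in (1, 2, 3):  # sd, skewness, kurtosis translation-invariant
        assert shifted[i] == pytest.approx(base[i], abs=1e-7)


# -------------------------------------------------------------- time block

def test_time_features_constant_segment():
    fv = time_domain_features(_static_segment(offset=0.25))
    series = fv.to_series()
    assert (series.filter(like="_sd") == 0).all()
    assert (series.filter(like="_skew") == 0).all()
    assert (series.filter(like="_kurt") == 0).all()
    assert series["j01_x_mean"] == pytest.approx(0.25)


def test_time_features_channel_permutation(noiseless_segment):
    """Swapping two joints permutes feature values without changing the set."""
    fv = time_domain_features(noiseless_segment)
    swapped = GaitSegment(
        relative_positions=noiseless_segment.relative_positions[:, ::-1, :].copy(),
        sensor_spine_z=noiseless_segment.sensor_spine_z,
        frame_rate=noiseless_segment.frame_rate,
        cycle_boundaries=noiseless_segment.cycle_boundaries,
    )
    fv2 = time_domain_features(swapped)
    assert sorted(np.round(fv.values, 10)) == sorted(np.round(fv2.values, 10))


# --------------------------------------------------------------------- DFT

def brute_force_dft(x):
    n = len(x)
    j = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * k * j / n)) for k in range(n)])


def test_dft_constant_series():
    spec = dft(np.full(8, 2.5))
    assert spec.dc_component == pytest.approx(2.5)
    np.testing.assert_allclose(spec.amplitudes, 0.0, atol=1e-12)


def test_dft_single_tone_concentration():
    n = 16
    x = np.cos(2 * np.pi * np.arange(n) / n)
    spec = dft(x)
    ref = brute_force_dft(x)
    np.testing.assert_allclose(spec.amplitudes, np.abs(ref[1:]), atol=1e-9)
    assert spec.amplitudes[0] == pytest.approx(n / 2)     # k = 1
    assert spec.amplitudes[-1] == pytest.approx(n / 2)    # k = n-1
    assert np.all(spec.amplitudes[1:-1] < 1e-9)


def test_dft_matches_brute_force_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        spec = dft(x)
        ref = brute_force_dft(x)
        assert spec.dc_component == pytest.approx(np.mean(x))
        np.testing.assert_allclose(spec.amplitudes, np.abs(ref[1:]), atol=1e-9)
        np.testing.assert_allclose(
            np.exp(1j * spec.phases), ref[1:] / np.abs(ref[1:]), atol=1e-7
        )


def test_dft_parseval_identity(rng):
    x = rng.normal(size=33)
    spec = dft(x)
    total = (spec.dc_component * len(x)) ** 2 + np.sum(spec.amplitudes**2)
    assert np.sum(x**2) == pytest.approx(total / len(x))


def test_dft_amplitudes_shift_invariant(rng):
    x = rng.normal(size=24)
    a1 = dft(x).amplitudes
    a2 = dft(np.roll(x, 5)).amplitudes
    np.testing.assert_allclose(a1, a2, atol=1e-9)


def test_dft_phases_principal_value(rng):
    spec = dft(rng.normal(size=50))
    assert np.all(spec.phases > -np.pi)
    assert np.all(spec.phases <= np.pi)


# --------------------------------------------------------- frequency block

def test_frequency_features_constant_channels():
    fv = frequency_domain_features(_static_segment(offset=0.3))
    series = fv.to_series()
    assert series["j01_x_dc"] == pytest.approx(0.3)
    assert (series.filter(like="_amp_mean") == 0).all()
    assert (series.filter(like="_amp_sd") == 0).all()


def test_frequency_stats_compose_from_moment_stats(noiseless_segment):
    """Amplitude mean/SD equal moment_stats applied to the amplitude list."""
    fv = frequency_domain_features(noiseless_segment).to_series()
    x = noiseless_segment.relative_positions[:, 0, 1]  # head Y channel
    spec = dft(x)
    mean, sd, skew, kurt = moment_stats(spec.amplitudes)
    assert fv["j01_y_amp_mean"] == pytest.approx(mean)
    assert fv["j01_y_amp_sd"] == pytest.approx(sd)
    assert fv["j01_y_amp_var"] == pytest.approx(sd * sd)
    assert fv["j01_y_amp_skew"] == pytest.approx(skew)
    assert fv["j01_y_dc"] == pytest.approx(np.mean(x))
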