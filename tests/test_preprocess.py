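"""Filtering, differentiation, segmentation and elbow-angle geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import reachdist as rd
from reachdist import ParameterError, SegmentationError


def brute_force_bounds(speed, fs, frac=0.1, hold=0.1):
    """Independent sample-by-sample scan of the threshold rule."""
    thr = frac * max(speed)
    hold_n = int(round(hold * fs))
    n = len(speed)
    onset = None
    for i in range(n):
        if all(speed[j] > thr for j in range(i, min(i + hold_n, n))) and i + hold_n <= n:
            onset = i
            break
    peak = int(np.argmax(speed))
    offset = None
    for i in range(peak + 1, n):
        run_end = i
        while run_end < n and speed[run_end] < thr:
            run_end += 1
        if speed[i] < thr and (run_end - i >= hold_n or run_end == n):
            offset = i - 1
            break
    return onset, offset


def triangular_profile():
    speed = np.empty(121)
    speed[:61] = np.arange(61) * 100.0 / 60.0
    speed[61:] = (120 - np.arange(61, 121)) * 100.0 / 60.0
    return speed


class TestButterworth:
    def test_dc_gain_is_unity(self):
        const = np.full(240, 7.3)
        assert np.allclose(rd.butterworth_zero_phase(const, 120), const)

    @pytest.mark.parametrize(
        "freq, min_ratio, max_ratio",
        [(0.5, 0.99, 1.0001), (30.0, 0.0, 0.01)],
    )
    def test_two_pass_frequency_response(self, freq, min_ratio, max_ratio):
        """Passband sine passes nearly untouched; a sine at 5x cutoff is
        attenuated by more than 99% (the squared 3rd-order magnitude)."""
        fs = 120.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = rd.butterworth_zero_phase(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert min_ratio < ratio < max_ratio

    def test_rejects_bad_cutoff_and_short_series(self):
        with pytest.raises(ParameterError):
            rd.butterworth_zero_phase(np.ones(100), fs=10, cutoff=6)
        with pytest.raises(SegmentationError):
            rd.butterworth_zero_phase(np.ones(5), fs=120, cutoff=6, order=3)


class TestDifferentiate:
    def test_linear_ramp_is_exact_everywhere(self):
        fs = 90.0
        t = np.arange(50) / fs
        assert np.allclose(rd.differentiate(3.5 * t - 1.0, fs), 3.5)

    def test_sine_derivative_matches_analytic(self):
        fs = 120.0
        t = np.arange(int(2 * fs)) / fs
        d = rd.differentiate(np.sin(2 * np.pi * t), fs)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.allclose(d[1:-1], expected[1:-1], rtol=1e-3)

    def test_constant_gives_zeros_and_short_input_raises(self):
        assert np.allclose(rd.differentiate(np.full(10, 4.2), 120), 0.0)
        with pytest.raises(ParameterError):
            rd.differentiate(np.array([1.0]), 120)


class TestTangentialSpeed:
    def test_straight_line_and_stationary(self):
        fs = 120.0
        t = np.arange(60) / fs
        moving = np.column_stack([10 * t, np.zeros_like(t), np.zeros_like(t)])
        assert np.allclose(rd.tangential_speed(moving, fs), 10.0)
        still = np.zeros((60, 3))
        assert np.allclose(rd.tangential_speed(still, fs), 0.0)

    def test_circular_motion_speed(self):
        fs, r, omega = 120.0, 5.0, 2.0
        t = np.arange(int(3 * fs)) / fs
        pos = np.column_stack(
            [r * np.cos(omega * t), r * np.sin(omega * t), np.zeros_like(t)]
        )
        speed = rd.tangential_speed(pos, fs)
        assert np.allclose(speed[1:-1], r * omega, rtol=5e-3)


class TestDetectMovementBounds:
    def test_triangular_profile_matches_brute_force(self):
        speed = triangular_profile()
        bounds = rd.detect_movement_bounds(speed, fs=120)
        assert (bounds.onset, bounds.offset) == (7, 114)
        assert (bounds.onset, bounds.offset) == brute_force_bounds(speed, 120)

    def test_zero_speed_and_unmet_hold_raise(self):
        with pytest.raises(SegmentationError):
            rd.detect_movement_bounds(np.zeros(100), fs=120)
        pulse = np.zeros(120)
        pulse[50:56] = 1.0  # 6 samples = 0.05 s, under the 0.1 s hold
        with pytest.raises(SegmentationError):
            rd.detect_movement_bounds(pulse, fs=120)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_invariant_to_positive_rescaling(self, scale):
        # generic bell profile: no sample sits exactly on the threshold
        t = np.arange(300) / 120.0
        speed = 97.3 * np.exp(-(((t - 1.25) / 0.4) ** 2))
        ref = rd.detect_movement_bounds(speed, 120)
        scaled = rd.detect_movement_bounds(scale * speed, 120)
        assert (ref.onset, ref.offset) == (scaled.onset, scaled.offset)

    def test_time_reversal_mirrors_bounds(self):
        fs = 120.0
        t = np.arange(int(2.5 * fs)) / fs
        # asymmetric smooth bell with quiet padding on both sides
        speed = np.exp(-(((t - 1.1) / 0.33) ** 2)) * (1 + 0.4 * (t - 1.1))
        speed = np.clip(speed, 0, None)
        fwd = rd.detect_movement_bounds(speed, fs)
        rev = rd.detect_movement_bounds(speed[::-1], fs)
        n = len(speed)
        assert rev.onset == n - 1 - fwd.offset
        assert rev.offset == n - 1 - fwd.onset

    def test_offset_fallback_when_tail_stays_fast(self):
        fs = 120.0
        speed = np.concatenate([np.zeros(30), np.linspace(0, 100, 120)])
        bounds = rd.detect_movement_bounds(speed, fs)
        assert bounds.offset == len(speed) - 1
        assert bounds.offset_fallback


class TestElbowAngle:
    def test_reference_geometries(self):
        shoulder = np.array([[0.0, 0, 0]])
        elbow = np.array([[30.0, 0, 0]])
        collinear = np.array([[60.0, 0, 0]])
        perp = np.array([[30.0, 25, 0]])
        w120 = np.array(
            [[30 + 25 * np.cos(np.radians(60)), 25 * np.sin(np.radians(60)), 0.0]]
        )
        assert rd.elbow_angle_series(shoulder, elbow, collinear)[0] == pytest.approx(180)
        assert rd.elbow_angle_series(shoulder, elbow, perp)[0] == pytest.approx(90)
        assert rd.elbow_angle_series(shoulder, elbow, w120)[0] == pytest.approx(120)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_to_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 10, (3, 5, 3))  # shoulder, elbow, wrist trajectories
        base = rd.elbow_angle_series(*pts)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0, 50, 3)
        moved = [p @ rot.T + shift for p in pts]
        assert np.allclose(rd.elbow_angle_series(*moved), base, atol=1e-8)

    def test_coincident_points_raise(self):
        p = np.array([[1.0, 2, 3]])
        with pytest.raises(rd.DegenerateGeometryError):
            rd.elbow_angle_series(p, p, np.array([[4.0, 5, 6]]))


def test_filtered_segmentation_of_reversed_trial_mirrors():
    """End-to-end reversal property: zero-phase filtering commutes with time
    reversal, so segmenting a reversed recording mirrors the bounds."""
    p = rd.TrialParams(duration=1.2, start_angle=60, end_angle=150, fs=120)
    tr = rd.simulate_trial(p, seed=5)
    fwd = rd.segment_trial(tr)
    rev = rd.segment_trial(
        rd.Trial(
            participant_id=tr.participant_id, target=tr.target, trial_id=tr.trial_id,
            fs=tr.fs, angle=tr.angle[::-1].copy(), speed=tr.speed[::-1].copy(),
        )
    )
    n = len(tr)
    assert abs(rev.onset_idx - (n - 1 - fwd.offset_idx)) <= 1
    assert abs(rev.offset_idx - (n - 1 - fwd.onset_idx)) <= 1
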