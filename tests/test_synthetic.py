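import numpy as np
import pytest

from earmotion.geometry import euler_zyx_to_quat, quat_from_axis_angle, quat_multiply, quat_to_euler_zyx
from earmotion.imu_core import AccelCalibration, apply_accel_calibration
from earmotion.synthetic import (
    ACTIVITY_CLASSES,
    ActivitySpec,
    NoiseSpec,
    default_participant_style,
    imu_from_trajectory,
    simulate_activity,
    simulate_dataset,
    simulate_head_trajectory,
)
from earmotion.imu_core import sliding_windows


class TestHeadTrajectory:
    def test_null_command_is_identically_zero(self):
        truth = simulate_head_trajectory("simple", 0.0, 0.0, 5.0, seed=0)
        assert np.all(truth.yaw == 0) and np.all(truth.pitch == 0) and np.all(truth.roll == 0)
        assert np.all(truth.body_rate == 0)

    def test_simple_trajectory_peaks_at_target_and_returns(self):
        truth = simulate_head_trajectory("simple", 30.0, 0.0, 8.0, seed=1)
        assert truth.yaw.max() == pytest.approx(30.0, abs=1e-6)
        assert abs(truth.yaw[-1]) < 1e-6
        assert abs(truth.pitch).max() < 1e-12

    def test_complex_trajectory_is_continuous_with_resting_phase_boundaries(self):
        truth = simulate_head_trajectory("complex", 40.0, 20.0, 12.0, seed=2)
        # continuity: no jump exceeds what the peak rate allows in one sample
        max_jump = np.abs(np.diff(truth.yaw)).max()
        assert max_jump < 61.0 / truth.fs
        assert abs(truth.yaw[-1]) < 1e-6 and abs(truth.pitch[-1]) < 1e-6
        # rate returns exactly to zero between rotation phases
        moving = np.abs(truth.body_rate).sum(axis=1) > 1e-9
        transitions = np.diff(moving.astype(int))
        assert (transitions != 0).sum() >= 4  # at least 2 distinct pulses

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_head_trajectory("simple", 120.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            simulate_head_trajectory("simple", 30.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            simulate_head_trajectory("spin", 30.0, 0.0, 5.0)

    def test_zero_noise_gyro_integration_recovers_yaw(self):
        """Quaternion integration of the exact body rates re-yields the
        commanded Euler trajectory (joint sign-convention check)."""
        truth = simulate_head_trajectory("simple", 35.0, 15.0, 8.0, seed=3)
        q = euler_zyx_to_quat(0.0, 0.0, 0.0)
        dt = 1.0 / truth.fs
        max_err = 0.0
        for i in range(1, len(truth)):
            rate = 0.5 * (truth.body_rate[i - 1] + truth.body_rate[i])  # trapezoid
            q = quat_multiply(q, quat_from_axis_angle(rate * np.pi / 180 * dt))
            _, _, yaw = quat_to_euler_zyx(q)
            max_err = max(max_err, abs(yaw - truth.yaw[i]))
        assert max_err < 0.1


class TestImuFromTrajectory:
    def test_static_truth_reads_pure_gravity(self):
        truth = simulate_head_trajectory("simple", 0.0, 0.0, 3.0, seed=0)
        trace = imu_from_trajectory(truth, NoiseSpec.zero(), seed=0)
        assert np.allclose(trace.accel, [0.0, 0.0, 1.0])
        assert np.allclose(trace.gyro, 0.0)

    def test_constant_yaw_rate_integrates_exactly(self):
        n = 500
        from earmotion.synthetic import TrajectoryTruth

        t = np.arange(n) / 100.0
        truth = TrajectoryTruth(
            t=t,
            roll=np.zeros(n),
            pitch=np.zeros(n),
            yaw=10.0 * t,
            body_rate=np.tile([0.0, 0.0, 10.0], (n, 1)),
            fs=100.0,
        )
        trace = imu_from_trajectory(truth, NoiseSpec.zero(), seed=0)
        integral = trace.gyro[:, 2].sum() / trace.fs
        assert integral == pytest.approx(50.0, rel=1e-9)

    def test_gain_bias_corruption_round_trips_through_calibration(self):
        truth = simulate_head_trajectory("simple", 25.0, 10.0, 6.0, seed=4)
        clean = imu_from_trajectory(truth, NoiseSpec.zero(), seed=0)
        noise = NoiseSpec(
            gyro_noise_sd=0.0,
            gyro_drift_rw_sd=0.0,
            accel_noise_sd=0.0,
            accel_gain=(1.2, 1.0, 1.0),
            accel_bias=(0.05, 0.0, 0.0),
        )
        corrupted = imu_from_trajectory(truth, noise, seed=0)
        cal = AccelCalibration(gains=(1.2, 1.0, 1.0), biases=(0.05, 0.0, 0.0))
        assert np.allclose(apply_accel_calibration(corrupted.accel, cal), clean.accel, atol=1e-12)

    def test_length_mismatch_rejected(self):
        truth = simulate_head_trajectory("simple", 10.0, 0.0, 3.0, seed=0)
        with pytest.raises(ValueError):
            imu_from_trajectory(truth, NoiseSpec.zero(), fs=50.0)


class TestActivities:
    def test_standing_with_zero_noise_is_one_g(self):
        style = {"amp": 0.0, "cadence": 1.0, "phase": 0.0, "tilt_roll": 0.0, "tilt_pitch": 0.0}
        spec = ActivitySpec("St", duration_s=5.0, participant_style=style, seed=0)
        trace = simulate_activity(spec, NoiseSpec.zero())
        mags = np.linalg.norm(trace.accel, axis=1)
        assert np.allclose(mags, 1.0, atol=1e-9)

    def test_turn_left_right_gyro_z_mirror(self):
        style = default_participant_style(np.random.default_rng(1))
        tl = simulate_activity(ActivitySpec("Tl", 10.0, style, seed=5))
        tr = simulate_activity(ActivitySpec("Tr", 10.0, style, seed=5))
        assert np.allclose(tl.gyro[:, 2], -tr.gyro[:, 2])
        assert np.allclose(tl.gyro[:, :2], tr.gyro[:, :2])
        assert np.allclose(tl.accel, tr.accel)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ActivitySpec("X", 5.0)

    def test_deterministic_under_seed(self):
        style = default_participant_style(np.random.default_rng(2))
        a = simulate_activity(ActivitySpec("W", 8.0, style, seed=9))
        b = simulate_activity(ActivitySpec("W", 8.0, style, seed=9))
        assert np.array_equal(a.accel, b.accel) and np.array_equal(a.gyro, b.gyro)

    def test_fall_cycles_contain_impacts_and_quiet_lying(self):
        style = {"amp": 1.0, "cadence": 1.0, "phase": 0.0, "tilt_roll": 0.0, "tilt_pitch": 0.0}
        trace = simulate_activity(ActivitySpec("F", 20.0, style, seed=0), NoiseSpec.zero())
        mag = np.linalg.norm(trace.accel, axis=1)
        # one impact (> 2 g) per ~8 s fall-and-recover cycle
        impacts = np.flatnonzero((mag[1:-1] > 2.0) & (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:]))
        assert len(impacts) >= 2
        # lying phase (4-6 s into the first cycle) is quiet, gravity along roll axis
        lying = trace.accel[450:600]
        assert np.allclose(np.linalg.norm(lying, axis=1), 1.0, atol=0.05)
        assert np.abs(lying[:, 1]).mean() > 0.9  # gravity rotated onto body y


class TestDataset:
    def test_single_participant_shares_one_id(self):
        traces = simulate_dataset(1, 10.0, seed=0, classes=("W",))
        assert {t.participant_id for t in traces} == {0}

    def test_identical_seed_identical_dataset(self):
        a = simulate_dataset(2, 6.0, seed=33)
        b = simulate_dataset(2, 6.0, seed=33)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.accel, tb.accel)
            assert np.array_equal(ta.gyro, tb.gyro)
            assert ta.label == tb.label and ta.participant_id == tb.participant_id

    def test_trace_count_and_window_count(self):
        traces = simulate_dataset(10, 25.0, seed=1)
        assert len(traces) == 90
        wins = list(sliding_windows(traces[0], 5.0, 0.5))
        assert len(wins) == 41

    def test_all_classes_present(self, small_dataset):
        assert {t.label for t in small_dataset} == set(ACTIVITY_CLASSES)
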