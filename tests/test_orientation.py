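"""Calibration, functional alignment, initial orientation and sensor fusion."""

import numpy as np
import pytest

from swimphase import orientation as ori
from swimphase import quaternion as quat
from swimphase.synthetic import simulate_tumble
from swimphase.types import GRAVITY, CalibrationParams, ImuRecording


def _static_recording(acc_vec, gyr_vec=(0, 0, 0), T=2.0, fs=500.0, frame="sensor"):
    n = int(T * fs)
    t = np.arange(n) / fs
    return ImuRecording(
        t=t,
        acc=np.tile(acc_vec, (n, 1)).astype(float),
        gyr=np.tile(gyr_vec, (n, 1)).astype(float),
        fs=fs,
        frame=frame,
    )


class TestApplyCalibration:
    def test_identity_calibration_only_flips_frame(self, rng):
        n = 100
        rec = ImuRecording(
            t=np.arange(n) / 500.0,
            acc=rng.normal(size=(n, 3)),
            gyr=rng.normal(size=(n, 3)),
            fs=500.0,
        )
        out = ori.apply_calibration(rec, CalibrationParams())
        assert out.frame == "anatomical"
        assert np.array_equal(out.acc, rec.acc)
        assert np.array_equal(out.gyr, rec.gyr)

    def test_bias_removal_zeroes_static_gravity_reading(self):
        rec = _static_recording([0, 0, GRAVITY])
        cal = CalibrationParams(acc_bias=[0, 0, GRAVITY])
        out = ori.apply_calibration(rec, cal)
        assert np.allclose(out.acc, 0.0)

    def test_rotation_agrees_with_matrix_product(self):
        ang = np.radians(90)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        rec = _static_recording([1, 0, 0])
        out = ori.apply_calibration(rec, CalibrationParams(R_sensor_to_anatomical=R))
        assert np.allclose(out.acc[0], R @ np.array([1.0, 0, 0]), atol=1e-12)
        assert np.allclose(out.acc[0], [0, 1, 0], atol=1e-12)

    def test_round_trip_with_inverse(self, rng):
        from swimphase.orientation import invert_calibration

        cal = CalibrationParams(
            acc_bias=[0.1, -0.2, 0.05],
            acc_scale=np.diag([1.01, 0.99, 1.02]),
            R_sensor_to_anatomical=quat.to_rotation_matrix(
                quat.from_axis_angle([0, 0, 1], 0.3)
            ),
        )
        n = 50
        rec = ImuRecording(
            t=np.arange(n) / 500.0,
            acc=rng.normal(size=(n, 3)),
            gyr=rng.normal(size=(n, 3)),
            fs=500.0,
            frame="anatomical",
        )
        back = ori.apply_calibration(invert_calibration(rec, cal), cal)
        assert np.allclose(back.acc, rec.acc, atol=1e-10)
        assert np.allclose(back.gyr, rec.gyr, atol=1e-10)

    def test_rejects_non_rotation_matrix(self):
        with pytest.raises(ValueError, match="proper rotation"):
            CalibrationParams(R_sensor_to_anatomical=np.diag([1.0, 1.0, 2.0]))

    def test_rejects_singular_scale(self):
        with pytest.raises(ValueError, match="invertible"):
            CalibrationParams(acc_scale=np.zeros((3, 3)))


def _alignment_recordings(R_mount, acc_noise=0.0, gyr_noise=0.0, seed=0):
    """Standing + squats as seen by a sensor mounted with rotation R_mount
    (anatomical -> sensor is R_mount.T)."""
    rng = np.random.default_rng(seed)
    fs = 500.0
    n = int(3 * fs)
    t = np.arange(n) / fs
    g_anat = np.array([0.0, GRAVITY, 0.0])  # longitudinal = y, upright
    acc = np.tile(R_mount.T @ g_anat, (n, 1)) + rng.normal(0, acc_noise, (n, 3))
    standing = ImuRecording(t=t, acc=acc, gyr=np.zeros((n, 3)), fs=fs)
    w_anat = np.zeros((n, 3))
    w_anat[:, 2] = 1.2 * np.sin(2 * np.pi * 0.5 * t)  # flexion-extension about z
    gyr = w_anat @ R_mount + rng.normal(0, gyr_noise, (n, 3))
    squats = ImuRecording(t=t, acc=acc.copy(), gyr=gyr, fs=fs)
    return standing, squats


class TestFunctionalAlignment:
    def test_already_anatomical_sensor_gives_identity(self):
        standing, squats = _alignment_recordings(np.eye(3))
        R = ori.estimate_functional_alignment(standing, squats)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_recovers_known_mounting_rotation(self):
        R_mount = quat.to_rotation_matrix(quat.from_axis_angle([0, 0, 1], np.radians(30)))
        standing, squats = _alignment_recordings(R_mount)
        R = ori.estimate_functional_alignment(standing, squats)
        err = np.degrees(
            np.arccos(np.clip((np.trace(R @ R_mount.T) - 1) / 2, -1, 1))
        )
        assert err < 2.0

    def test_noisy_windows_recover_axes_within_2_degrees(self):
        R_mount = quat.to_rotation_matrix(
            quat.from_axis_angle([1, 1, 0.3], np.radians(20))
        )
        errs = []
        for seed in range(100):
            standing, squats = _alignment_recordings(
                R_mount, acc_noise=0.05, gyr_noise=0.02, seed=seed
            )
            R = ori.estimate_functional_alignment(standing, squats)
            errs.append(
                np.degrees(np.arccos(np.clip((np.trace(R @ R_mount.T) - 1) / 2, -1, 1)))
            )
        assert np.max(errs) < 2.0

    def test_rejects_non_static_standing(self):
        standing, squats = _alignment_recordings(np.eye(3))
        standing.acc *= 1.2  # gravity norm far outside the plausible band
        with pytest.raises(ValueError, match="not static"):
            ori.estimate_functional_alignment(standing, squats)

    def test_rejects_degenerate_squat_axis(self):
        standing, squats = _alignment_recordings(np.eye(3))
        squats.gyr = np.roll(squats.gyr, 1, axis=1) * 0  # rotate about y = longitudinal
        squats.gyr[:, 1] = 1.2 * np.sin(2 * np.pi * 0.5 * squats.t)
        with pytest.raises(ValueError, match="degenerate"):
            ori.estimate_functional_alignment(standing, squats)


class TestInitialOrientation:
    def test_gravity_along_vertical_axis_gives_identity(self):
        rec = _static_recording([0, 0, GRAVITY], T=5.0, frame="anatomical")
        q0 = ori.estimate_initial_orientation(rec)
        assert np.allclose(q0, [1, 0, 0, 0], atol=1e-12)

    def test_twenty_degree_tilt_recovered(self):
        tilt = quat.from_axis_angle([1, 0, 0], np.radians(20))
        g_body = quat.rotate_vector(quat.conjugate(tilt), np.array([0.0, 0, GRAVITY]))
        rec = _static_recording(g_body, T=5.0, frame="anatomical")
        q0 = ori.estimate_initial_orientation(rec)
        assert np.degrees(quat.geodesic_angle(q0, tilt)) < 0.5

    def test_noise_on_tilted_gravity_below_half_degree(self):
        tilt = quat.from_axis_angle([0.3, 1, 0], np.radians(15))
        g_body = quat.rotate_vector(quat.conjugate(tilt), np.array([0.0, 0, GRAVITY]))
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rec = _static_recording(g_body, T=5.0, frame="anatomical")
            rec.acc = rec.acc + rng.normal(0, 0.1, rec.acc.shape)
            q0 = ori.estimate_initial_orientation(rec)
            errs.append(np.degrees(quat.geodesic_angle(q0, tilt)))
        assert np.max(errs) < 0.5

    def test_non_static_window_warns(self):
        rec = _static_recording([0, 0, GRAVITY], gyr_vec=[0, 0.5, 0], frame="anatomical")
        with pytest.warns(RuntimeWarning, match="static"):
            ori.estimate_initial_orientation(rec)


class TestFusion:
    def test_static_consistent_input_keeps_initial_quaternion(self):
        rec = _static_recording([0, 0, GRAVITY], T=2.0, frame="anatomical")
        tr = ori.fuse_orientation(rec, np.array([1.0, 0, 0, 0]))
        dev = np.degrees(quat.geodesic_angle(tr.q, np.array([1.0, 0, 0, 0])))
        assert dev.max() < 0.01

    def test_vertical_rotation_integrates_but_cannot_be_corrected(self):
        # 90 deg/s about the vertical for 1 s: yaw follows the gyro, roll/pitch stay
        fs = 500.0
        n = int(fs)
        rec = ImuRecording(
            t=np.arange(n) / fs,
            acc=np.tile([0, 0, GRAVITY], (n, 1)),
            gyr=np.tile([0, 0, np.radians(90)], (n, 1)),
            fs=fs,
            frame="anatomical",
        )
        tr = ori.fuse_orientation(rec, np.array([1.0, 0, 0, 0]))
        psi, theta, phi = np.degrees(tr.euler[-1])
        assert abs(abs(psi) - 90) < 0.5
        assert abs(theta) < 1.0 and abs(phi) < 1.0

    def test_tumble_recovery_noise_free(self):
        rec, qs = simulate_tumble()
        q0 = quat.multiply(quat.from_axis_angle([1, 0, 0], np.radians(10)), qs[0])
        tr = ori.fuse_orientation(rec, q0)
        err = np.degrees(quat.geodesic_angle(tr.q, qs))
        assert err[int(2 * rec.fs):].max() < 2.0

    def test_tumble_recovery_with_sensor_noise(self):
        rec, qs = simulate_tumble(acc_noise=0.05, gyr_noise=0.01, seed=5)
        q0 = quat.multiply(quat.from_axis_angle([0, 1, 0], np.radians(10)), qs[0])
        tr = ori.fuse_orientation(rec, q0)
        err = np.degrees(quat.geodesic_angle(tr.q, qs))
        assert err[int(2 * rec.fs):].max() < 4.0

    def test_rejects_nan_samples(self):
        rec = _static_recording([0, 0, GRAVITY], frame="anatomical")
        rec.acc[10, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ori.fuse_orientation(rec, np.array([1.0, 0, 0, 0]))

    def test_all_outputs_unit_norm(self):
        rec, qs = simulate_tumble(T=2.0, acc_noise=0.05, gyr_noise=0.01, seed=2)
        tr = ori.fuse_orientation(rec, qs[0])
        assert np.abs(np.linalg.norm(tr.q, axis=1) - 1).max() < 1e-9


class TestRotateToGlobal:
    def test_identity_orientation_subtracts_gravity(self):
        rec = _static_recording([0.1, 0.2, GRAVITY + 0.3], frame="anatomical")
        n = len(rec)
        from swimphase.types import OrientationTrace

        tr = OrientationTrace(
            t=rec.t, q=np.tile([1.0, 0, 0, 0], (n, 1)), euler=np.zeros((n, 3))
        )
        out = ori.rotate_to_global(rec, tr)
        assert out.frame == "global"
        assert np.allclose(out.acc, [0.1, 0.2, 0.3], atol=1e-12)

    def test_static_global_recording_has_near_zero_motion_channels(self, prepared_lap):
        lap, rec_a, trace, rec_g = prepared_lap
        pre = rec_g.slice(0.5, 5.0)  # pre-lap static span
        assert np.abs(pre.acc.mean(axis=0)).max() < 0.05

    def test_length_mismatch_rejected(self, prepared_lap):
        lap, rec_a, trace, rec_g = prepared_lap
        with pytest.raises(ValueError, match="length"):
            ori.rotate_to_global(rec_a.slice(0, 1.0), trace)
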