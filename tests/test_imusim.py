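"""IMU synthesis: resampling, derivatives, ideal readings, error model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gloveforge as gf
from gloveforge._quat import quat_to_matrix
from gloveforge.errors import ValidationError
from gloveforge.imusim import GRAVITY, ImuErrorParams, ModalityErrorParams, SensorKinematics


def _clean_params(**kw):
    return ImuErrorParams(
        accel=ModalityErrorParams(**kw.get("accel", {})),
        gyro=ModalityErrorParams(**kw.get("gyro", {})),
        mag=ModalityErrorParams(**kw.get("mag", {})),
    )


def _rotz_traj(rate_hz, omega, duration=2.0):
    t = np.arange(0, duration, 1.0 / rate_hz)
    ang = omega * t
    q = np.stack([np.cos(ang / 2), 0 * t, 0 * t, np.sin(ang / 2)], axis=1)
    return t, q


class TestResample:
    def test_identity_on_same_grid(self, rng):
        t = np.arange(0, 1, 0.01)
        p = rng.standard_normal((len(t), 3)).cumsum(axis=0) * 0.001
        q = np.tile([1.0, 0, 0, 0], (len(t), 1))
        kin = gf.resample_trajectory(t, p, q, 100.0)
        assert np.allclose(kin.times, t, atol=1e-12)
        assert np.allclose(kin.p, p, atol=1e-12)

    def test_linear_position_reproduced(self):
        t = np.arange(0, 1, 0.05)
        v = np.array([0.1, -0.2, 0.3])
        p = t[:, None] * v
        kin = gf.resample_trajectory(t, p, np.tile([1.0, 0, 0, 0], (len(t), 1)), 80.0)
        assert np.allclose(kin.p, kin.times[:, None] * v, atol=1e-12)

    def test_slerp_matches_closed_form(self):
        t, q = _rotz_traj(10.0, 1.5)
        kin = gf.resample_trajectory(t, q * 0.0 + q, q, 40.0)
        expected = np.stack(
            [np.cos(1.5 * kin.times / 2), 0 * kin.times, 0 * kin.times, np.sin(1.5 * kin.times / 2)],
            axis=1,
        )
        dots = np.abs(np.sum(kin.q * expected, axis=1))
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_bad_rate_rejected(self, rng):
        t = np.arange(4.0)
        with pytest.raises(ValidationError):
            gf.resample_trajectory(t, np.zeros((4, 3)), np.tile([1.0, 0, 0, 0], (4, 1)), 0.0)


class TestLinearAcceleration:
    def test_constant_position_zero(self):
        t = np.arange(0, 1, 0.01)
        assert np.allclose(gf.linear_acceleration(np.ones((len(t), 3)), t), 0.0)

    def test_quadratic_exact(self):
        t = np.arange(0, 1, 0.01)
        p = 0.5 * GRAVITY * t[:, None] ** 2 * np.array([0, 0, 1.0])
        a = gf.linear_acceleration(p, t)
        assert np.allclose(a, [0, 0, GRAVITY], atol=1e-6)

    def test_centripetal_within_one_percent(self):
        t = np.arange(0, 2, 0.01)  # 100 Hz
        r, w = 0.1, 5.0
        p = np.stack([r * np.cos(w * t), r * np.sin(w * t), 0 * t], axis=1)
        a = gf.linear_acceleration(p, t)
        mags = np.linalg.norm(a[2:-2], axis=1)
        assert np.allclose(mags, r * w**2, rtol=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            gf.linear_acceleration(np.zeros((2, 3)), np.arange(2.0))


class TestAngularVelocity:
    def test_constant_orientation_zero(self):
        t = np.arange(0, 1, 0.01)
        q = np.tile([1.0, 0, 0, 0], (len(t), 1))
        assert np.allclose(gf.angular_velocity_quat(q, t), 0.0, atol=1e-12)
        om, res = gf.angular_velocity_matrix(quat_to_matrix(q), t)
        assert np.allclose(om, 0.0, atol=1e-12) and np.allclose(res, 0.0, atol=1e-12)

    def test_constant_rate_rotation(self):
        t, q = _rotz_traj(100.0, 2.0)
        om = gf.angular_velocity_quat(q, t)
        assert np.allclose(np.linalg.norm(om[2:-2], axis=1), 2.0, atol=1e-3)
        om_m, _ = gf.angular_velocity_matrix(quat_to_matrix(q), t)
        assert np.allclose(om_m[2:-2], [0, 0, 2.0], atol=1e-3)

    def test_quat_and_matrix_paths_agree(self):
        """ω from the quaternion derivative and from S(ω)=dR/dt·Rᵀ must agree
        (after the sensor→ground frame change) on a smooth trajectory."""
        t = np.arange(0, 2, 0.001)
        rv = np.stack(
            [
                0.3 * np.sin(2 * np.pi * 0.4 * t),
                0.2 * np.sin(2 * np.pi * 0.3 * t + 1.0),
                0.25 * np.sin(2 * np.pi * 0.5 * t + 2.0),
            ],
            axis=1,
        )
        q = np.roll(Rotation.from_rotvec(rv).as_quat(), 1, axis=-1)
        om_s = gf.angular_velocity_quat(q, t)
        om_g, res = gf.angular_velocity_matrix(quat_to_matrix(q), t)
        om_s_in_g = np.einsum("nij,nj->ni", quat_to_matrix(q), om_s)
        assert np.abs(om_s_in_g - om_g)[5:-5].max() < 1e-6
        assert res.max() < 1e-3

    def test_gyro_invariant_to_translation(self, rng):
        t = np.arange(0, 1, 0.01)
        _, q = _rotz_traj(100.0, 1.0, 1.0)
        om1 = gf.angular_velocity_quat(q, t)
        # angular velocity depends only on orientation, not on p at all
        assert om1.shape == (len(t), 3)

    def test_nonunit_quaternion_rejected(self):
        t = np.arange(0, 1, 0.01)
        q = np.tile([2.0, 0, 0, 0], (len(t), 1))
        with pytest.raises(ValidationError):
            gf.angular_velocity_quat(q, t)


class TestIdealReadings:
    def _static_kin(self, q_row, n=100):
        t = np.arange(n) / 100.0
        kin = SensorKinematics(t, np.zeros((n, 3)), np.tile(q_row, (n, 1)))
        kin.a = gf.linear_acceleration(kin.p, t)
        kin.omega = gf.angular_velocity_quat(kin.q, t)
        return kin

    def test_stationary_upright_reads_gravity(self):
        acc, gyr, mag = gf.ideal_readings(self._static_kin([1.0, 0, 0, 0]), _clean_params())
        assert np.allclose(acc, [0, 0, GRAVITY], atol=1e-9)
        assert np.allclose(gyr, 0.0, atol=1e-9)
        assert np.allclose(mag, [0, 50.0, 0], atol=1e-9)

    def test_upside_down_flips_gravity(self):
        q = [0.0, 1.0, 0.0, 0.0]  # 180° about x
        acc, _, _ = gf.ideal_readings(self._static_kin(q), _clean_params())
        assert np.allclose(acc, [0, 0, -GRAVITY], atol=1e-9)

    def test_free_fall_reads_zero(self):
        t = np.arange(0, 1, 0.01)
        p = -0.5 * GRAVITY * t[:, None] ** 2 * np.array([0, 0, 1.0])
        kin = SensorKinematics(t, p, np.tile([1.0, 0, 0, 0], (len(t), 1)))
        kin.a = gf.linear_acceleration(p, t)
        kin.omega = gf.angular_velocity_quat(kin.q, t)
        acc, _, _ = gf.ideal_readings(kin, _clean_params())
        assert np.abs(acc).max() < 0.05

    def test_magnetometer_magnitude_invariant(self, rng):
        t = np.arange(0, 1, 0.01)
        rv = 0.5 * np.sin(2 * np.pi * t)[:, None] * np.array([1.0, 0.7, -0.3])
        q = np.roll(Rotation.from_rotvec(rv).as_quat(), 1, axis=-1)
        kin = SensorKinematics(t, np.zeros((len(t), 3)), q)
        kin.a = gf.linear_acceleration(kin.p, t)
        kin.omega = gf.angular_velocity_quat(kin.q, t)
        _, _, mag = gf.ideal_readings(kin, _clean_params())
        norms = np.linalg.norm(mag, axis=1)
        assert np.ptp(norms) < 1e-9


class TestErrorModel:
    def _ideal(self, n=100_000):
        x = np.zeros((n, 3))
        return x, x.copy(), x.copy()

    def test_zero_params_is_identity(self, rng):
        t = np.arange(0, 1, 0.01)
        ideal = (rng.normal(size=(100, 3)), rng.normal(size=(100, 3)), rng.normal(size=(100, 3)))
        out = gf.apply_error_model(ideal, _clean_params(), rng)
        for a, b in zip(out, ideal):
            assert np.array_equal(a, b)

    def test_constant_bias_shifts_mean(self, rng):
        params = _clean_params(accel={"constant_bias": [0.1, 0.0, 0.0]})
        out = gf.apply_error_model(self._ideal(), params, rng)
        assert np.allclose(out[0].mean(axis=0), [0.1, 0, 0], atol=1e-12)

    def test_white_noise_scaling_law(self, rng):
        """Empirical sd equals noise_density·√(rate/2) within 5%."""
        N = 0.01
        params = _clean_params(gyro={"noise_density": [N, N, N]})
        out = gf.apply_error_model(self._ideal(), params, rng)
        assert out[1].std() == pytest.approx(N * np.sqrt(50.0), rel=0.05)

    def test_quantization_and_saturation(self, rng):
        params = _clean_params(accel={"resolution": 0.5, "measurement_range": 2.0})
        x = np.linspace(-5, 5, 101)[:, None] * np.array([1.0, 0, 0])
        out = gf.apply_error_model((x, np.zeros_like(x), np.zeros_like(x)), params, rng)
        assert out[0].max() == 2.0 and out[0].min() == -2.0
        steps = np.unique(np.round(out[0][:, 0] / 0.5) * 0.5 - out[0][:, 0])
        assert np.allclose(steps, 0.0, atol=1e-12)

    def test_misalignment_and_scale(self, rng):
        M = Rotation.from_euler("z", 2, degrees=True).as_matrix()
        params = _clean_params(accel={"axis_misalignment": M, "scale_factor": [1.1, 1.0, 1.0]})
        x = np.tile([1.0, 0, 0], (10, 1))
        out = gf.apply_error_model((x, np.zeros_like(x), np.zeros_like(x)), params, rng)
        assert np.allclose(out[0], (M @ np.array([1.1, 0, 0]))[None, :], atol=1e-12)


def test_simulate_site_end_to_end(model, rng):
    """A gesture simulated at a fingertip produces plausible gravity-scale
    accelerometer output and deterministic ideal readings."""
    take = gf.generate_take(gf.default_vocabulary()[0], model, 30.0, 2.0, rng)
    from gloveforge.synth import _poses_from_motion
    from gloveforge.hand_model import all_site_kinematics

    kins = [all_site_kinematics(model, pose) for pose in _poses_from_motion(take, model)]
    p = np.stack([k["INDEX_DISTAL"][0] for k in kins])
    q = np.stack([k["INDEX_DISTAL"][1] for k in kins])
    kin, (acc, gyr, mag) = gf.simulate_site(take.times, p, q, ImuErrorParams())
    assert kin.rate == pytest.approx(100.0)
    assert 5.0 < np.median(np.linalg.norm(acc, axis=1)) < 20.0
    kin2, (acc2, _, _) = gf.simulate_site(take.times, p, q, ImuErrorParams())
    assert np.array_equal(acc, acc2)
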