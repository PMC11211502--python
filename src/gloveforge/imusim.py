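"""Synthesis of IMU readings (accelerometer, gyroscope, magnetometer) from a
sensor site's pose trajectory, plus a parametric measurement-error model.

Conventions
-----------
* Ground frame: z-up; gravity vector g = (0, 0, −9.80665) m/s².
* The site quaternion ``q`` is the sensor attitude: it rotates sensor-frame
  vectors into the ground frame (v_ground = q ⊗ v_sensor ⊗ q*); ``R(q)`` is
  the equivalent matrix.
* Linear acceleration is the second time derivative of position (central
  differences at a uniform rate).
* Angular velocity comes from either the quaternion route
  ω_sensor = 2 q* ⊗ dq/dt (vector part) or the matrix route
  S(ω_ground) = dR/dt · Rᵀ; the two agree after rotating frames and serve as
  mutual cross-checks.
* The accelerometer measures specific force: at rest it reads +9.80665 m/s²
  on the axis pointing away from the ground — orientation is therefore
  visible in the accelerometer through the gravity decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter

from ._quat import enforce_continuity, qconj, qmult, qnormalize, quat_to_matrix, slerp_quat
from .errors import ValidationError

__all__ = [
    "GRAVITY",
    "SensorKinematics",
    "ImuErrorParams",
    "ModalityErrorParams",
    "resample_trajectory",
    "linear_acceleration",
    "angular_velocity_quat",
    "angular_velocity_matrix",
    "ideal_readings",
    "apply_error_model",
    "simulate_site",
]

GRAVITY = 9.80665  # m/s²


@dataclass
class SensorKinematics:
    """Uniformly sampled pose (and optionally derivative) trajectory of one sensor."""

    times: np.ndarray  # (n,) s, uniform
    p: np.ndarray  # (n, 3) m, ground frame
    q: np.ndarray  # (n, 4) attitude quaternions, sign-continuous
    a: np.ndarray | None = None  # (n, 3) m/s², ground frame
    omega: np.ndarray | None = None  # (n, 3) rad/s, sensor frame

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.p = np.asarray(self.p, float)
        self.q = enforce_continuity(qnormalize(np.asarray(self.q, float)))

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def R(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices, sensor → ground."""
        return quat_to_matrix(self.q)


@dataclass
class ModalityErrorParams:
    """Error parameters of one modality (accelerometer, gyroscope or magnetometer).

    Units follow the modality's output unit (m/s², rad/s, µT); noise density
    is unit/√Hz.  All defaults are the identity/no-error values.
    """

    measurement_range: float = np.inf  # saturation, symmetric ±range
    resolution: float = 0.0  # quantization step; 0 disables
    constant_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_density: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bias_instability: np.ndarray = field(default_factory=lambda: np.zeros(3))
    random_walk: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    scale_factor: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        if not self.measurement_range > 0:
            raise ValidationError("measurement_range must be positive")
        if self.resolution < 0:
            raise ValidationError("resolution must be >= 0")
        for name in ("constant_bias", "noise_density", "bias_instability", "random_walk", "scale_factor"):
            setattr(self, name, np.broadcast_to(np.asarray(getattr(self, name), float), (3,)).copy())
        self.axis_misalignment = np.asarray(self.axis_misalignment, float)


def default_mems_accel() -> ModalityErrorParams:
    """Datasheet-typical consumer MEMS accelerometer: ±16 g range, 16-bit
    resolution, ~180 µg/√Hz noise density; bias terms zero."""
    return ModalityErrorParams(
        measurement_range=16 * GRAVITY,
        resolution=2 * 16 * GRAVITY / 2**16,
        noise_density=np.full(3, 180e-6 * GRAVITY),
    )


def default_mems_gyro() -> ModalityErrorParams:
    """Datasheet-typical MEMS gyroscope: ±2000 dps, 16-bit, ~7 mdps/√Hz."""
    dps = np.pi / 180.0
    return ModalityErrorParams(
        measurement_range=2000 * dps,
        resolution=2 * 2000 * dps / 2**16,
        noise_density=np.full(3, 7e-3 * dps),
    )


@dataclass
class ImuErrorParams:
    sample_rate: float = 100.0  # Hz
    gravity: float = GRAVITY
    magnetic_field: np.ndarray = field(default_factory=lambda: np.array([0.0, 50.0, 0.0]))  # µT
    accel: ModalityErrorParams = field(default_factory=default_mems_accel)
    gyro: ModalityErrorParams = field(default_factory=default_mems_gyro)
    mag: ModalityErrorParams = field(default_factory=ModalityErrorParams)

    def __post_init__(self):
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        self.magnetic_field = np.asarray(self.magnetic_field, float)


def resample_trajectory(
    times: np.ndarray, p: np.ndarray, q: np.ndarray, rate: float
) -> SensorKinematics:
    """Resample a pose trajectory onto a uniform grid at ``rate`` Hz.

    Positions are cubic-spline interpolated; orientations are slerped between
    hemisphere-aligned neighbors.
    """
    if not rate > 0:
        raise ValidationError("rate must be positive")
    times = np.asarray(times, float)
    if len(times) < 4:
        raise ValidationError("need at least 4 frames to resample")
    duration = times[-1] - times[0]
    n = int(np.floor(duration * rate)) + 1
    new_times = times[0] + np.arange(n) / rate
    spline = CubicSpline(times, np.asarray(p, float), axis=0)
    new_p = spline(new_times)
    new_q = slerp_quat(times, np.asarray(q, float), new_times)
    return SensorKinematics(new_times, new_p, new_q)


def _uniform_dt(times: np.ndarray) -> float:
    d = np.diff(times)
    if len(d) == 0 or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("derivative routines require uniform sampling")
    return float(d[0])


def linear_acceleration(p: np.ndarray, times: np.ndarray) -> np.ndarray:
    """a = d²p/dt² by central second differences (one-sided, second order at
    the ends); ground frame."""
    p = np.asarray(p, float)
    if len(p) < 3:
        raise ValidationError("need at least 3 samples for a second derivative")
    dt = _uniform_dt(times)
    a = np.empty_like(p)
    a[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    a[0] = (2 * p[0] - 5 * p[1] + 4 * p[2] - p[3]) / dt**2 if len(p) >= 4 else a[1]
    a[-1] = (2 * p[-1] - 5 * p[-2] + 4 * p[-3] - p[-4]) / dt**2 if len(p) >= 4 else a[-2]
    return a


def _dq_dt(q: np.ndarray, dt: float) -> np.ndarray:
    dq = np.empty_like(q)
    dq[1:-1] = (q[2:] - q[:-2]) / (2 * dt)
    dq[0] = (-3 * q[0] + 4 * q[1] - q[2]) / (2 * dt)
    dq[-1] = (3 * q[-1] - 4 * q[-2] + q[-3]) / (2 * dt)
    return dq


def angular_velocity_quat(q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Sensor-frame angular velocity ω = 2 q* ⊗ dq/dt (vector part)."""
    q = np.asarray(q, float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("quaternions must be unit norm")
    q = enforce_continuity(q)
    dt = _uniform_dt(times)
    omega_quat = 2.0 * qmult(qconj(q), _dq_dt(q, dt))
    return omega_quat[..., 1:]


def angular_velocity_matrix(R: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-frame angular velocity from S(ω) = dR/dt · Rᵀ.

    R holds sensor→ground rotation matrices, shape (n, 3, 3).  Returns
    (ω_ground, residual) where residual is the Frobenius norm of the
    symmetric part of S per sample — a numerical-quality metric that is zero
    for an exact skew-symmetric S.
    """
    R = np.asarray(R, float)
    dets = np.linalg.det(R)
    if np.any(np.abs(dets - 1.0) > 1e-6):
        raise ValidationError("matrices must be proper rotations (det = 1)")
    dt = _uniform_dt(times)
    dR = np.empty_like(R)
    dR[1:-1] = (R[2:] - R[:-2]) / (2 * dt)
    dR[0] = (-3 * R[0] + 4 * R[1] - R[2]) / (2 * dt)
    dR[-1] = (3 * R[-1] - 4 * R[-2] + R[-3]) / (2 * dt)
    S = dR @ np.swapaxes(R, -1, -2)
    skew = 0.5 * (S - np.swapaxes(S, -1, -2))
    sym = 0.5 * (S + np.swapaxes(S, -1, -2))
    omega = np.stack([skew[..., 2, 1], skew[..., 0, 2], skew[..., 1, 0]], axis=-1)
    residual = np.linalg.norm(sym, axis=(-2, -1))
    return omega, residual


def ideal_readings(
    kin: SensorKinematics, params: ImuErrorParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Error-free sensor-frame readings (accel m/s², gyro rad/s, mag µT).

    accel is the specific force (a − g) rotated into the sensor frame; gyro
    is the sensor-frame angular velocity; mag is the constant ground-frame
    field rotated into the sensor frame (its magnitude is time-invariant).
    """
    a = kin.a if kin.a is not None else linear_acceleration(kin.p, kin.times)
    omega = kin.omega if kin.omega is not None else angular_velocity_quat(kin.q, kin.times)
    g_vec = np.array([0.0, 0.0, -params.gravity])
    Rt = np.swapaxes(kin.R, -1, -2)  # ground → sensor
    accel = np.einsum("nij,nj->ni", Rt, a - g_vec)
    mag = np.einsum("nij,j->ni", Rt, params.magnetic_field)
    return accel, omega, mag


def _modality_errors(
    x: np.ndarray, mp: ModalityErrorParams, fs: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(x)
    y = (mp.axis_misalignment @ (mp.scale_factor * x).T).T + mp.constant_bias
    sd_white = mp.noise_density * np.sqrt(fs / 2.0)
    if np.any(sd_white > 0):
        y = y + rng.standard_normal((n, 3)) * sd_white
    if np.any(mp.bias_instability > 0):
        # first-order-filtered (pink-ish) white noise at the stated amplitude
        w = rng.standard_normal((n, 3)) * mp.bias_instability
        y = y + lfilter([1 - 0.99], [1, -0.99], w, axis=0) / np.sqrt(1 - 0.99**2) * np.sqrt(2)
    if np.any(mp.random_walk > 0):
        inc = rng.standard_normal((n, 3)) * (mp.random_walk / np.sqrt(fs))
        y = y + np.cumsum(inc, axis=0)
    y = np.clip(y, -mp.measurement_range, mp.measurement_range)
    if mp.resolution > 0:
        y = np.round(y / mp.resolution) * mp.resolution
    return y


def apply_error_model(
    ideal: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: ImuErrorParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt ideal readings with the parametric error model.

    Per modality: y = quantize(saturate(M·diag(s)·x + b + white + bias
    instability + random walk)); the all-defaults (zero/identity) model is
    the identity map.
    """
    accel, gyro, mag = ideal
    fs = params.sample_rate
    return (
        _modality_errors(np.asarray(accel, float), params.accel, fs, rng),
        _modality_errors(np.asarray(gyro, float), params.gyro, fs, rng),
        _modality_errors(np.asarray(mag, float), params.mag, fs, rng),
    )


def simulate_site(
    times: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    params: ImuErrorParams,
    rng: np.random.Generator | None = None,
) -> tuple[SensorKinematics, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Resample a site trajectory to the IMU rate and synthesize readings.

    Returns the resampled kinematics (with a and ω filled in) and the
    (accel, gyro, mag) readings — noisy when an rng is supplied, ideal
    otherwise.
    """
    kin = resample_trajectory(times, p, q, params.sample_rate)
    kin.a = linear_acceleration(kin.p, kin.times)
    kin.omega = angular_velocity_quat(kin.q, kin.times)
    readings = ideal_readings(kin, params)
    if rng is not None:
        readings = apply_error_model(readings, params, rng)
    return kin, readings
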