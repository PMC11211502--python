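"""Unit-quaternion helpers (scalar-first, Hamilton convention).

A quaternion ``q = (w, x, y, z)`` stores the attitude of a frame: rotating a
vector ``v`` expressed in the local (sensor/bone) frame into the ground frame
is ``q ⊗ (0, v) ⊗ q*``.  All arrays are float64; batched inputs have the
quaternion on the last axis.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "qmult",
    "qconj",
    "qnormalize",
    "quat_to_matrix",
    "matrix_to_quat",
    "rotate_vector",
    "enforce_continuity",
    "slerp_quat",
    "random_quat",
]


def qmult(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2 (broadcasting over leading axes)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ v_local = v_ground."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1)).as_matrix()


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    q_xyzw = Rotation.from_matrix(R).as_quat()
    return np.roll(q_xyzw, 1, axis=-1)


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate local-frame vector(s) v into the ground frame by q."""
    return Rotation.from_quat(np.roll(np.asarray(q, float), -1, axis=-1)).apply(v)


def enforce_continuity(q: np.ndarray) -> np.ndarray:
    """Resolve antipodal sign flips so consecutive quaternions satisfy q_t·q_{t+1} ≥ 0."""
    q = np.array(q, dtype=float, copy=True)
    for i in range(1, len(q)):
        if np.dot(q[i - 1], q[i]) < 0.0:
            q[i] = -q[i]
    return q


def slerp_quat(times: np.ndarray, q: np.ndarray, new_times: np.ndarray) -> np.ndarray:
    """Spherical linear interpolation of a quaternion series onto new_times."""
    q = enforce_continuity(qnormalize(q))
    rot = Rotation.from_quat(np.roll(q, -1, axis=-1))
    interp = Slerp(np.asarray(times, float), rot)
    out = interp(np.clip(new_times, times[0], times[-1])).as_quat()
    return enforce_continuity(np.roll(out, 1, axis=-1))


def random_quat(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly distributed random rotation(s) as unit quaternions."""
    shape = (4,) if n is None else (n, 4)
    q = rng.standard_normal(shape)
    return qnormalize(q)
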