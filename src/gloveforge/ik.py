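"""Per-frame constrained inverse kinematics and take-quality diagnostics.

Each frame solves a nonlinear least-squares problem over the 26 DOF (wrist
translation + rotation and 20 finger joint angles): minimize the mean squared
distance between the model's forward-kinematics markers and the target
markers, with soft quadratic penalties for joint-limit violations.  Quality
is summarized by the mean distance error (MDE, mm) and by the constraint
violation ratio/magnitude (CVR %, CVM degrees) of the unclipped solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._quat import matrix_to_quat, quat_to_matrix
from .errors import ValidationError
from .hand_model import HandModel, Pose, forward_kinematics
from .preprocess import MarkerSequence

__all__ = [
    "JointAngleMotion",
    "IKDiagnostics",
    "IKConfig",
    "solve_frame",
    "solve_sequence",
    "clip_to_limits",
    "constraint_violations",
    "filter_takes",
    "best_k_per_activity",
]


@dataclass
class JointAngleMotion:
    """Joint-angle time series (degrees) with activity/session labels."""

    times: np.ndarray  # (n,) s, strictly increasing
    angles: pd.DataFrame  # n rows, one column per joint (degrees)
    activity: str = ""
    session: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.angles):
            raise ValidationError("times and angles length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def copy(self) -> "JointAngleMotion":
        return JointAngleMotion(
            self.times.copy(), self.angles.copy(), self.activity, self.session
        )


@dataclass
class IKDiagnostics:
    mde_mean: float  # mm
    mde_std: float  # mm
    cvr: float  # % of (frame, joint) pairs outside limits
    cvm_mean: float  # degrees past the limit, over violating pairs only
    cvm_std: float
    frame_mde: np.ndarray  # (n,) mm
    nonconverged_frames: list[int] = field(default_factory=list)


@dataclass
class IKConfig:
    limit_penalty_weight: float = 10.0  # residual weight per degree of violation
    max_iterations: int = 200
    tolerance: float = 1e-8
    mde_filter_threshold: float = 10.0  # mm
    warm_start: bool = True

    def __post_init__(self):
        if not self.mde_filter_threshold > 0:
            raise ValidationError("mde_filter_threshold must be positive")


def _pose_to_vector(model: HandModel, pose: Pose) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rotvec = Rotation.from_matrix(quat_to_matrix(pose.wrist_orientation)).as_rotvec()
    ang = np.radians([pose.angles[j] for j in model.joint_names])
    return np.concatenate([pose.wrist_position, rotvec, ang])


def _vector_to_pose(model: HandModel, x: np.ndarray) -> Pose:
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(x[3:6]).as_matrix()
    angles = dict(zip(model.joint_names, np.degrees(x[6:])))
    return Pose(angles, wrist_position=x[:3], wrist_orientation=matrix_to_quat(R))


def _mde_mm(markers: np.ndarray, targets: np.ndarray) -> float:
    return 1000.0 * float(np.mean(np.linalg.norm(markers - targets, axis=1)))


def solve_frame(
    model: HandModel,
    target_markers: np.ndarray,
    init: Pose,
    cfg: IKConfig | None = None,
) -> tuple[Pose, float]:
    """Fit one frame; returns (pose, frame MDE in mm).

    Never returns a pose worse than the initial guess: if the optimizer fails
    to improve on the start, the start is returned.
    """
    cfg = cfg or IKConfig()
    targets = np.asarray(target_markers, float)
    if targets.shape != (21, 3):
        raise ValidationError(f"target markers must be (21, 3), got {targets.shape}")
    limits = np.radians(model.limits_array())
    w = np.sqrt(cfg.limit_penalty_weight) * (180.0 / np.pi)

    def residuals(x: np.ndarray) -> np.ndarray:
        pose = _vector_to_pose(model, x)
        marker_res = (forward_kinematics(model, pose) - targets).ravel()
        ang = x[6:]
        viol = np.maximum(0.0, limits[:, 0] - ang) + np.maximum(0.0, ang - limits[:, 1])
        return np.concatenate([marker_res, w * viol])

    x0 = _pose_to_vector(model, init)
    res = least_squares(
        residuals,
        x0,
        method="trf",
        max_nfev=cfg.max_iterations * (len(x0) + 1),
        xtol=cfg.tolerance,
        ftol=cfg.tolerance,
        gtol=cfg.tolerance,
        x_scale=np.concatenate([np.full(3, 0.01), np.full(3, 0.1), np.full(20, 0.1)]),
    )
    pose = _vector_to_pose(model, res.x)
    mde = _mde_mm(forward_kinematics(model, pose), targets)
    init_mde = _mde_mm(forward_kinematics(model, init), targets)
    if mde > init_mde:
        return init, init_mde
    return pose, mde


def constraint_violations(
    motion: JointAngleMotion, model: HandModel, tol: float = 1e-6
) -> tuple[float, float, float]:
    """(CVR %, CVM mean deg, CVM std deg) of a joint-angle motion.

    CVR counts (frame, joint) pairs outside the limits by more than ``tol``
    degrees (rest angles often sit exactly on a limit, so sub-tolerance
    numerical excursions are not violations); CVM statistics are taken over
    the violating pairs only (NaN when there are none).
    """
    lims = {j.name: j.limits for j in model.joints}
    cols = [c for c in motion.angles.columns if c in lims]
    vals = motion.angles[cols].to_numpy()
    lo = np.array([lims[c][0] for c in cols])
    hi = np.array([lims[c][1] for c in cols])
    over = np.maximum(0.0, vals - hi) + np.maximum(0.0, lo - vals)
    mask = over > tol
    cvr = 100.0 * mask.sum() / over.size
    if mask.any():
        return cvr, float(over[mask].mean()), float(over[mask].std())
    return cvr, float("nan"), float("nan")


def solve_sequence(
    model: HandModel,
    seq: MarkerSequence,
    cfg: IKConfig | None = None,
    activity: str = "",
    session: str = "",
) -> tuple[JointAngleMotion, IKDiagnostics]:
    """Run per-frame IK over a preprocessed marker sequence."""
    cfg = cfg or IKConfig()
    if len(seq) == 0:
        raise ValidationError("cannot solve an empty sequence")
    frame_mde = np.empty(len(seq))
    rows = []
    init = model.zero_pose()
    flagged: list[int] = []
    for t in range(len(seq)):
        pose, mde = solve_frame(model, seq.positions[t], init, cfg)
        frame_mde[t] = mde
        rows.append([pose.angles[j] for j in model.joint_names])
        if cfg.warm_start:
            init = pose
    angles = pd.DataFrame(rows, columns=model.joint_names)
    motion = JointAngleMotion(seq.times, angles, activity=activity, session=session)
    cvr, cvm_mean, cvm_std = constraint_violations(motion, model)
    diag = IKDiagnostics(
        mde_mean=float(frame_mde.mean()),
        mde_std=float(frame_mde.std()),
        cvr=cvr,
        cvm_mean=cvm_mean,
        cvm_std=cvm_std,
        frame_mde=frame_mde,
        nonconverged_frames=flagged,
    )
    return motion, diag


def clip_to_limits(motion: JointAngleMotion, model: HandModel) -> JointAngleMotion:
    """Hard-clip every joint column into its [lo, hi] limits (idempotent)."""
    lims = {j.name: j.limits for j in model.joints}
    angles = motion.angles.copy()
    for c in angles.columns:
        if c in lims:
            angles[c] = angles[c].clip(*lims[c])
    return replace(motion, angles=angles)


def filter_takes(
    takes: list[tuple[JointAngleMotion, IKDiagnostics]], threshold_mm: float
) -> tuple[list, list]:
    """Partition takes into (kept, discarded) by mean distance error."""
    if not threshold_mm > 0:
        raise ValidationError("threshold must be positive")
    kept = [t for t in takes if t[1].mde_mean <= threshold_mm]
    discarded = [t for t in takes if t[1].mde_mean > threshold_mm]
    return kept, discarded


def best_k_per_activity(
    takes: list[tuple[JointAngleMotion, IKDiagnostics]], k: int
) -> list[tuple[JointAngleMotion, IKDiagnostics]]:
    """Keep the k lowest-MDE takes of each activity (all, if fewer exist)."""
    by_act: dict[str, list] = {}
    for t in takes:
        by_act.setdefault(t[0].activity, []).append(t)
    out = []
    for act in by_act:
        ranked = sorted(by_act[act], key=lambda t: t[1].mde_mean)
        out.extend(ranked[:k])
    return out
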