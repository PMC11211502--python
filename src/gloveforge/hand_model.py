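"""Kinematic right-hand model: 26 DOF, 21 markers, 15 candidate sensor sites.

The hand is a pure kinematic chain rooted at the wrist.  The wrist contributes
six degrees of freedom (free translation and rotation of the hand in space);
each of the five digits contributes four rotational degrees of freedom:

* non-thumb fingers — metacarpophalangeal abduction and flexion, proximal
  interphalangeal (PIP) flexion, distal interphalangeal (DIP) flexion;
* thumb — carpometacarpal (CMC) abduction and flexion, metacarpophalangeal
  (MCP) flexion, interphalangeal (IP) flexion.

6 + 5 × 4 = 26 DOF in total.  At the zero pose the hand lies flat in the
``z = 0`` plane with the fingers along +y, the thumb splayed toward +x (right
hand) and the palm facing +z; positive flexion curls a digit toward the palm.

Units: meters for lengths, degrees for joint angles in poses and motion
files.  Quaternions are scalar-first Hamilton; a bone/site quaternion rotates
local-frame vectors into the ground frame.

The 21 markers follow the common hand key-point numbering (wrist = 0, then
four points per digit from the base outward, thumb first).  The 15 candidate
sensor sites sit at mid-bone: distal/middle/proximal phalanx of each finger
and distal/proximal phalanx plus metacarpal of the thumb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ._quat import matrix_to_quat, quat_to_matrix
from .errors import ConfigurationError, ValidationError

__all__ = [
    "DIGITS",
    "MARKER_NAMES",
    "SENSOR_SITE_NAMES",
    "JointDef",
    "Pose",
    "HandModel",
    "default_model",
    "forward_kinematics",
    "sensor_frame_kinematics",
    "scale_model",
    "load_model",
    "save_model",
]

DIGITS = ("thumb", "index", "middle", "ring", "pinky")

# Bones per digit, base to tip.  The thumb's first link ("carpal") is the
# short rigid span from the wrist to the CMC joint; non-thumb metacarpals are
# rigid palm bones.  Articulated thumb bones start at the metacarpal.
_DIGIT_BONES = {
    "thumb": ("carpal", "metacarpal", "proximal", "distal"),
    "index": ("metacarpal", "proximal", "middle", "distal"),
    "middle": ("metacarpal", "proximal", "middle", "distal"),
    "ring": ("metacarpal", "proximal", "middle", "distal"),
    "pinky": ("metacarpal", "proximal", "middle", "distal"),
}

# Default bone lengths as fractions of the wrist-to-middle-fingertip distance.
# Middle-finger fractions sum to 1 by construction; the remaining digits
# follow typical adult hand proportions.
_DEFAULT_FRACTIONS = {
    "thumb": (0.12, 0.20, 0.17, 0.14),
    "index": (0.35, 0.26, 0.17, 0.145),
    "middle": (0.36, 0.28, 0.20, 0.16),
    "ring": (0.33, 0.26, 0.17, 0.145),
    "pinky": (0.31, 0.20, 0.12, 0.12),
}

# In-plane splay of each digit's base direction (degrees about +z); negative
# values rotate toward +x, i.e. toward the thumb side of a right hand.
_DEFAULT_SPLAY = {"thumb": -50.0, "index": -10.0, "middle": 0.0, "ring": 10.0, "pinky": 20.0}

_MARKER_SUFFIX = {
    "thumb": ("CMC", "MCP", "IP", "TIP"),
    "index": ("MCP", "PIP", "DIP", "TIP"),
    "middle": ("MCP", "PIP", "DIP", "TIP"),
    "ring": ("MCP", "PIP", "DIP", "TIP"),
    "pinky": ("MCP", "PIP", "DIP", "TIP"),
}

MARKER_NAMES = tuple(
    ["WRIST"] + [f"{d.upper()}_{s}" for d in DIGITS for s in _MARKER_SUFFIX[d]]
)

# Sensor-bearing bone per site: phalanges for the fingers, and the thumb's
# metacarpal in place of the middle phalanx it lacks.
_SITE_BONES = {
    "thumb": (("DISTAL", "distal"), ("PROXIMAL", "proximal"), ("METACARPAL", "metacarpal")),
    "index": (("DISTAL", "distal"), ("MIDDLE", "middle"), ("PROXIMAL", "proximal")),
    "middle": (("DISTAL", "distal"), ("MIDDLE", "middle"), ("PROXIMAL", "proximal")),
    "ring": (("DISTAL", "distal"), ("MIDDLE", "middle"), ("PROXIMAL", "proximal")),
    "pinky": (("DISTAL", "distal"), ("MIDDLE", "middle"), ("PROXIMAL", "proximal")),
}

SENSOR_SITE_NAMES = tuple(
    f"{d.upper()}_{label}" for d in DIGITS for label, _ in _SITE_BONES[d]
)

_DEFAULT_LIMITS = {
    "MCP_flex": (-20.0, 90.0),
    "MCP_abd": (-25.0, 25.0),
    "PIP": (0.0, 110.0),
    "DIP": (-10.0, 90.0),
    "CMC_flex": (-30.0, 60.0),
    "CMC_abd": (-10.0, 60.0),
    "MCP": (0.0, 60.0),
    "IP": (-10.0, 80.0),
}

_FLEX_AXIS = (1.0, 0.0, 0.0)
_ABD_AXIS = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class JointDef:
    name: str
    finger: str
    axis: tuple[float, float, float]
    limits: tuple[float, float]
    role: str

    def __post_init__(self):
        if self.limits[0] >= self.limits[1]:
            raise ConfigurationError(
                f"joint {self.name}: lower limit must be < upper limit, got {self.limits}"
            )


@dataclass
class Pose:
    """A single hand configuration: joint angles (degrees) plus the wrist frame."""

    angles: dict[str, float]
    wrist_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    wrist_orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self):
        self.wrist_position = np.asarray(self.wrist_position, dtype=float)
        self.wrist_orientation = np.asarray(self.wrist_orientation, dtype=float)
        n = np.linalg.norm(self.wrist_orientation)
        if abs(n - 1.0) > 1e-6:
            raise ValidationError(f"wrist orientation quaternion must be unit norm, got {n}")
        self.wrist_orientation = self.wrist_orientation / n


def _joint_defs() -> list[JointDef]:
    joints = []
    joints += [
        JointDef("THUMB_CMC_ABDUCTION", "thumb", _ABD_AXIS, _DEFAULT_LIMITS["CMC_abd"], "CMC_abd"),
        JointDef("THUMB_CMC_FLEXION", "thumb", _FLEX_AXIS, _DEFAULT_LIMITS["CMC_flex"], "CMC_flex"),
        JointDef("THUMB_MCP", "thumb", _FLEX_AXIS, _DEFAULT_LIMITS["MCP"], "MCP"),
        JointDef("THUMB_IP", "thumb", _FLEX_AXIS, _DEFAULT_LIMITS["IP"], "IP"),
    ]
    for d in DIGITS[1:]:
        D = d.upper()
        joints += [
            JointDef(f"{D}_ABDUCTION", d, _ABD_AXIS, _DEFAULT_LIMITS["MCP_abd"], "MCP_abd"),
            JointDef(f"{D}_MCP_FLEXION", d, _FLEX_AXIS, _DEFAULT_LIMITS["MCP_flex"], "MCP_flex"),
            JointDef(f"{D}_PIP", d, _FLEX_AXIS, _DEFAULT_LIMITS["PIP"], "PIP"),
            JointDef(f"{D}_DIP", d, _FLEX_AXIS, _DEFAULT_LIMITS["DIP"], "DIP"),
        ]
    return joints


@dataclass
class HandModel:
    """Right-hand kinematic model (bone lengths in meters, splay in degrees)."""

    bone_lengths: dict[str, float]
    joints: list[JointDef] = field(default_factory=_joint_defs)
    splay_deg: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SPLAY))

    def __post_init__(self):
        for name, L in self.bone_lengths.items():
            if not L > 0:
                raise ConfigurationError(f"bone {name} has non-positive length {L}")
        expected = {f"{d.upper()}_{b.upper()}" for d in DIGITS for b in _DIGIT_BONES[d]}
        if set(self.bone_lengths) != expected:
            raise ConfigurationError("bone set does not match the 20-bone hand topology")
        per_finger = {d: sum(1 for j in self.joints if j.finger == d) for d in DIGITS}
        if any(n != 4 for n in per_finger.values()):
            raise ConfigurationError(f"each digit must have 4 DOF, got {per_finger}")
        if self.dof_count != 26:
            raise ConfigurationError(f"model must expose 26 DOF, got {self.dof_count}")
        assert len(MARKER_NAMES) == 21 and len(SENSOR_SITE_NAMES) == 15

    # -- structural accessors -------------------------------------------------
    @property
    def dof_count(self) -> int:
        # 6 wrist DOF (3 translation + 3 rotation) plus the articulated joints.
        return 6 + len(self.joints)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    @property
    def markers(self) -> tuple[str, ...]:
        return MARKER_NAMES

    @property
    def sensor_sites(self) -> tuple[str, ...]:
        return SENSOR_SITE_NAMES

    @property
    def hand_length(self) -> float:
        """Wrist-to-middle-fingertip distance at rest (m)."""
        return sum(self.bone_lengths[f"MIDDLE_{b.upper()}"] for b in _DIGIT_BONES["middle"])

    def digit_length(self, digit: str) -> float:
        """Total phalanx length of a digit (crease-to-tip, excluding the palm bone)."""
        bones = _DIGIT_BONES[digit][1:] if digit == "thumb" else _DIGIT_BONES[digit][1:]
        return sum(self.bone_lengths[f"{digit.upper()}_{b.upper()}"] for b in bones)

    @property
    def finger_ratios(self) -> dict[str, float]:
        ref = self.digit_length("middle")
        return {d: self.digit_length(d) / ref for d in DIGITS}

    def joint(self, name: str) -> JointDef:
        for j in self.joints:
            if j.name == name:
                return j
        raise ConfigurationError(f"unknown joint {name!r}")

    def limits_array(self) -> np.ndarray:
        return np.array([j.limits for j in self.joints])

    def zero_pose(self) -> Pose:
        return Pose({j.name: 0.0 for j in self.joints})

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "bone_lengths": {k: float(v) for k, v in self.bone_lengths.items()},
            "splay_deg": {k: float(v) for k, v in self.splay_deg.items()},
            "joints": [
                {
                    "name": j.name,
                    "finger": j.finger,
                    "axis": list(j.axis),
                    "limits": list(j.limits),
                    "role": j.role,
                }
                for j in self.joints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HandModel":
        joints = [
            JointDef(j["name"], j["finger"], tuple(j["axis"]), tuple(j["limits"]), j["role"])
            for j in d["joints"]
        ]
        return cls(dict(d["bone_lengths"]), joints, dict(d["splay_deg"]))


def default_model(hand_length: float = 0.193) -> HandModel:
    """Build the default model scaled to the given hand length (m)."""
    if not hand_length > 0:
        raise ValidationError("hand_length must be positive")
    lengths = {
        f"{d.upper()}_{b.upper()}": frac * hand_length
        for d in DIGITS
        for b, frac in zip(_DIGIT_BONES[d], _DEFAULT_FRACTIONS[d])
    }
    return HandModel(lengths)


def _rotz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotx(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _digit_chain(model: HandModel, pose: Pose, digit: str, R_w: np.ndarray, p_w: np.ndarray):
    """Frames and endpoints of one digit's bones.

    Returns a list of ``(bone_name, R, start, end)`` base-to-tip, where R maps
    bone-local vectors (bone axis = +y) to the ground frame.
    """
    D = digit.upper()
    L = [model.bone_lengths[f"{D}_{b.upper()}"] for b in _DIGIT_BONES[digit]]
    a = pose.angles
    R0 = R_w @ _rotz(model.splay_deg[digit])
    ey = np.array([0.0, 1.0, 0.0])
    out = []
    if digit == "thumb":
        rots_after = [
            _rotz(a["THUMB_CMC_ABDUCTION"]) @ _rotx(a["THUMB_CMC_FLEXION"]),
            _rotx(a["THUMB_MCP"]),
            _rotx(a["THUMB_IP"]),
        ]
    else:
        rots_after = [
            _rotz(a[f"{D}_ABDUCTION"]) @ _rotx(a[f"{D}_MCP_FLEXION"]),
            _rotx(a[f"{D}_PIP"]),
            _rotx(a[f"{D}_DIP"]),
        ]
    R = R0
    start = p_w
    for i, bone in enumerate(_DIGIT_BONES[digit]):
        end = start + L[i] * (R @ ey)
        out.append((f"{D}_{bone.upper()}", R, start, end))
        if i < 3:
            R = R @ rots_after[i]
            start = end
    return out


def _check_pose(model: HandModel, pose: Pose) -> None:
    model_set = set(model.joint_names)
    pose_set = set(pose.angles)
    if pose_set != model_set:
        missing = model_set - pose_set
        extra = pose_set - model_set
        raise ConfigurationError(f"pose/model joint mismatch: missing={missing}, unknown={extra}")


def forward_kinematics(model: HandModel, pose: Pose) -> np.ndarray:
    """Ground-frame positions of the 21 markers for a pose, shape (21, 3)."""
    _check_pose(model, pose)
    R_w = quat_to_matrix(pose.wrist_orientation)
    p_w = pose.wrist_position
    markers = np.empty((21, 3))
    markers[0] = p_w
    idx = 1
    for digit in DIGITS:
        for _, _, _, end in _digit_chain(model, pose, digit, R_w, p_w):
            markers[idx] = end
            idx += 1
    return markers


def sensor_frame_kinematics(
    model: HandModel, pose: Pose, site: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-frame position and orientation quaternion of a sensor site.

    The site sits at the midpoint of its bone with its frame aligned to the
    bone frame (+y along the bone, +z off the bone's dorsal face); the
    returned quaternion rotates site-local vectors into the ground frame.
    """
    if site not in SENSOR_SITE_NAMES:
        raise ConfigurationError(f"unknown sensor site {site!r}")
    _check_pose(model, pose)
    digit = site.split("_")[0].lower()
    label = site[len(digit) + 1 :]
    bone_kind = dict(_SITE_BONES[digit])[label]
    bone_name = f"{digit.upper()}_{bone_kind.upper()}"
    R_w = quat_to_matrix(pose.wrist_orientation)
    for name, R, start, end in _digit_chain(model, pose, digit, R_w, pose.wrist_position):
        if name == bone_name:
            return 0.5 * (start + end), matrix_to_quat(R)
    raise ConfigurationError(f"site {site!r} maps to unknown bone {bone_name!r}")


def all_site_kinematics(model: HandModel, pose: Pose) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Position and attitude quaternion of every sensor site for one pose.

    Computes each digit chain once, so it is the preferred call when all 15
    sites are needed per frame (e.g. whole-glove IMU simulation).
    """
    _check_pose(model, pose)
    R_w = quat_to_matrix(pose.wrist_orientation)
    frames = {}
    for digit in DIGITS:
        for name, R, start, end in _digit_chain(model, pose, digit, R_w, pose.wrist_position):
            frames[name] = (R, start, end)
    out = {}
    for site in SENSOR_SITE_NAMES:
        digit = site.split("_")[0].lower()
        label = site[len(digit) + 1 :]
        bone = f"{digit.upper()}_{dict(_SITE_BONES[digit])[label].upper()}"
        R, start, end = frames[bone]
        out[site] = (0.5 * (start + end), matrix_to_quat(R))
    return out


def scale_model(model: HandModel, hand_length: float, index_ring_ratio: float) -> HandModel:
    """Rescale a model to a target hand length and index:ring digit-length ratio.

    The whole hand is scaled uniformly to the target wrist-to-middle-fingertip
    length; then the index and ring phalanges are adjusted reciprocally (their
    geometric-mean length is preserved) until the ratio of their total
    phalanx lengths equals ``index_ring_ratio``.  All other proportions are
    inherited from the base model.
    """
    if not (hand_length > 0 and index_ring_ratio > 0):
        raise ValidationError("hand_length and index_ring_ratio must be positive")
    s = hand_length / model.hand_length
    lengths = {k: v * s for k, v in model.bone_lengths.items()}
    r0 = model.digit_length("index") / model.digit_length("ring")
    f = np.sqrt(index_ring_ratio / r0)
    for b in ("PROXIMAL", "MIDDLE", "DISTAL"):
        lengths[f"INDEX_{b}"] *= f
        lengths[f"RING_{b}"] /= f
    return replace(model, bone_lengths=lengths)


def save_model(model: HandModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=True)


def load_model(path) -> HandModel:
    with open(path) as fh:
        return HandModel.from_dict(yaml.safe_load(fh))
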