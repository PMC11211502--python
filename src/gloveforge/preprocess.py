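"""Raw key-point sequences → model-compatible marker sequences.

Monocular hand key-point estimators produce trajectories in an arbitrary,
frame-varying coordinate system with drifting bone lengths.  Before inverse
kinematics, each take is therefore (1) mirrored to a right hand if needed,
(2) per-segment rescaled so every bone matches the model's rest length,
(3) translated so the wrist key-point coincides with the model wrist, and
(4) rigidly rotated per frame onto the model's rest markers with the Kabsch
algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, ValidationError
from .hand_model import DIGITS, HandModel, forward_kinematics

__all__ = [
    "MarkerSequence",
    "SEGMENTS",
    "mirror_to_right",
    "detect_handedness",
    "scale_segments",
    "translate_to_wrist",
    "kabsch_rotation",
    "preprocess_sequence",
]

# The 20 kinematic segments of the key-point topology as (parent, child)
# marker indices: wrist → digit base, then along each digit.
SEGMENTS: list[tuple[int, int]] = []
for _d in range(5):
    base = 1 + 4 * _d
    SEGMENTS.append((0, base))
    SEGMENTS += [(base + k, base + k + 1) for k in range(3)]

# Segment order matches the bone naming of the hand model.
_SEGMENT_BONES = [
    f"{d.upper()}_{b.upper()}"
    for d, bones in zip(
        DIGITS,
        (
            ("carpal", "metacarpal", "proximal", "distal"),
            ("metacarpal", "proximal", "middle", "distal"),
            ("metacarpal", "proximal", "middle", "distal"),
            ("metacarpal", "proximal", "middle", "distal"),
            ("metacarpal", "proximal", "middle", "distal"),
        ),
    )
    for b in bones
]


@dataclass
class MarkerSequence:
    """Timestamped 21-marker trajectory."""

    times: np.ndarray  # (n,) seconds, strictly increasing
    positions: np.ndarray  # (n, 21, 3)
    handedness: str = "right"  # {"left", "right"}
    source: str = "mocap"  # {"mocap", "video_keypoints"}

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (21, 3):
            raise ValidationError(f"positions must be (n, 21, 3), got {self.positions.shape}")
        if len(self.times) != len(self.positions):
            raise ValidationError("times and positions length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.handedness not in ("left", "right"):
            raise ValidationError(f"handedness must be left/right, got {self.handedness!r}")

    def __len__(self) -> int:
        return len(self.times)


def detect_handedness(frame: np.ndarray) -> str:
    """Infer chirality of one 21x3 frame from the signed volume of the
    tetrahedron (wrist, index MCP, pinky MCP, middle fingertip)."""
    v1 = frame[5] - frame[0]
    v2 = frame[17] - frame[0]
    v3 = frame[12] - frame[0]
    vol = np.dot(np.cross(v1, v2), v3)
    return "right" if vol >= 0 else "left"


def mirror_to_right(seq: MarkerSequence) -> MarkerSequence:
    """Reflect a left-hand take about the wrist's sagittal plane (x → −x)."""
    if seq.handedness == "right":
        warnings.warn("sequence is already right-handed; mirroring skipped")
        return seq
    wrist_x = seq.positions[:, :1, :1]  # (n,1,1) per-frame wrist x
    pos = seq.positions.copy()
    pos[..., 0] = 2.0 * wrist_x[..., 0] - pos[..., 0]
    return replace(seq, positions=pos, handedness="right")


def scale_segments(seq: MarkerSequence, model: HandModel) -> MarkerSequence:
    """Rescale every kinematic segment to the model's bone length, per frame.

    Proceeds from the wrist outward so the chain stays connected; the wrist
    marker is left in place.  A zero-length input segment inherits the
    previous frame's direction (first frame: error).
    """
    if seq.handedness != "right":
        raise ValidationError("scale_segments expects a right-handed sequence")
    pos = seq.positions
    out = np.empty_like(pos)
    out[:, 0] = pos[:, 0]
    target = np.array([model.bone_lengths[b] for b in _SEGMENT_BONES])
    prev_dir = np.zeros((len(SEGMENTS), 3))
    for t in range(len(seq)):
        for k, (i, j) in enumerate(SEGMENTS):
            v = pos[t, j] - pos[t, i]
            n = np.linalg.norm(v)
            if n < 1e-12:
                if t == 0:
                    raise ValidationError(
                        f"zero-length segment {i}->{j} in the first frame; direction undefined"
                    )
                d = prev_dir[k]
            else:
                d = v / n
            prev_dir[k] = d
            out[t, j] = out[t, i] + target[k] * d
    return replace(seq, positions=out)


def translate_to_wrist(
    seq: MarkerSequence, model: HandModel, target: np.ndarray | None = None
) -> MarkerSequence:
    """Shift every frame so the wrist marker lands on the model wrist (origin
    by default)."""
    tgt = np.zeros(3) if target is None else np.asarray(target, float)
    shift = tgt - seq.positions[:, 0]  # (n, 3)
    return replace(seq, positions=seq.positions + shift[:, None, :])


def kabsch_rotation(P: np.ndarray, Q: np.ndarray, center: bool = True) -> np.ndarray:
    """Optimal proper rotation R minimizing Σ‖R·Pᵢ − Qᵢ‖² (Kabsch, via SVD).

    P and Q are n×3 paired point sets, centered internally by default; pass
    ``center=False`` when both sets are already expressed about a common
    anchor (e.g. the wrist) and the rotation should pivot about it.  A
    reflection in the SVD solution is corrected by flipping the smallest
    singular direction, so det(R) = +1 always.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValidationError("kabsch_rotation needs matching n>=3 point sets of shape (n, 3)")
    if center:
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
    else:
        Pc, Qc = P, Q
    H = Pc.T @ Qc
    if np.linalg.matrix_rank(Pc, tol=1e-10) < 2:
        raise AlignmentError("point set is rank-deficient; rotation is not determined")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


# Markers rigid with respect to the wrist frame: the wrist itself, the thumb
# CMC and the four finger MCP knuckles.  Finger flexion never moves them, so
# aligning on this subset recovers the wrist orientation exactly for any
# pose, whereas an all-21 alignment of a flexed hand onto the flat rest pose
# is biased by the fingers.
PALM_MARKERS = (0, 1, 5, 9, 13, 17)


def preprocess_sequence(
    seq: MarkerSequence, model: HandModel, alignment_markers=PALM_MARKERS
) -> MarkerSequence:
    """Full mirror → scale → translate → per-frame Kabsch pipeline.

    Output markers are in meters in the model's ground frame, per-frame
    rigidly aligned to the model's rest-pose markers (the reference the IK
    subsequently fits against).  ``alignment_markers`` selects the Kabsch
    correspondence subset; the default palm set makes forward-kinematics
    output an exact fixed point of the pipeline.  Pass ``range(21)`` to align
    on all key-points instead.
    """
    if seq.handedness == "left":
        seq = mirror_to_right(seq)
    seq = scale_segments(seq, model)
    seq = translate_to_wrist(seq, model)
    rest = forward_kinematics(model, model.zero_pose())
    pos = seq.positions.copy()
    wrist = rest[0]
    idx = list(alignment_markers)
    for t in range(len(seq)):
        # Anchor the rotation at the wrist so the translation step's
        # wrist coincidence survives; uncentered Kabsch then minimizes the
        # actual wrist-pivoted alignment cost (never worse than no rotation).
        R = kabsch_rotation(pos[t, idx] - wrist, rest[idx] - wrist, center=False)
        pos[t] = (pos[t] - wrist) @ R.T + wrist
    return replace(seq, positions=pos, source=seq.source)
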