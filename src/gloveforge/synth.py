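"""Synthetic gesture data: joint-angle takes, noisy marker projections, and
labeled multi-subject benchmarks.

Templates describe a gesture as key poses at fractional times with smoothstep
transitions; per-take jitter perturbs key-pose angles and duration so repeated
takes differ like repeated human executions.  ``project_to_markers`` turns a
joint-angle take back into 21-key-point trajectories with controllable
isotropic noise, per-frame scale drift and random rigid motion — emulating
the failure modes of monocular key-point estimators that the preprocessing
stage corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._quat import random_quat
from .augment import HandDimensionDistribution, sample_hand_dimensions
from .errors import ValidationError
from .hand_model import (
    HandModel,
    Pose,
    all_site_kinematics,
    forward_kinematics,
    scale_model,
)
from .ik import JointAngleMotion
from .imusim import ImuErrorParams, simulate_site
from .pipeline import SensorRecording
from .placement import MotionDataset

__all__ = [
    "GestureTemplate",
    "default_vocabulary",
    "generate_take",
    "project_to_markers",
    "build_benchmark",
    "make_pinch_dataset",
    "motions_to_recordings",
]


@dataclass
class GestureTemplate:
    """Key-pose description of a gesture.

    ``key_poses`` maps fractional times in [0, 1] (strictly increasing) to
    partial angle maps; unspecified joints rest at 0°.  Transitions are
    smoothstep (3t² − 2t³), which keeps every joint within the envelope of
    its key-pose values.
    """

    name: str
    key_poses: list[tuple[float, dict[str, float]]]
    jitter_deg: float = 2.0
    duration_sd: float = 0.1  # seconds

    def __post_init__(self):
        fracs = [f for f, _ in self.key_poses]
        if any(b <= a for a, b in zip(fracs, fracs[1:])) or not fracs:
            raise ValidationError("key-pose time fractions must be strictly increasing")
        if fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValidationError("key poses must start at 0 and end at 1")


_FIST = {
    **{f"{d}_MCP_FLEXION": 80.0 for d in ("INDEX", "MIDDLE", "RING", "PINKY")},
    **{f"{d}_PIP": 95.0 for d in ("INDEX", "MIDDLE", "RING", "PINKY")},
    **{f"{d}_DIP": 60.0 for d in ("INDEX", "MIDDLE", "RING", "PINKY")},
    "THUMB_CMC_FLEXION": 40.0,
    "THUMB_MCP": 40.0,
    "THUMB_IP": 30.0,
}

_THUMBS_UP = {k: v for k, v in _FIST.items() if not k.startswith("THUMB")}

_ROCKER = {
    **{f"{d}_MCP_FLEXION": 80.0 for d in ("MIDDLE", "RING")},
    **{f"{d}_PIP": 95.0 for d in ("MIDDLE", "RING")},
    **{f"{d}_DIP": 60.0 for d in ("MIDDLE", "RING")},
    "THUMB_CMC_FLEXION": 30.0,
    "THUMB_MCP": 30.0,
}

_SPREAD = {
    "THUMB_CMC_ABDUCTION": 40.0,
    "INDEX_ABDUCTION": -20.0,
    "MIDDLE_ABDUCTION": -5.0,
    "RING_ABDUCTION": 15.0,
    "PINKY_ABDUCTION": 22.0,
}

_CLICK_ONE = {"INDEX_MCP_FLEXION": 50.0, "INDEX_PIP": 40.0, "INDEX_DIP": 25.0}
_CLICK_TWO = {
    **_CLICK_ONE,
    "MIDDLE_MCP_FLEXION": 50.0,
    "MIDDLE_PIP": 40.0,
    "MIDDLE_DIP": 25.0,
}


def _updown(name: str, peak: dict[str, float], **kw) -> GestureTemplate:
    return GestureTemplate(name, [(0.0, {}), (0.5, peak), (1.0, {})], **kw)


def default_vocabulary() -> list[GestureTemplate]:
    """Case-study-style vocabulary: neutral → gesture apex → neutral."""
    return [
        _updown("fist", _FIST),
        _updown("thumbs_up", _THUMBS_UP),
        _updown("rocker", _ROCKER),
        _updown("spread", _SPREAD),
        _updown("click_one_finger", _CLICK_ONE),
        _updown("click_two_fingers", _CLICK_TWO),
    ]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3.0 - 2.0 * t)


def generate_take(
    template: GestureTemplate,
    model: HandModel,
    rate: float,
    duration: float,
    rng: np.random.Generator,
    session: str = "s0",
    clip_limits: bool = True,
) -> JointAngleMotion:
    """One jittered execution of a gesture template as a joint-angle take."""
    if not (rate > 0 and duration > 0):
        raise ValidationError("rate and duration must be positive")
    duration = max(2.0 / rate, duration + rng.normal(0.0, template.duration_sd))
    n = int(round(duration * rate))
    times = np.arange(n) / rate
    limits = {j.name: j.limits for j in model.joints}
    cols = model.joint_names
    # jittered key-pose matrix: (n_key, n_joints)
    key_t = np.array([f for f, _ in template.key_poses]) * times[-1]
    key_vals = np.zeros((len(template.key_poses), len(cols)))
    for k, (_, angle_map) in enumerate(template.key_poses):
        for j, c in enumerate(cols):
            v = angle_map.get(c, 0.0)
            if template.jitter_deg > 0:
                v += rng.normal(0.0, template.jitter_deg)
            if clip_limits:
                v = float(np.clip(v, *limits[c]))
            key_vals[k, j] = v
    X = np.empty((n, len(cols)))
    seg = np.searchsorted(key_t, times, side="right") - 1
    seg = np.clip(seg, 0, len(key_t) - 2)
    span = key_t[seg + 1] - key_t[seg]
    frac = np.where(span > 0, (times - key_t[seg]) / np.where(span > 0, span, 1.0), 0.0)
    w = _smoothstep(np.clip(frac, 0.0, 1.0))[:, None]
    X = (1 - w) * key_vals[seg] + w * key_vals[seg + 1]
    angles = pd.DataFrame(X, columns=cols)
    return JointAngleMotion(times, angles, activity=template.name, session=session)


def _poses_from_motion(motion: JointAngleMotion, model: HandModel) -> list[Pose]:
    cols = model.joint_names
    vals = motion.angles[cols].to_numpy()
    return [Pose(dict(zip(cols, row))) for row in vals]


def project_to_markers(
    motion: JointAngleMotion,
    model: HandModel,
    noise_sd_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    scale_drift: bool = False,
    rigid_jitter: bool = False,
):
    """Forward-project a joint-angle take to a 21-marker sequence.

    Optional corruptions per frame: isotropic Gaussian position noise,
    uniform scale drift in [0.8, 1.2] about the wrist, and a random rigid
    rotation/translation — together mimicking monocular depth/scale
    ambiguity.  Returns a right-handed MarkerSequence.
    """
    from .preprocess import MarkerSequence
    from ._quat import quat_to_matrix

    rng = rng or np.random.default_rng()
    frames = []
    for pose in _poses_from_motion(motion, model):
        m = forward_kinematics(model, pose)
        if scale_drift:
            s = rng.uniform(0.8, 1.2)
            m = m[0] + s * (m - m[0])
        if rigid_jitter:
            R = quat_to_matrix(random_quat(rng))
            t = rng.uniform(-0.2, 0.2, size=3)
            m = m @ R.T + t
        if noise_sd_mm > 0:
            m = m + rng.normal(0.0, noise_sd_mm / 1000.0, size=m.shape)
        frames.append(m)
    return MarkerSequence(motion.times, np.stack(frames), handedness="right", source="mocap")


def build_benchmark(
    vocabulary: list[GestureTemplate],
    n_subjects: int,
    takes_per_gesture: int,
    rng: np.random.Generator,
    rate: float = 30.0,
    duration: float = 3.0,
    dist: HandDimensionDistribution | None = None,
) -> tuple[MotionDataset, dict[str, HandModel]]:
    """Labeled multi-subject benchmark: takes_per_gesture takes of each
    gesture for each subject, each subject with sampled hand dimensions.

    Returns the dataset and a subject → scaled-model map.
    """
    dist = dist or HandDimensionDistribution()
    from .hand_model import default_model

    base = default_model()
    subjects = {}
    takes = []
    for i in range(n_subjects):
        sid = f"subj{i}"
        length, ratio = sample_hand_dimensions(dist, rng)
        subjects[sid] = scale_model(base, length, ratio)
        for tmpl in vocabulary:
            for k in range(takes_per_gesture):
                takes.append(
                    generate_take(
                        tmpl, base, rate, duration, rng, session=f"{sid}_take{k}"
                    )
                )
    return MotionDataset(takes), subjects


# --- the "pinch" construction: a vocabulary with known-optimal sensor sites ---

_ACTIVE = {
    # joint → (offset deg, amplitude deg); mid-range offsets keep motion in-limits
    "THUMB_CMC_FLEXION": (15.0, 25.0),
    "THUMB_CMC_ABDUCTION": (25.0, 20.0),
    "THUMB_MCP": (30.0, 20.0),
    "THUMB_IP": (35.0, 30.0),
    "INDEX_MCP_FLEXION": (35.0, 30.0),
    "INDEX_ABDUCTION": (0.0, 10.0),
    "INDEX_PIP": (50.0, 40.0),
    "INDEX_DIP": (30.0, 25.0),
}

# Distinct integer frequencies (Hz·duration) make same-finger joints mutually
# near-orthogonal over the take.
_JOINT_FREQ = {
    "THUMB_CMC_FLEXION": 1,
    "THUMB_CMC_ABDUCTION": 2,
    "THUMB_MCP": 3,
    "THUMB_IP": 4,
    "INDEX_MCP_FLEXION": 5,
    "INDEX_ABDUCTION": 6,
    "INDEX_PIP": 7,
    "INDEX_DIP": 8,
}

# class → (thumb amplitude gain, index amplitude gain, frequency multiplier)
_PINCH_CLASSES = {
    "thumb_roll": (1.0, 0.15, 1),
    "index_tap": (0.15, 1.0, 1),
    "pinch_fast": (1.0, 1.0, 2),
}


def make_pinch_dataset(
    rng: np.random.Generator,
    n_sessions: int = 6,
    duration: float = 2.0,
    rate: float = 50.0,
    model: HandModel | None = None,
) -> MotionDataset:
    """Three-class vocabulary in which thumb and index are independent actors
    and middle/ring/pinky mirror one another.

    By construction the thumb/index sites carry all class information (their
    inter-finger independence is ≈1 and their joints are mutually
    near-uncorrelated) while middle, ring and pinky are mutually redundant
    and class-uninformative — so a correct importance ranking must place
    thumb/index sites on top.
    """
    from .hand_model import default_model

    model = model or default_model()
    cols = model.joint_names
    n = int(round(duration * rate))
    times = np.arange(n) / rate
    takes = []
    for cls, (g_thumb, g_index, fmult) in _PINCH_CLASSES.items():
        for s in range(n_sessions):
            X = pd.DataFrame(0.0, index=range(n), columns=cols)
            for joint, (off, amp) in _ACTIVE.items():
                gain = g_thumb if joint.startswith("THUMB") else g_index
                freq = _JOINT_FREQ[joint] * fmult / duration
                phase = rng.uniform(0, 2 * np.pi)
                X[joint] = off + gain * amp * np.sin(2 * np.pi * freq * times + phase)
            # middle drives ring and pinky identically: redundant fingers,
            # same distribution in every class (no class information)
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.sin(2 * np.pi * 1.5 / duration * times + phase)
            for d in ("MIDDLE", "RING", "PINKY"):
                X[f"{d}_MCP_FLEXION"] = 35.0 + 30.0 * carrier
                X[f"{d}_ABDUCTION"] = 10.0 * carrier
                X[f"{d}_PIP"] = 50.0 + 40.0 * carrier
                X[f"{d}_DIP"] = 30.0 + 25.0 * carrier
            takes.append(
                JointAngleMotion(times.copy(), X, activity=cls, session=f"s{s}")
            )
    return MotionDataset(takes)


def motions_to_recordings(
    ds: MotionDataset,
    model: HandModel,
    sites: list[str],
    params: ImuErrorParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[SensorRecording]:
    """Simulate IMU streams at the given sites for every take of a dataset.

    Channel names are ``<site>/<ax|ay|az|gx|gy|gz|mx|my|mz>``; noisy when an
    rng is supplied.  Take ids are ``<activity>/<session>``.
    """
    params = params or ImuErrorParams()
    recs = []
    for take in ds.takes:
        poses = _poses_from_motion(take, model)
        site_kin = [all_site_kinematics(model, pose) for pose in poses]
        cols, data, times_out = [], [], None
        for site in sites:
            p = np.stack([sk[site][0] for sk in site_kin])
            q = np.stack([sk[site][1] for sk in site_kin])
            kin, (acc, gyr, mag) = simulate_site(take.times, p, q, params, rng)
            times_out = kin.times
            cols += [f"{site}/{c}" for c in ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")]
            data.append(np.hstack([acc, gyr, mag]))
        take_id = f"{take.activity}/{take.session}"
        recs.append(
            SensorRecording(
                times=times_out,
                data=np.hstack(data),
                channel_names=cols,
                activity=take.activity,
                take_id=take_id,
            )
        )
    return recs
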