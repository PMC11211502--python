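"""Correlation-based ranking of the 15 candidate sensor sites.

The idea: a sensor is informative when the joints it observes move
independently of joints already observed by sensors closer to the fingertip,
and when its finger moves independently of the other fingers.  From a labeled
joint-angle dataset x_{a,s,f,j} (activity a, session s, finger f, joint j)
the module computes

* inter-joint independence  G_{f,j1,j2} = 1 − | mean_a mean_s r(x_j1, x_j2) |
* finger degree of redundancy D_{f,a} = max_{f'≠f} | mean_j mean_s r(x_f, x_f') |
* inter-finger independence H_f = 1 − min_a D_{f,a}
* importance I per site: distal = H_f; middle phalanx = G(DIP,PIP)·H_f;
  proximal = G(PIP,MCP)·G(DIP,MCP)·H_f (thumb analogues use IP/MCP/CMC).

r is the Pearson correlation; activities are weighted equally regardless of
how many sessions each has.  Sites are ranked by descending importance with
a deterministic anatomical tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hand_model import DIGITS, SENSOR_SITE_NAMES
from .ik import JointAngleMotion

__all__ = [
    "MotionDataset",
    "PlacementScores",
    "ROLE_PAIRED_JOINTS",
    "pearson",
    "inter_joint_independence",
    "finger_redundancy",
    "inter_finger_independence",
    "importance_scores",
    "candidate_sets",
]

# Joints of each finger in cross-finger role-pairing order: thumb CMC pairs
# with the finger MCP (flexion then abduction), thumb MCP with PIP, IP with
# DIP.  J = 4 joints per finger.
ROLE_PAIRED_JOINTS: dict[str, tuple[str, ...]] = {
    "thumb": ("THUMB_CMC_FLEXION", "THUMB_CMC_ABDUCTION", "THUMB_MCP", "THUMB_IP"),
    **{
        d: (
            f"{d.upper()}_MCP_FLEXION",
            f"{d.upper()}_ABDUCTION",
            f"{d.upper()}_PIP",
            f"{d.upper()}_DIP",
        )
        for d in DIGITS[1:]
    },
}

# (joint1, joint2) behind each non-distal site, and the "flexion chain" used
# by the importance products.  Distal sites carry no inter-joint term.
_SITE_JOINT_PRODUCTS: dict[str, list[tuple[str, str]]] = {}
for _d in DIGITS[1:]:
    D = _d.upper()
    _SITE_JOINT_PRODUCTS[f"{D}_DISTAL"] = []
    _SITE_JOINT_PRODUCTS[f"{D}_MIDDLE"] = [(f"{D}_DIP", f"{D}_PIP")]
    _SITE_JOINT_PRODUCTS[f"{D}_PROXIMAL"] = [
        (f"{D}_PIP", f"{D}_MCP_FLEXION"),
        (f"{D}_DIP", f"{D}_MCP_FLEXION"),
    ]
_SITE_JOINT_PRODUCTS["THUMB_DISTAL"] = []
_SITE_JOINT_PRODUCTS["THUMB_PROXIMAL"] = [("THUMB_IP", "THUMB_MCP")]
_SITE_JOINT_PRODUCTS["THUMB_METACARPAL"] = [
    ("THUMB_IP", "THUMB_CMC_FLEXION"),
    ("THUMB_MCP", "THUMB_CMC_FLEXION"),
]


@dataclass
class MotionDataset:
    """Labeled joint-angle takes; one take = one recording session of one activity."""

    takes: list[JointAngleMotion]

    def __post_init__(self):
        if any(not t.activity for t in self.takes):
            raise ValidationError("every take must carry an activity label")

    @property
    def activities(self) -> list[str]:
        return sorted({t.activity for t in self.takes})

    def sessions(self, activity: str) -> list[JointAngleMotion]:
        return [t for t in self.takes if t.activity == activity]


@dataclass
class PlacementScores:
    G: dict[tuple[str, str, str], float]  # (finger, j1, j2) → inter-joint independence
    D_fa: dict[tuple[str, str], float]  # (finger, activity) → redundancy
    H: dict[str, float]  # finger → inter-finger independence
    I: dict[str, float]  # sensor site → importance
    ranking: list[str] = field(default_factory=list)  # sites, most important first
    degenerate: bool = False  # all-zero importance (tie-break-only ranking)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 by convention when either series is constant
    ("no movement" is treated as uninformative rather than undefined)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length 1-D series")
    if len(x) < 2:
        raise ValidationError("pearson needs at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd**2))
    sy = np.sqrt(np.sum(yd**2))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.sum(xd * yd) / (sx * sy))


def inter_joint_independence(
    ds: MotionDataset, finger: str, j1: str, j2: str, abs_per_activity: bool = False
) -> float:
    """G = 1 − |r̄| with r̄ averaged over sessions then activities.

    By default the signed session/activity averages are taken first and the
    absolute value last (as the score is defined), so opposite-signed
    correlations in different activities can cancel.  ``abs_per_activity``
    switches to 1 − mean of per-activity |r̄_a|, which forbids that
    cancellation.
    """
    for t in ds.takes:
        if j1 not in t.angles.columns or j2 not in t.angles.columns:
            raise ValidationError(f"take {t.activity}/{t.session} lacks column {j1} or {j2}")
    per_activity = []
    for a in ds.activities:
        rs = [pearson(t.angles[j1].to_numpy(), t.angles[j2].to_numpy()) for t in ds.sessions(a)]
        per_activity.append(np.mean(rs))
    if abs_per_activity:
        return 1.0 - float(np.mean(np.abs(per_activity)))
    return 1.0 - abs(float(np.mean(per_activity)))


def finger_redundancy(ds: MotionDataset, finger: str, activity: str) -> float:
    """D_{f,a} = max over other fingers of |mean over role-paired joints and
    sessions of r|."""
    jf = ROLE_PAIRED_JOINTS[finger]
    best = 0.0
    for other in DIGITS:
        if other == finger:
            continue
        jo = ROLE_PAIRED_JOINTS[other]
        rs = []
        for t in ds.sessions(activity):
            for a_col, b_col in zip(jf, jo):
                rs.append(pearson(t.angles[a_col].to_numpy(), t.angles[b_col].to_numpy()))
        best = max(best, abs(float(np.mean(rs))))
    return best


def inter_finger_independence(ds: MotionDataset, finger: str) -> float:
    """H_f = 1 − min over activities of D_{f,a}."""
    return 1.0 - min(finger_redundancy(ds, finger, a) for a in ds.activities)


def importance_scores(ds: MotionDataset) -> PlacementScores:
    """Score and rank all 15 candidate sites.

    Ties are broken anatomically (thumb → pinky, distal → proximal) so the
    ranking is deterministic; an all-zero score vector is flagged degenerate.
    """
    if not ds.takes:
        raise ValidationError("dataset is empty")
    G: dict[tuple[str, str, str], float] = {}
    D_fa: dict[tuple[str, str], float] = {}
    H: dict[str, float] = {}
    for f in DIGITS:
        for a in ds.activities:
            D_fa[(f, a)] = finger_redundancy(ds, f, a)
        H[f] = 1.0 - min(D_fa[(f, a)] for a in ds.activities)
    I: dict[str, float] = {}
    for site in SENSOR_SITE_NAMES:
        finger = site.split("_")[0].lower()
        score = H[finger]
        for j1, j2 in _SITE_JOINT_PRODUCTS[site]:
            key = (finger, j1, j2)
            if key not in G:
                G[key] = inter_joint_independence(ds, finger, j1, j2)
            score *= G[key]
        I[site] = score
    order = {name: i for i, name in enumerate(SENSOR_SITE_NAMES)}
    ranking = sorted(I, key=lambda s: (-I[s], order[s]))
    return PlacementScores(
        G=G, D_fa=D_fa, H=H, I=I, ranking=ranking,
        degenerate=all(v == 0.0 for v in I.values()),
    )


def candidate_sets(scores: PlacementScores, k: int) -> tuple[list[list[str]], list[list[str]]]:
    """Nested best-i and worst-i sensor sets for i = 1..k.

    ``best[i-1]`` holds the i highest-ranked sites; ``worst[i-1]`` the i
    lowest-ranked, for best-vs-worst design comparisons.
    """
    if not 1 <= k <= len(scores.ranking):
        raise ValidationError(f"k must be in [1, {len(scores.ranking)}], got {k}")
    best = [scores.ranking[:i] for i in range(1, k + 1)]
    worst = [scores.ranking[-i:] for i in range(1, k + 1)]
    return best, worst
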