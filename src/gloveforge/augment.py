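"""Dataset enlargement: hand-size augmentation and key-pose time warping.

Hand-size augmentation exploits the fact that joint-angle trajectories are
invariant to hand geometry: each variant pairs the *unchanged* angle series
with a model rescaled to dimensions drawn from population statistics
(length ~ N(19.3 cm, 1.25 cm), index:ring digit ratio ~ N(1.0, 0.05),
truncated at ±4 sd).  The variation appears downstream when sensors are
simulated on the resized hand.

Gesture-style augmentation warps time between automatically extracted key
poses.  Key poses are prominent local extrema of the variance-trace profile
D(t) = √Tr(QQᵀ) = √(total variance of the joint-angle channels in a sliding
window), where Q collects the covariance eigenvectors scaled by the square
root of their eigenvalues.  Each inter-key-pose duration is multiplied by
(1 + u), u ~ Uniform(−0.4, 0.4); segments are Fourier-resampled to the new
length, low-pass filtered to suppress resampling end effects, and rejoined
with their endpoints pinned to the source key poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks, resample

from .errors import ValidationError
from .hand_model import HandModel, scale_model
from .ik import JointAngleMotion

__all__ = [
    "HandDimensionDistribution",
    "VarianceProfile",
    "WarpConfig",
    "sample_hand_dimensions",
    "hand_size_augment",
    "variance_trace",
    "extract_key_poses",
    "draw_warp_noise",
    "time_warp",
]


@dataclass
class HandDimensionDistribution:
    """Population statistics of hand size (meters) and index:ring digit ratio."""

    length_mean: float = 0.193
    length_sd: float = 0.0125
    index_ring_ratio_mean: float = 1.0
    index_ring_ratio_sd: float = 0.05

    def __post_init__(self):
        if not (self.length_sd > 0 and self.index_ring_ratio_sd > 0):
            raise ValidationError("standard deviations must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal draws re-drawn until within mean ± 4 sd (forbids non-physical hands)."""
    out = rng.normal(mean, sd, size=n)
    bad = np.abs(out - mean) > 4.0 * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > 4.0 * sd
    return out


def sample_hand_dimensions(
    dist: HandDimensionDistribution, rng: np.random.Generator, n: int | None = None
):
    """Draw (hand_length m, index_ring_ratio); vectorized when n is given."""
    m = 1 if n is None else n
    lengths = _truncated_normal(rng, dist.length_mean, dist.length_sd, m)
    ratios = _truncated_normal(rng, dist.index_ring_ratio_mean, dist.index_ring_ratio_sd, m)
    if n is None:
        return float(lengths[0]), float(ratios[0])
    return lengths, ratios


def hand_size_augment(
    motion: JointAngleMotion,
    base_model: HandModel,
    dist: HandDimensionDistribution,
    rng: np.random.Generator,
    n_variants: int,
) -> list[tuple[JointAngleMotion, HandModel]]:
    """Pair the unchanged motion with n resized hand models."""
    out = []
    for _ in range(n_variants):
        length, ratio = sample_hand_dimensions(dist, rng)
        out.append((motion.copy(), scale_model(base_model, length, ratio)))
    return out


@dataclass
class VarianceProfile:
    D: np.ndarray  # (n_windows,) raw √(total windowed variance)
    D_normalized: np.ndarray  # D rescaled to [0, 1] over the take
    window_length: int
    frame_index: np.ndarray  # center frame of each analysis window


def variance_trace(motion: JointAngleMotion, window_length: int) -> VarianceProfile:
    """Sliding-window motion-variance profile D = √Tr(QQᵀ).

    Per window, the covariance C of the joint-angle channels is
    eigendecomposed C = QₑΛQₑᵀ and Q = Qₑ·Λ^{1/2}, so
    Tr(QQᵀ) = Σλ = Tr(C): D is the square root of the total local variance.
    """
    if window_length < 2:
        raise ValidationError("window_length must be >= 2 frames")
    X = motion.angles.to_numpy(dtype=float)
    n = len(X)
    if window_length > n:
        raise ValidationError(f"window_length {window_length} exceeds take length {n}")
    n_win = n - window_length + 1
    D = np.empty(n_win)
    for i in range(n_win):
        W = X[i : i + window_length]
        C = np.cov(W, rowvar=False, bias=False)
        C = np.atleast_2d(C)
        lam = np.clip(np.linalg.eigvalsh(C), 0.0, None)
        D[i] = np.sqrt(lam.sum())
    rng_ = D.max() - D.min()
    Dn = (D - D.min()) / rng_ if rng_ > 0 else np.zeros_like(D)
    centers = np.arange(n_win) + window_length // 2
    return VarianceProfile(D=D, D_normalized=Dn, window_length=window_length, frame_index=centers)


@dataclass
class WarpConfig:
    noise_bound: float = 0.4  # |u| bound of the multiplicative time adjustment
    prominence_threshold: float = 0.1  # fraction of the normalized-D range
    butterworth_order: int = 4
    cutoff_fraction: float = 0.3  # low-pass cutoff as a fraction of Nyquist
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.noise_bound < 1.0):
            raise ValidationError("noise_bound must be in [0, 1)")


def extract_key_poses(profile: VarianceProfile, cfg: WarpConfig) -> np.ndarray:
    """Frame indices of prominence-qualified extrema of D, plus the endpoints.

    Local maxima and minima of the normalized profile whose prominence
    exceeds the threshold qualify; the first and last frame of the take are
    always key poses.  Takes too short for an interior extremum return the
    endpoints only.
    """
    Dn = profile.D_normalized
    w = profile.window_length
    last = int(profile.frame_index[-1] + (w - 1 - w // 2))  # final frame of the take
    if len(Dn) < 3:
        return np.array([0, last])
    peaks, _ = find_peaks(Dn, prominence=cfg.prominence_threshold)
    valleys, _ = find_peaks(-Dn, prominence=cfg.prominence_threshold)
    frames = sorted(set(profile.frame_index[np.concatenate([peaks, valleys]).astype(int)]))
    key = np.unique(np.concatenate([[0], frames, [last]]).astype(int))
    return key


def draw_warp_noise(cfg: WarpConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """The bounded multiplicative time-adjustment noise u ~ Uniform(−b, b)."""
    return rng.uniform(-cfg.noise_bound, cfg.noise_bound, size=n)


def _lowpass(seg: np.ndarray, cfg: WarpConfig) -> np.ndarray:
    if cfg.cutoff_fraction <= 0 or cfg.cutoff_fraction >= 1:
        return seg
    b, a = butter(cfg.butterworth_order, cfg.cutoff_fraction)
    padlen = 3 * max(len(a), len(b))  # scipy's filtfilt default pad
    if len(seg) <= padlen:
        return seg
    return filtfilt(b, a, seg, axis=0)


def time_warp(
    motion: JointAngleMotion,
    key_frames: np.ndarray,
    cfg: WarpConfig,
    rng: np.random.Generator,
    u: np.ndarray | None = None,
) -> JointAngleMotion:
    """Warp time between key poses by per-segment factors (1 + uᵢ).

    Each segment between consecutive key frames is Fourier-resampled to
    round(nᵢ·(1+uᵢ)) samples, low-pass filtered, then linearly corrected so
    its endpoints coincide with the source key-pose angles (which removes
    instantaneous jumps at the joins and preserves key poses exactly).
    ``u`` overrides the random draw, for reproducible bookkeeping.
    """
    key_frames = np.asarray(key_frames, int)
    if len(key_frames) < 2:
        raise ValidationError("need at least two key frames")
    X = motion.angles.to_numpy(dtype=float)
    dt = float(np.median(np.diff(motion.times)))
    n_seg = len(key_frames) - 1
    if u is None:
        u = draw_warp_noise(cfg, rng, n_seg)
    u = np.asarray(u, float)
    pieces = []
    for i in range(n_seg):
        a_idx, b_idx = key_frames[i], key_frames[i + 1]
        seg = X[a_idx : b_idx + 1]
        n_i = len(seg)
        m_i = int(round(n_i * (1.0 + u[i])))
        while m_i < 2:  # too-short segment: redraw this factor
            u[i] = draw_warp_noise(cfg, rng, 1)[0]
            m_i = int(round(n_i * (1.0 + u[i])))
        # Detrend to the segment's endpoint chord before Fourier resampling:
        # the residual is near-periodic, which suppresses wrap-around ringing.
        chord_src = np.linspace(0.0, 1.0, n_i)[:, None] * (seg[-1] - seg[0]) + seg[0]
        chord_new = np.linspace(0.0, 1.0, m_i)[:, None] * (seg[-1] - seg[0]) + seg[0]
        if m_i != n_i:
            warped = resample(seg - chord_src, m_i, axis=0) + chord_new
        else:
            warped = seg.copy()
        warped = _lowpass(warped - chord_new, cfg) + chord_new
        # Pin segment endpoints back onto the source key poses with a linear
        # ramp (removes Fourier wrap-around end effects at the joins).
        ramp = np.linspace(0.0, 1.0, m_i)[:, None]
        corr0 = seg[0] - warped[0]
        corr1 = seg[-1] - warped[-1]
        warped = warped + (1 - ramp) * corr0 + ramp * corr1
        pieces.append(warped if i == 0 else warped[1:])
    Y = np.vstack(pieces)
    times = motion.times[0] + dt * np.arange(len(Y))
    angles = pd.DataFrame(Y, columns=motion.angles.columns)
    return JointAngleMotion(times, angles, activity=motion.activity, session=motion.session)
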