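"""Training-data preparation and design evaluation for gesture recognition.

Simulated multi-sensor streams are cut into 0.5 s sliding windows with 80 %
overlap, split 0.6/0.2/0.2 at take level (augmented takes always follow
their source take's split so nothing leaks into validation/test),
standardized with train-split statistics, and fed to any classifier obeying
the fit/predict contract.  Performance is the class-support-weighted F1,
F1_c = 2TP/(2TP + FP + FN) per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._quat import quat_to_matrix, random_quat
from .errors import ValidationError

__all__ = [
    "SensorRecording",
    "WindowedDataset",
    "EvaluationReport",
    "sliding_windows",
    "split_takes",
    "normalize",
    "train_time_augment",
    "weighted_f1",
    "evaluate",
    "design_report",
    "WindowFeatureClassifier",
]


@dataclass
class SensorRecording:
    """One take's uniformly sampled multi-channel sensor stream.

    Channel names are ``"<site>/<quantity>"`` (e.g. ``"INDEX_DISTAL/ax"``)
    with the three axes of each modality contiguous.  ``source_id`` names the
    original take an augmented variant was derived from (equal to
    ``take_id`` for originals) and drives the split-leakage guard.
    """

    times: np.ndarray  # (n,)
    data: np.ndarray  # (n, C)
    channel_names: list[str]
    activity: str
    take_id: str
    source_id: str = ""
    labels: np.ndarray | None = None  # optional per-sample labels

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.data = np.asarray(self.data, float)
        if self.data.shape != (len(self.times), len(self.channel_names)):
            raise ValidationError("data shape must be (n_samples, n_channels)")
        if not self.source_id:
            self.source_id = self.take_id

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class WindowedDataset:
    windows: np.ndarray  # (N, C, S)
    labels: np.ndarray  # (N,) str
    take_ids: np.ndarray  # (N,) str
    source_ids: np.ndarray  # (N,) str
    channel_names: list[str]
    window_s: float
    overlap: float
    rate: float
    split: dict[str, str] = field(default_factory=dict)  # source take id → split

    def split_mask(self, name: str) -> np.ndarray:
        return np.array([self.split.get(s) == name for s in self.source_ids])

    def subset_channels(self, keep: list[str]) -> "WindowedDataset":
        idx = [self.channel_names.index(c) for c in keep]
        return WindowedDataset(
            self.windows[:, idx, :], self.labels, self.take_ids, self.source_ids,
            keep, self.window_s, self.overlap, self.rate, dict(self.split),
        )


def window_count(n_samples: int, window: int, stride: int) -> int:
    if n_samples < window:
        return 0
    return (n_samples - window) // stride + 1


def sliding_windows(
    recordings: list[SensorRecording], window_s: float = 0.5, overlap: float = 0.8
) -> WindowedDataset:
    """Segment recordings into fixed-length windows with fractional overlap.

    Windows lie wholly inside each stream; each is annotated with the
    activity present in the majority of its samples.  A stream shorter than
    one window contributes no windows (with a warning via numpy's empty
    concatenation being avoided).
    """
    if not recordings:
        raise ValidationError("no recordings given")
    if not (0.0 <= overlap < 1.0):
        raise ValidationError("overlap must be in [0, 1)")
    rate = recordings[0].rate
    w = int(round(window_s * rate))
    stride = max(1, int(round(w * (1.0 - overlap))))
    wins, labels, take_ids, source_ids = [], [], [], []
    for rec in recordings:
        n = len(rec.times)
        for k in range(window_count(n, w, stride)):
            a = k * stride
            wins.append(rec.data[a : a + w].T)  # (C, S)
            if rec.labels is not None:
                seg = rec.labels[a : a + w]
                vals, counts = np.unique(seg, return_counts=True)
                labels.append(vals[np.argmax(counts)])
            else:
                labels.append(rec.activity)
            take_ids.append(rec.take_id)
            source_ids.append(rec.source_id)
    if not wins:
        raise ValidationError("no stream was long enough for a single window")
    return WindowedDataset(
        np.stack(wins), np.array(labels), np.array(take_ids), np.array(source_ids),
        list(recordings[0].channel_names), window_s, overlap, rate,
    )


def split_takes(
    recordings: list[SensorRecording],
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Take-level train/val/test assignment, stratified by activity.

    Only source takes are assigned; augmented variants inherit their source
    take's split, which prevents augmented copies of a test gesture from
    reaching the training set.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValidationError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    sources: dict[str, str] = {}
    for rec in recordings:
        sources.setdefault(rec.source_id, rec.activity)
    by_act: dict[str, list[str]] = {}
    for tid in sorted(sources):
        by_act.setdefault(sources[tid], []).append(tid)
    assignment: dict[str, str] = {}
    for act, tids in sorted(by_act.items()):
        if len(tids) < 3:
            raise ValidationError(f"activity {act!r} has fewer takes ({len(tids)}) than splits")
        tids = list(tids)
        rng.shuffle(tids)
        n = len(tids)
        # largest-remainder apportionment, at least one take per split
        raw = np.array(proportions) * n
        counts = np.floor(raw).astype(int)
        counts = np.maximum(counts, 1)
        while counts.sum() > n:
            counts[np.argmax(counts)] -= 1
        order = np.argsort(-(raw - np.floor(raw)))
        i = 0
        while counts.sum() < n:
            counts[order[i % 3]] += 1
            i += 1
        names = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
        for tid, name in zip(tids, names):
            assignment[tid] = name
    return assignment


def normalize(ds: WindowedDataset) -> WindowedDataset:
    """Standardize every channel to zero mean / unit variance using statistics
    of the train split only (constant channels are mean-removed)."""
    train = ds.split_mask("train")
    if not train.any():
        raise ValidationError("train split is empty; assign splits first")
    X = ds.windows
    mu = X[train].mean(axis=(0, 2), keepdims=True)
    sd = X[train].std(axis=(0, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    out = WindowedDataset(
        (X - mu) / sd, ds.labels, ds.take_ids, ds.source_ids, list(ds.channel_names),
        ds.window_s, ds.overlap, ds.rate, dict(ds.split),
    )
    return out


def train_time_augment(
    batch: np.ndarray,
    rng: np.random.Generator,
    rotation: bool = True,
    noise_sd: float = 0.2,
) -> np.ndarray:
    """Orientation-robustness augmentation applied at each training step.

    A uniform random 3-D rotation (one per window) is applied jointly to
    every contiguous 3-channel vector triplet — the accel/gyro/mag axes of
    each sensor — and element-wise multiplicative Gaussian noise with mean 1
    and sd ``noise_sd`` is applied on top.
    """
    out = np.array(batch, float, copy=True)  # (N, C, S)
    N, C, S = out.shape
    if rotation:
        if C % 3 != 0:
            raise ValidationError("channel count must be a multiple of 3 for rotation")
        R = quat_to_matrix(random_quat(rng, N))  # (N, 3, 3)
        out = out.reshape(N, C // 3, 3, S)
        out = np.einsum("nij,ngjs->ngis", R, out).reshape(N, C, S)
    if noise_sd > 0:
        out = out * rng.normal(1.0, noise_sd, size=out.shape)
    return out


@dataclass
class EvaluationReport:
    per_class: dict[str, dict[str, float]]  # class → {tp, fp, fn, f1, support}
    weighted_f1: float
    excluded_classes: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def weighted_f1(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Per-class F1 = 2TP/(2TP+FP+FN), support-weighted average.

    Classes absent from ``y_true`` have undefined F1 and are excluded (they
    carry zero support weight anyway).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label/prediction length mismatch")
    classes = sorted(set(y_true) | set(y_pred))
    per_class = {}
    excluded = []
    total = 0.0
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        support = int(np.sum(y_true == c))
        if support == 0:
            excluded.append(c)
            continue
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        per_class[c] = {"tp": tp, "fp": fp, "fn": fn, "f1": f1, "support": support}
        total += support * f1
    wf1 = total / len(y_true) if len(y_true) else 0.0
    return EvaluationReport(per_class=per_class, weighted_f1=wf1, excluded_classes=excluded)


class WindowFeatureClassifier:
    """Fast reference classifier: per-channel summary statistics feeding a
    standardized logistic regression.

    Satisfies the pluggable contract — ``fit(windows, labels)`` and
    ``predict(windows)`` with windows shaped (N, C, S) — so heavier sequence
    models can be substituted without touching the pipeline.
    """

    def __init__(self, seed: int = 0, C: float = 1.0):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, C=C, random_state=seed),
        )

    @staticmethod
    def _features(windows: np.ndarray) -> np.ndarray:
        feats = [
            windows.mean(axis=2),
            windows.std(axis=2),
            windows.min(axis=2),
            windows.max(axis=2),
        ]
        return np.concatenate(feats, axis=1)

    def fit(self, windows: np.ndarray, labels: np.ndarray):
        self._model.fit(self._features(windows), labels)
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self._model.predict(self._features(windows))


def evaluate(model, ds: WindowedDataset, config: dict | None = None) -> EvaluationReport:
    """Train on the train split and score weighted F1 on the test split."""
    train = ds.split_mask("train")
    test = ds.split_mask("test")
    if not train.any() or not test.any():
        raise ValidationError("both train and test splits must be non-empty")
    model.fit(ds.windows[train], ds.labels[train])
    pred = model.predict(ds.windows[test])
    report = weighted_f1(ds.labels[test], pred)
    report.config = dict(config or {})
    return report


def design_report(
    candidate_sets: list[list[str]],
    ds: WindowedDataset,
    classifier_factory=None,
    worst_sets: list[list[str]] | None = None,
    seed: int = 0,
) -> dict:
    """Train one classifier per candidate sensor set and tabulate weighted F1.

    Channel selection keeps every channel whose ``<site>/`` prefix belongs to
    the set.  Parameter count of the fitted model (when exposed) is reported
    as a hardware-independent cost proxy.  Deterministic given the seed.
    """
    if not candidate_sets:
        raise ValidationError("need at least one candidate set")
    factory = classifier_factory or (lambda seed: WindowFeatureClassifier(seed=seed))

    def run(sets, tag):
        rows = []
        for sensors in sets:
            keep = [c for c in ds.channel_names if c.split("/")[0] in set(sensors)]
            sub = normalize(ds.subset_channels(keep))
            rep = evaluate(factory(seed), sub, config={"sensors": sensors, "seed": seed})
            rows.append(
                {
                    "kind": tag,
                    "n_sensors": len(sensors),
                    "sensors": list(sensors),
                    "n_channels": len(keep),
                    "weighted_f1": rep.weighted_f1,
                }
            )
        return rows

    results = run(candidate_sets, "best")
    if worst_sets:
        results += run(worst_sets, "worst")
    return {"seed": seed, "window_s": ds.window_s, "overlap": ds.overlap, "results": results}
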