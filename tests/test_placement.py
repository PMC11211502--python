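"""Joint-independence scores against brute-force oracles and invariances."""

import numpy as np
import pandas as pd
import pytest

import gloveforge as gf
from gloveforge.errors import ValidationError
from gloveforge.hand_model import DIGITS, SENSOR_SITE_NAMES
from gloveforge.ik import JointAngleMotion
from gloveforge.placement import (
    ROLE_PAIRED_JOINTS,
    MotionDataset,
    finger_redundancy,
    inter_finger_independence,
    inter_joint_independence,
    pearson,
)

ALL_JOINTS = [j for f in DIGITS for j in ROLE_PAIRED_JOINTS[f]]


def _take(data: dict, activity, session, n=None):
    n = n if n is not None else len(next(iter(data.values())))
    df = pd.DataFrame({j: data.get(j, np.zeros(n)) for j in ALL_JOINTS})
    return JointAngleMotion(np.arange(n) / 30.0, df, activity=activity, session=session)


def _random_dataset(rng, n_activities=2, n_sessions=3, n=40):
    takes = []
    for a in range(n_activities):
        for s in range(n_sessions):
            data = {j: rng.normal(size=n) for j in ALL_JOINTS}
            takes.append(_take(data, f"act{a}", f"s{s}"))
    return MotionDataset(takes)


class TestPearson:
    def test_self_correlation(self):
        x = np.array([1.0, 2.0, 4.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson(np.array([1.0, 2, 3]), np.array([6.0, 4, 2])) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # deviations (-1,0,1)·(-1,1,0): covariance 1, denominators √2·√2
        assert pearson(np.array([1.0, 2, 3]), np.array([1.0, 3, 2])) == pytest.approx(0.5)

    def test_constant_series_convention(self):
        assert pearson(np.ones(5), np.arange(5.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pearson(np.arange(3.0), np.arange(4.0))


class TestInterJointIndependence:
    def test_identical_joints_zero(self, rng):
        x = rng.normal(size=30)
        ds = MotionDataset([_take({"INDEX_PIP": x, "INDEX_DIP": x}, "a", "s0")])
        assert inter_joint_independence(ds, "index", "INDEX_DIP", "INDEX_PIP") == pytest.approx(0.0)

    def test_negated_joint_also_zero(self, rng):
        x = rng.normal(size=30)
        ds = MotionDataset([_take({"INDEX_PIP": x, "INDEX_DIP": -x}, "a", "s0")])
        assert inter_joint_independence(ds, "index", "INDEX_DIP", "INDEX_PIP") == pytest.approx(0.0)

    def test_cross_activity_cancellation(self, rng):
        """Per-activity mean correlations +1 and −1 cancel: G = 1 as printed,
        while the abs-per-activity switch gives G = 0."""
        x = rng.normal(size=30)
        ds = MotionDataset(
            [
                _take({"INDEX_PIP": x, "INDEX_DIP": x}, "a1", "s0"),
                _take({"INDEX_PIP": x, "INDEX_DIP": -x}, "a2", "s0"),
            ]
        )
        assert inter_joint_independence(ds, "index", "INDEX_DIP", "INDEX_PIP") == pytest.approx(1.0)
        assert inter_joint_independence(
            ds, "index", "INDEX_DIP", "INDEX_PIP", abs_per_activity=True
        ) == pytest.approx(0.0)


class TestFingerRedundancy:
    def test_duplicate_finger_redundancy_one(self, rng):
        data = {}
        for jf, jo in zip(ROLE_PAIRED_JOINTS["index"], ROLE_PAIRED_JOINTS["middle"]):
            x = rng.normal(size=30)
            data[jf] = x
            data[jo] = x.copy()
        ds = MotionDataset([_take(data, "a", "s0")])
        assert finger_redundancy(ds, "index", "a") == pytest.approx(1.0)

    def test_all_others_constant_zero(self, rng):
        data = {j: rng.normal(size=30) for j in ROLE_PAIRED_JOINTS["index"]}
        ds = MotionDataset([_take(data, "a", "s0")])
        assert finger_redundancy(ds, "index", "a") == 0.0

    def test_h_from_redundancies(self, rng):
        """H_f = 1 − min over activities, checked on a constructed 3-activity
        dataset with known per-activity redundancies."""
        ds = _random_dataset(rng, n_activities=3)
        D = [finger_redundancy(ds, "ring", t) for t in ds.activities]
        assert inter_finger_independence(ds, "ring") == pytest.approx(1.0 - min(D))


def _bruteforce_scores(ds):
    """Nested-loop re-implementation of the scoring chain (the oracle)."""
    acts = sorted({t.activity for t in ds.takes})

    def r(x, y):
        xd, yd = x - x.mean(), y - y.mean()
        den = np.sqrt((xd**2).sum()) * np.sqrt((yd**2).sum())
        return 0.0 if den == 0 else float((xd * yd).sum() / den)

    def G(f, j1, j2):
        vals = []
        for a in acts:
            sessions = [t for t in ds.takes if t.activity == a]
            vals.append(
                sum(r(t.angles[j1].to_numpy(), t.angles[j2].to_numpy()) for t in sessions)
                / len(sessions)
            )
        return 1.0 - abs(sum(vals) / len(vals))

    def D(f, a):
        sessions = [t for t in ds.takes if t.activity == a]
        best = 0.0
        for other in DIGITS:
            if other == f:
                continue
            tot, cnt = 0.0, 0
            for t in sessions:
                for jf, jo in zip(ROLE_PAIRED_JOINTS[f], ROLE_PAIRED_JOINTS[other]):
                    tot += r(t.angles[jf].to_numpy(), t.angles[jo].to_numpy())
                    cnt += 1
            best = max(best, abs(tot / cnt))
        return best

    H = {f: 1.0 - min(D(f, a) for a in acts) for f in DIGITS}
    I = {}
    for f in DIGITS:
        F = f.upper()
        if f == "thumb":
            I["THUMB_DISTAL"] = H[f]
            I["THUMB_PROXIMAL"] = G(f, "THUMB_IP", "THUMB_MCP") * H[f]
            I["THUMB_METACARPAL"] = (
                G(f, "THUMB_IP", "THUMB_CMC_FLEXION")
                * G(f, "THUMB_MCP", "THUMB_CMC_FLEXION")
                * H[f]
            )
        else:
            I[f"{F}_DISTAL"] = H[f]
            I[f"{F}_MIDDLE"] = G(f, f"{F}_DIP", f"{F}_PIP") * H[f]
            I[f"{F}_PROXIMAL"] = (
                G(f, f"{F}_PIP", f"{F}_MCP_FLEXION")
                * G(f, f"{F}_DIP", f"{F}_MCP_FLEXION")
                * H[f]
            )
    return H, I


class TestImportanceScores:
    def test_matches_bruteforce_oracle(self, rng):
        ds = _random_dataset(rng)
        scores = gf.importance_scores(ds)
        H, I = _bruteforce_scores(ds)
        for f in DIGITS:
            assert scores.H[f] == pytest.approx(H[f], abs=1e-12)
        for site in SENSOR_SITE_NAMES:
            assert scores.I[site] == pytest.approx(I[site], abs=1e-12)

    def test_scores_in_unit_interval(self, rng):
        scores = gf.importance_scores(_random_dataset(rng))
        assert all(0.0 <= v <= 1.0 for v in scores.I.values())
        assert all(0.0 <= v <= 1.0 for v in scores.H.values())
        assert all(0.0 <= v <= 1.0 for v in scores.D_fa.values())
        assert sorted(scores.ranking) == sorted(SENSOR_SITE_NAMES)

    def test_all_fingers_identical_degenerate(self, rng):
        x4 = [rng.normal(size=30) for _ in range(4)]
        data = {}
        for f in DIGITS:
            for j, x in zip(ROLE_PAIRED_JOINTS[f], x4):
                data[j] = x.copy()
        ds = MotionDataset([_take(data, "a", "s0")])
        scores = gf.importance_scores(ds)
        assert scores.degenerate
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in scores.I.values())

    def test_only_index_moves_tops_ranking(self, rng):
        data = {j: rng.normal(size=60) for j in ROLE_PAIRED_JOINTS["index"]}
        ds = MotionDataset([_take(data, "a", "s0")])
        scores = gf.importance_scores(ds)
        for site in ("INDEX_DISTAL", "INDEX_MIDDLE", "INDEX_PROXIMAL"):
            assert scores.I[site] > 0.8
        top = max(scores.I.values())
        assert max(scores.I[s] for s in SENSOR_SITE_NAMES if not s.startswith("INDEX")) <= top

    def test_activity_duplication_invariance(self, rng):
        """Equal per-activity weighting: duplicating all sessions of one
        activity leaves every score unchanged."""
        ds = _random_dataset(rng)
        extra = [t.copy() for t in ds.takes if t.activity == "act0"]
        for i, t in enumerate(extra):
            t.session = f"dup{i}"
        ds_dup = MotionDataset(ds.takes + extra)
        s1, s2 = gf.importance_scores(ds), gf.importance_scores(ds_dup)
        for site in SENSOR_SITE_NAMES:
            assert s1.I[site] == pytest.approx(s2.I[site], abs=1e-12)

    def test_sign_flip_invariance(self, rng):
        """Negating a whole finger leaves every score unchanged; negating a
        single joint column leaves the inter-joint independences unchanged
        (the redundancy average is signed per joint pair, so a lone flip may
        legitimately move D)."""
        ds = _random_dataset(rng)
        whole = []
        for t in ds.takes:
            c = t.copy()
            for j in ROLE_PAIRED_JOINTS["ring"]:
                c.angles[j] = -c.angles[j]
            whole.append(c)
        s1 = gf.importance_scores(ds)
        s2 = gf.importance_scores(MotionDataset(whole))
        for site in SENSOR_SITE_NAMES:
            assert s1.I[site] == pytest.approx(s2.I[site], abs=1e-12)

        single = []
        for t in ds.takes:
            c = t.copy()
            c.angles["RING_PIP"] = -c.angles["RING_PIP"]
            single.append(c)
        ds_single = MotionDataset(single)
        g1 = inter_joint_independence(ds, "ring", "RING_DIP", "RING_PIP")
        g2 = inter_joint_independence(ds_single, "ring", "RING_DIP", "RING_PIP")
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            gf.importance_scores(MotionDataset([]))


class TestCandidateSets:
    def _scores(self, rng):
        return gf.importance_scores(_random_dataset(rng))

    def test_nested_and_complete(self, rng):
        scores = self._scores(rng)
        best, worst = gf.candidate_sets(scores, 15)
        assert len(best[0]) == 1 and best[0][0] == scores.ranking[0]
        assert set(best[-1]) == set(SENSOR_SITE_NAMES)
        for i in range(14):
            assert set(best[i]) < set(best[i + 1])
            assert set(worst[i]) < set(worst[i + 1])
        assert worst[0][0] == scores.ranking[-1]

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValidationError):
            gf.candidate_sets(self._scores(rng), 0)
        with pytest.raises(ValidationError):
            gf.candidate_sets(self._scores(rng), 16)


def test_pinch_construction_ranks_thumb_index_on_top(rng):
    ds = gf.make_pinch_dataset(rng)
    scores = gf.importance_scores(ds)
    assert scores.H["thumb"] > 0.9 and scores.H["index"] > 0.9
    assert scores.H["middle"] < 0.1 and scores.H["ring"] < 0.1 and scores.H["pinky"] < 0.1
    top3 = scores.ranking[:3]
    assert all(s.startswith(("THUMB", "INDEX")) for s in top3)
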