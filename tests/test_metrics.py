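import itertools
import math

import numpy as np
import pytest

from neopose.metrics import (
    DEFAULT_KAPPAS,
    FrameScore,
    MetricConfig,
    ScaleCase,
    average_precision,
    compare_groups,
    compute_scale,
    oks,
    rescale_rmse,
    score_frames,
    stratified_report,
)
from neopose.types import Detection, TorsoAnnotation, Visibility

V, O, N = Visibility.VISIBLE, Visibility.OCCLUDED, Visibility.NOT_VISIBLE


def ann(kps, vis, frame_id="f", **labels):
    return TorsoAnnotation(frame_id=frame_id, keypoints=np.asarray(kps, float),
                           visibility=vis, **labels)


BOX_KPS = [[10.0, 5.0], [50.0, 5.0], [10.0, 30.0], [50.0, 30.0]]  # 40 x 25 box


class TestComputeScale:
    def test_four_visible_torso_box(self):
        res = compute_scale(ann(BOX_KPS, (V, V, V, V)))
        assert res.case is ScaleCase.TORSO_BOX
        assert res.s2 == pytest.approx(3.28 * 40 * 25)

    def test_opposing_corners_use_torso_box(self):
        res = compute_scale(ann(BOX_KPS, (V, N, N, V)))
        assert res.case is ScaleCase.TORSO_BOX
        assert res.s2 == pytest.approx(3.28 * 40 * 25)
        res = compute_scale(ann(BOX_KPS, (N, V, V, N)))
        assert res.case is ScaleCase.TORSO_BOX

    def test_single_side_pair_uses_height(self):
        res = compute_scale(ann(BOX_KPS, (V, N, V, N)))
        assert res.case is ScaleCase.SIDE_PAIR
        assert res.s2 == pytest.approx(2.0 * 25**2)

    def test_only_shoulders_uses_width(self):
        kps = [[0.0, 0.0], [50.0, 0.0], [0.0, 30.0], [50.0, 30.0]]
        res = compute_scale(ann(kps, (V, V, N, N)))
        assert res.case is ScaleCase.SHOULDERS
        assert res.s2 == pytest.approx(6.16 * 2500)

    def test_only_hips_uses_width(self):
        kps = [[0.0, 0.0], [50.0, 0.0], [0.0, 30.0], [20.0, 30.0]]
        res = compute_scale(ann(kps, (N, N, V, V)))
        assert res.case is ScaleCase.HIPS
        assert res.s2 == pytest.approx(13.64 * 400)

    def test_one_or_zero_visible_excluded(self):
        for vis in [(V, N, N, N), (N, N, N, N)]:
            res = compute_scale(ann(BOX_KPS, vis))
            assert res.excluded and res.case is ScaleCase.EXCLUDED

    def test_occluded_counts_by_default_but_not_in_strict_mode(self):
        res = compute_scale(ann(BOX_KPS, (O, O, O, O)))
        assert not res.excluded
        strict = MetricConfig(delta_min_visibility=Visibility.VISIBLE)
        res = compute_scale(ann(BOX_KPS, (O, O, O, O)), strict)
        assert res.excluded

    def test_cases_exhaustive_over_all_visibility_patterns(self):
        """Every one of the 3^4 visibility assignments maps to exactly one
        scale case, consistent with the number of delta = 1 key-points."""
        for vis in itertools.product([V, O, N], repeat=4):
            res = compute_scale(ann(BOX_KPS, vis))
            n_vis = sum(1 for v in vis if v >= O)
            if n_vis <= 1:
                assert res.excluded
            else:
                assert not res.excluded
                assert res.s2 > 0

    def test_degenerate_zero_extent_excluded(self):
        res = compute_scale(ann(np.zeros((4, 2)), (V, V, V, V)))
        assert res.excluded


class TestOKS:
    def test_perfect_detection_scores_one(self):
        a = ann(BOX_KPS, (V, V, V, V))
        det = Detection("f", np.asarray(BOX_KPS), np.ones(4))
        assert oks(det, a).oks == pytest.approx(1.0)

    def test_single_keypoint_closed_form_e_minus_one(self):
        a = ann(BOX_KPS, (V, V, N, N))
        scale = compute_scale(a)
        cfg = MetricConfig()
        d2 = 2.0 * cfg.kappas[0] ** 2 * scale.s2
        kps = np.asarray(BOX_KPS, float)
        kps[0, 0] += math.sqrt(d2)
        a_single = ann(BOX_KPS, (V, V, N, N))
        det = Detection("f", kps, np.ones(4))
        # both shoulders visible; move only one and check the mixed value
        expected = (math.exp(-1.0) + 1.0) / 2.0
        assert oks(det, a_single, scale).oks == pytest.approx(expected)

    def test_matches_direct_formula(self, rng):
        cfg = MetricConfig()
        for _ in range(20):
            kps = rng.uniform(0, 60, (4, 2))
            vis = tuple(rng.choice([V, O, N], p=[0.6, 0.2, 0.2]) for _ in range(4))
            a = ann(kps, vis)
            scale = compute_scale(a, cfg)
            if scale.excluded:
                continue
            det = Detection("f", kps + rng.normal(0, 5, (4, 2)), np.ones(4))
            got = oks(det, a, scale, cfg).oks
            num = den = 0.0
            for i in range(4):
                if vis[i] >= O:
                    d2 = np.sum((det.keypoints[i] - kps[i]) ** 2)
                    num += math.exp(-d2 / (2 * cfg.kappas[i] ** 2 * scale.s2))
                    den += 1.0
            assert got == pytest.approx(num / den)

    def test_translation_and_joint_scaling_invariance(self, rng):
        a = ann(BOX_KPS, (V, V, V, V))
        det = Detection("f", np.asarray(BOX_KPS) + rng.normal(0, 3, (4, 2)),
                        np.ones(4))
        base = oks(det, a).oks
        shift = np.array([17.0, -4.0])
        a2 = ann(np.asarray(BOX_KPS) + shift, (V, V, V, V))
        det2 = Detection("f", det.keypoints + shift, np.ones(4))
        assert oks(det2, a2).oks == pytest.approx(base, rel=1e-12)
        a3 = ann(np.asarray(BOX_KPS) * 2.5, (V, V, V, V))
        det3 = Detection("f", det.keypoints * 2.5, np.ones(4))
        assert oks(det3, a3).oks == pytest.approx(base, rel=1e-12)

    def test_strictly_decreasing_in_distance(self):
        a = ann(BOX_KPS, (V, V, V, V))
        vals = []
        for d in (0.0, 2.0, 5.0, 15.0, 60.0):
            kps = np.asarray(BOX_KPS, float)
            kps[2, 1] += d
            vals.append(oks(Detection("f", kps, np.ones(4)), a).oks)
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_excluded_scale_raises(self):
        a = ann(BOX_KPS, (V, N, N, N))
        det = Detection("f", np.asarray(BOX_KPS), np.ones(4))
        with pytest.raises(ValueError, match="not\\s+evaluated"):
            oks(det, a, compute_scale(a))


def scores_from(values, **labels):
    return [
        FrameScore(frame_id=str(i), oks=v, case=ScaleCase.TORSO_BOX, **labels)
        for i, v in enumerate(values)
    ]


class TestAveragePrecision:
    def test_all_perfect(self):
        res = average_precision(scores_from([1.0] * 7))
        assert res == {"AP": 1.0, "AP50": 1.0, "AP75": 1.0}

    def test_all_060_gives_03(self):
        res = average_precision(scores_from([0.60] * 11))
        assert res["AP"] == pytest.approx(0.3)
        assert res["AP50"] == 1.0 and res["AP75"] == 0.0

    def test_matches_threshold_counting_oracle(self, rng):
        vals = rng.uniform(0, 1, 200)
        res = average_precision(scores_from(vals))
        thresholds = np.arange(0.50, 0.951, 0.05)
        expected = np.mean([np.mean(vals >= t) for t in thresholds])
        assert res["AP"] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 1, 50)
        res = average_precision(scores_from(vals))
        assert res["AP50"] >= res["AP"] >= np.mean(vals >= 0.95)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            average_precision([])


class TestCocoProtocolAgreement:
    """Cross-check against an independent evaluator that follows the COCO
    matching protocol (score-ranked matching, 101-point interpolated
    precision) in the one-detection-per-frame setting."""

    @staticmethod
    def coco_protocol_ap(oks_values, det_scores, thr):
        order = np.argsort(-np.asarray(det_scores), kind="stable")
        matches = (np.asarray(oks_values)[order] >= thr).astype(float)
        tp = np.cumsum(matches)
        fp = np.cumsum(1.0 - matches)
        recall = tp / len(oks_values)
        precision = tp / np.maximum(tp + fp, 1e-12)
        # make precision monotonically decreasing from the right
        for i in range(len(precision) - 2, -1, -1):
            precision[i] = max(precision[i], precision[i + 1])
        out = 0.0
        for r in np.linspace(0, 1, 101):
            idx = np.searchsorted(recall, r, side="left")
            out += precision[idx] if idx < len(precision) else 0.0
        return out / 101.0

    def test_agreement_on_fixture_frames(self, rng):
        vals = rng.uniform(0, 1, 200)
        res = average_precision(scores_from(vals))
        # detections ranked by their own quality: the protocol AP equals
        # per-threshold counting up to the 101-point quantisation
        thresholds = np.arange(0.50, 0.951, 0.05)
        coco = np.mean([self.coco_protocol_ap(vals, vals, t) for t in thresholds])
        assert res["AP"] == pytest.approx(coco, abs=0.01)


class TestStratifiedReport:
    def test_single_stratum_equals_global(self):
        sc = scores_from([0.9, 0.8, 0.7], position="prone", covering="none",
                         intervention=False)
        rep = stratified_report(sc)
        row = rep[(rep.stratum == "position") & (rep.value == "prone")].iloc[0]
        assert row.mean_oks == pytest.approx(0.8)
        assert row.n == 3

    def test_two_strata_means(self):
        sc = scores_from([1.0], position="prone") + scores_from(
            [0.5], position="side"
        )
        rep = stratified_report(sc)
        by = {r.value: r.mean_oks for _, r in rep.iterrows() if r.stratum == "position"}
        assert by == {"prone": pytest.approx(1.0), "side": pytest.approx(0.5)}

    def test_matches_groupby_oracle(self, rng):
        positions = rng.choice(["prone", "supine", "side"], 60)
        vals = rng.uniform(0.2, 1.0, 60)
        sc = [
            FrameScore(str(i), v, ScaleCase.TORSO_BOX, position=p)
            for i, (v, p) in enumerate(zip(vals, positions))
        ]
        rep = stratified_report(sc)
        for p in ("prone", "supine", "side"):
            expected = vals[positions == p].mean()
            row = rep[(rep.stratum == "position") & (rep.value == p)].iloc[0]
            assert row.mean_oks == pytest.approx(expected)
            assert row.p5 == pytest.approx(np.percentile(vals[positions == p], 5))


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        a = rng.uniform(0, 1, 40)
        assert compare_groups(a, a) > 0.5

    def test_disjoint_supports_highly_significant(self, rng):
        a = rng.uniform(0.8, 1.0, 50)
        b = rng.uniform(0.0, 0.2, 50)
        assert compare_groups(a, b) < 1e-5

    def test_permutation_mode_agrees_with_u_test_decision(self, rng):
        a = rng.normal(0.8, 0.05, 30)
        b = rng.normal(0.6, 0.05, 30)
        p_u = compare_groups(a, b)
        p_perm = compare_groups(a, b, method="permutation", seed=5)
        assert (p_u < 0.01) == (p_perm < 0.01)
        # and a null case
        c = rng.normal(0.7, 0.05, 30)
        d = rng.normal(0.7, 0.05, 30)
        assert (compare_groups(c, d) < 0.01) == (
            compare_groups(c, d, method="permutation", seed=5) < 0.01
        )

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [0.5])


class TestRescaleRMSE:
    def test_proportionality(self):
        assert rescale_rmse([[10.0, 0.0]], (1280, 720)) == pytest.approx(1.0)

    def test_zero_errors(self):
        assert rescale_rmse(np.zeros((5, 2)), (640, 576)) == 0.0

    def test_matches_hand_computation(self):
        errs = np.array([[10.0, 5.0], [-4.0, 8.0]])
        got = rescale_rmse(errs, (640, 576))
        sx, sy = 128 / 640, 96 / 576
        scaled = errs * [sx, sy]
        expected = np.sqrt(np.mean(np.sum(scaled**2, axis=1)))
        assert got == pytest.approx(expected)
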