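"""RULA posture coding, table lookups, occlusion fallback and assessment."""

import itertools

import numpy as np
import pytest

from ergokit.config import RulaConfig
from ergokit.measure import measure_frame
from ergokit.rula import (
    AdjustmentFlags,
    BodyPartScores,
    ManualInputs,
    PART_RANGES,
    RulaRangeError,
    action_level,
    assess_frame,
    assess_sequence,
    classify_body_parts,
    leg_occlusion_fallback,
    score_tables,
    table_a_lookup,
    table_b_lookup,
    table_c_lookup,
)
from ergokit.synthetic import PoseRecipe, generate_pose, generate_sequence, perturb_pose

from conftest import make_frame


def classify(recipe_kwargs, side="right", flags=AdjustmentFlags(), legs_code=1):
    frame = generate_pose(PoseRecipe(**recipe_kwargs))
    return classify_body_parts(measure_frame(frame), side, flags=flags, legs_code=legs_code)


class TestClassification:
    def test_worksheet_neutral_upper_arm(self):
        assert classify({"upper_arm_flexion": 10.0}).upper_arm == 1

    def test_worksheet_raised_arm_with_abduction(self):
        scores = classify(
            {"upper_arm_flexion": 95.0}, flags=AdjustmentFlags(arm_abducted=True)
        )
        assert scores.upper_arm == 5  # bin 4 + abduction adjustment

    def test_worksheet_neutral_wrist(self):
        assert classify({"wrist_flexion": 0.0}).wrist == 1

    def test_wrist_deviation_adds_one(self):
        base = {"wrist_flexion": 10.0}
        assert classify(base).wrist == 2
        assert classify({**base, "wrist_deviation": 20.0, "wrist_twist": 90.0}).wrist == 3

    def test_arm_support_subtracts_one(self):
        scores = classify(
            {"upper_arm_flexion": 30.0}, flags=AdjustmentFlags(arm_supported=True)
        )
        assert scores.upper_arm == 1

    def test_neck_extension_codes_four(self):
        assert classify({"neck_flexion": -15.0}).neck == 4

    def test_trunk_twist_and_side_bend_adjust(self):
        flags = AdjustmentFlags(trunk_twisted=True, trunk_side_bent=True)
        assert classify({"trunk_flexion": 30.0}, flags=flags).trunk == 5

    def test_missing_joints_mark_part_uncodable(self):
        frame = generate_pose(PoseRecipe())
        kps = {k: v for k, v in frame.keypoints.items() if "hand" not in k}
        frame = type(frame)(skeleton=frame.skeleton, keypoints=kps)
        scores = classify_body_parts(measure_frame(frame), "right", legs_code=1)
        assert scores.wrist is None and scores.wrist_twist is None
        assert scores.upper_arm is not None  # the rest still codes


# Half-open posture bins: (recipe field, angle -> expected code)
BOUNDARY_CASES = [
    ("upper_arm", "upper_arm_flexion", -22.0, 2),
    ("upper_arm", "upper_arm_flexion", -18.0, 1),
    ("upper_arm", "upper_arm_flexion", 18.0, 1),
    ("upper_arm", "upper_arm_flexion", 22.0, 2),
    ("upper_arm", "upper_arm_flexion", 43.0, 2),
    ("upper_arm", "upper_arm_flexion", 47.0, 3),
    ("upper_arm", "upper_arm_flexion", 88.0, 3),
    ("upper_arm", "upper_arm_flexion", 92.0, 4),
    ("lower_arm", "elbow_flexion", 58.0, 2),
    ("lower_arm", "elbow_flexion", 62.0, 1),
    ("lower_arm", "elbow_flexion", 98.0, 1),
    ("lower_arm", "elbow_flexion", 102.0, 2),
    ("wrist", "wrist_flexion", 0.0, 1),
    ("wrist", "wrist_flexion", 2.0, 2),
    ("wrist", "wrist_flexion", -2.0, 2),
    ("wrist", "wrist_flexion", 13.0, 2),
    ("wrist", "wrist_flexion", 17.0, 3),
    ("wrist", "wrist_flexion", -17.0, 3),
    ("neck", "neck_flexion", -2.0, 4),
    ("neck", "neck_flexion", 2.0, 1),
    ("neck", "neck_flexion", 8.0, 1),
    ("neck", "neck_flexion", 12.0, 2),
    ("neck", "neck_flexion", 18.0, 2),
    ("neck", "neck_flexion", 22.0, 3),
    ("trunk", "trunk_flexion", 1.0, 1),
    ("trunk", "trunk_flexion", 5.0, 2),
    ("trunk", "trunk_flexion", -5.0, 2),
    ("trunk", "trunk_flexion", 18.0, 2),
    ("trunk", "trunk_flexion", 22.0, 3),
    ("trunk", "trunk_flexion", 58.0, 3),
    ("trunk", "trunk_flexion", 62.0, 4),
]


class TestBoundaryRecovery:
    @pytest.mark.parametrize("part,field,angle,expected", BOUNDARY_CASES)
    def test_generated_pose_codes_correctly_around_every_bin_boundary(
        self, part, field, angle, expected
    ):
        scores = classify({field: angle})
        assert getattr(scores, part) == expected

    @pytest.mark.parametrize("twist,expected", [(43.0, 2), (47.0, 1), (88.0, 1)])
    def test_wrist_twist_fold_threshold(self, twist, expected):
        # the folded palm-normal angle can only drop below 90 with a bent wrist
        scores = classify({"wrist_flexion": 60.0, "wrist_twist": twist})
        assert scores.wrist_twist == expected

    @pytest.mark.parametrize("support,expected", [(True, 1), (False, 2)])
    def test_leg_support_codes(self, support, expected):
        frame = generate_pose(PoseRecipe(leg_support=support))
        legs, upper_only = leg_occlusion_fallback(frame)
        assert legs == expected and upper_only is False

    def test_recovery_on_both_sides(self):
        # codes must agree between the left and right side of a symmetric pose
        for angle in (19.0, 21.0, 44.0, 46.0):
            frame = generate_pose(PoseRecipe(upper_arm_flexion=angle))
            m = measure_frame(frame)
            left = classify_body_parts(m, "left", legs_code=1)
            right = classify_body_parts(m, "right", legs_code=1)
            assert left.upper_arm == right.upper_arm


class TestTables:
    def test_table_a_corner(self):
        assert table_a_lookup(1, 1, 1, 1) == 1

    def test_table_b_corner(self):
        assert table_b_lookup(1, 1, 1) == 1

    def test_table_a_range_over_exhaustive_sweep(self):
        values = {
            table_a_lookup(ua, la, w, wt)
            for ua in range(1, 7)
            for la in range(1, 4)
            for w in range(1, 5)
            for wt in range(1, 3)
        }
        assert values <= set(range(1, 10)) and max(values) == 9

    def test_table_b_range_over_exhaustive_sweep(self):
        values = {
            table_b_lookup(n, t, l)
            for n in range(1, 7)
            for t in range(1, 7)
            for l in range(1, 3)
        }
        assert values <= set(range(1, 10))

    def test_out_of_range_codes_raise(self):
        with pytest.raises(RulaRangeError):
            table_a_lookup(7, 1, 1, 1)
        with pytest.raises(RulaRangeError):
            table_b_lookup(0, 1, 1)
        with pytest.raises(RulaRangeError):
            table_c_lookup(0, 1)

    def test_table_c_caps_inputs_above_table_limits(self):
        assert table_c_lookup(9, 7) == table_c_lookup(8, 7)
        assert table_c_lookup(12, 12) == table_c_lookup(8, 7) == 7

    def test_tables_monotone_in_each_argument(self):
        for ua, la, w, wt in itertools.product(
            range(1, 7), range(1, 4), range(1, 5), range(1, 3)
        ):
            base = table_a_lookup(ua, la, w, wt)
            if ua < 6:
                assert table_a_lookup(ua + 1, la, w, wt) >= base
            if la < 3:
                assert table_a_lookup(ua, la + 1, w, wt) >= base
            if w < 4:
                assert table_a_lookup(ua, la, w + 1, wt) >= base
            if wt < 2:
                assert table_a_lookup(ua, la, w, wt + 1) >= base
        for n, t, l in itertools.product(range(1, 7), range(1, 7), range(1, 3)):
            base = table_b_lookup(n, t, l)
            if n < 6:
                assert table_b_lookup(n + 1, t, l) >= base
            if t < 6:
                assert table_b_lookup(n, t + 1, l) >= base
            if l < 2:
                assert table_b_lookup(n, t, l + 1) >= base
        for c, d in itertools.product(range(1, 10), range(1, 9)):
            base = table_c_lookup(c, d)
            assert table_c_lookup(c + 1, d) >= base
            assert table_c_lookup(c, d + 1) >= base


class TestActionLevel:
    @pytest.mark.parametrize(
        "grand,level", [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 3), (7, 4)]
    )
    def test_published_action_level_mapping(self, grand, level):
        assert action_level(grand) == level

    def test_exactly_four_distinct_levels(self):
        assert {action_level(g) for g in range(1, 8)} == {1, 2, 3, 4}

    def test_out_of_range_raises(self):
        for bad in (0, 8):
            with pytest.raises(RulaRangeError):
                action_level(bad)


class TestGrandScoreMonotonicity:
    def test_grand_score_monotone_over_full_code_lattice(self):
        """Raising any posture code, muscle use or force load never lowers
        the grand score — exhaustive over the code lattice."""
        parts = list(PART_RANGES)
        ranges = [range(lo, hi + 1) for lo, hi in PART_RANGES.values()]
        for combo in itertools.product(*ranges):
            codes = dict(zip(parts, combo))
            base = score_tables(BodyPartScores(side="right", **codes)).grand_score
            for part, (lo, hi) in PART_RANGES.items():
                if codes[part] < hi:
                    bumped = dict(codes, **{part: codes[part] + 1})
                    assert (
                        score_tables(BodyPartScores(side="right", **bumped)).grand_score
                        >= base
                    )

    def test_grand_score_monotone_in_manual_inputs(self):
        scores = BodyPartScores(
            side="right", upper_arm=3, lower_arm=2, wrist=2, wrist_twist=1,
            neck=2, trunk=2, legs=1,
        )
        base = score_tables(scores).grand_score
        for manual in (
            ManualInputs(muscle_use_a=1),
            ManualInputs(muscle_use_b=1),
            ManualInputs(force_load_a=3),
            ManualInputs(force_load_b=3),
        ):
            assert score_tables(scores, manual).grand_score >= base

    def test_manual_inputs_validated(self):
        with pytest.raises(RulaRangeError):
            ManualInputs(muscle_use_a=2)
        with pytest.raises(RulaRangeError):
            ManualInputs(force_load_a=4)


class TestOcclusionFallback:
    def test_absent_ankles_force_upper_body_only(self):
        frame = generate_pose(PoseRecipe())
        frame = perturb_pose(frame, 0.0, occlude=["left_ankle", "right_ankle"])
        legs, upper_only = leg_occlusion_fallback(frame)
        assert (legs, upper_only) == (1, True)

    def test_supported_visible_legs_code_normally(self):
        legs, upper_only = leg_occlusion_fallback(generate_pose(PoseRecipe()))
        assert (legs, upper_only) == (1, False)

    def test_anomalous_shank_length_triggers_fallback(self):
        seq = generate_sequence([PoseRecipe(seed=i) for i in range(5)])
        bad = generate_pose(
            PoseRecipe(limb_lengths_mm={"shank": 3 * 400.0}, seed=99)
        )
        legs, upper_only = leg_occlusion_fallback(bad, sequence_context=seq)
        assert (legs, upper_only) == (1, True)

    def test_low_confidence_legs_trigger_fallback(self):
        frame = generate_pose(PoseRecipe())
        kps = dict(frame.keypoints)
        kps["left_knee"] = type(kps["left_knee"])(
            x=kps["left_knee"].x, y=kps["left_knee"].y, z=kps["left_knee"].z,
            visibility=kps["left_knee"].visibility, confidence=0.1,
        )
        frame = type(frame)(skeleton=frame.skeleton, keypoints=kps)
        legs, upper_only = leg_occlusion_fallback(frame)
        assert (legs, upper_only) == (1, True)


class TestAssessment:
    def test_neutral_pose_matches_worksheet_hand_computation(self):
        # neutral standing: every part codes 1, Table A=1, Table B=1,
        # C=D=1 -> grand 1, action level 1
        res = assess_frame(generate_pose(PoseRecipe()))
        h = res.headline
        assert h.scores.uncodable_parts() == []
        assert all(
            getattr(h.scores, p) == 1 for p in PART_RANGES
        )
        assert (h.table_a, h.table_b, h.grand_score, h.action_level) == (1, 1, 1, 1)

    def test_stooped_pose_matches_worksheet_hand_computation(self, stooped_frame):
        # hand-walked worksheet: upper arm 95deg->4, elbow 30->2, wrist 20->3,
        # twist neutral->1 gives Table A=4; neck 25->3, trunk 30->3, legs 1
        # gives Table B=4; C=4, D=4 -> Table C grand 4 -> action level 2
        res = assess_frame(stooped_frame)
        h = res.headline
        assert (h.scores.upper_arm, h.scores.lower_arm, h.scores.wrist) == (4, 2, 3)
        assert (h.scores.neck, h.scores.trunk, h.scores.legs) == (3, 3, 1)
        assert (h.table_a, h.table_b) == (4, 4)
        assert (h.grand_score, h.action_level) == (4, 2)

    def test_muscle_use_never_lowers_grand_score(self, stooped_frame):
        base = assess_frame(stooped_frame, ManualInputs()).grand_score
        loaded = assess_frame(stooped_frame, ManualInputs(muscle_use_a=1)).grand_score
        assert loaded >= base

    def test_sequence_subsampling_arithmetic(self):
        seq = generate_sequence([PoseRecipe(seed=i) for i in range(300)], fps=30.0)
        results = assess_sequence(seq, sample_fps=1.0)
        assert len(results) == 10

    def test_upper_body_only_frames_identical_above_hips_score_identically(self):
        kwargs = dict(upper_arm_flexion=50.0, trunk_flexion=25.0, seed=4)
        occlusions = (["left_ankle", "right_ankle"], ["left_knee", "left_ankle"])
        results = []
        for occ in occlusions:
            frame = perturb_pose(generate_pose(PoseRecipe(**kwargs)), 0.0, occlude=occ)
            res = assess_frame(frame)
            assert res.upper_body_only
            results.append(res)
        assert results[0].grand_score == results[1].grand_score
        assert results[0].headline.scores.legs == results[1].headline.scores.legs == 1

    def test_unassessable_frame_has_reason(self):
        frame = generate_pose(PoseRecipe())
        occ = [f"{s}_{j}" for s in ("left", "right") for j in ("hand", "thumb")]
        res = assess_frame(perturb_pose(frame, 0.0, occlude=occ))
        assert res.headline is None
        assert "wrist" in res.unassessable_reason

    def test_headline_is_worse_side(self):
        # make the right arm worse by overriding one side's codes directly
        frame = generate_pose(PoseRecipe(upper_arm_flexion=30.0))
        res = assess_frame(frame)
        assert res.headline.grand_score == max(
            res.left.grand_score, res.right.grand_score
        )


class TestParameterRecoveryAtScale:
    def test_noise_free_recipes_recover_codes(self, rng):
        """Poses generated with target per-part codes come back code-for-code."""
        cases = 0
        hits = 0
        for _ in range(40):
            ua = float(rng.uniform(-40, 150))
            el = float(rng.uniform(10, 140))
            wf = float(rng.uniform(-50, 50))
            nk = float(rng.uniform(-40, 50))
            tk = float(rng.uniform(-20, 80))
            recipe = PoseRecipe(
                upper_arm_flexion=ua, elbow_flexion=el, wrist_flexion=wf,
                neck_flexion=nk, trunk_flexion=tk, seed=int(rng.integers(1 << 30)),
            )
            expected = {
                "upper_arm": (1 if -20 <= ua < 20 else 2 if ua < 45 else 3 if ua < 90 else 4),
                "lower_arm": 1 if 60 <= el < 100 else 2,
                "wrist": (1 if abs(wf) <= 1.0 else 2 if abs(wf) <= 15 else 3),
                "neck": (4 if nk < -1.0 else 1 if nk < 10 else 2 if nk < 20 else 3),
                "trunk": (1 if abs(tk) <= 3.0 else 2 if tk < 20 else 3 if tk < 60 else 4),
            }
            scores = classify_body_parts(
                measure_frame(generate_pose(recipe)), "right", legs_code=1
            )
            for part, want in expected.items():
                cases += 1
                hits += getattr(scores, part) == want
        assert hits / cases >= 0.99
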