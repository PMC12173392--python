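"""Geometry feature tests: analytic examples, oracle equivalence, invariances."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pifr.errors import DegenerateGeometryError, MissingKeypointError
from pifr.features import (
    FEATURE_NAMES,
    center_of_mass,
    extract_features,
    hip_angle,
    leg_angle,
    nose_to_ankle_angle,
    shoulder_angle,
    shoulder_nose_angle,
    torso_angle,
)
from pifr.keypoints import COCO_KEYPOINT_NAMES, LEFT_RIGHT_PAIRS, Keypoint
from pifr.simulate import rotate_frame

from .conftest import (
    frame_from_coords,
    frame_from_named,
    oracle_angle_between,
    oracle_horizontal_angle,
    oracle_vertical_angle,
    random_nondegenerate_frame,
)

ARCCOS_08_DEG = math.degrees(math.acos(0.8))  # 36.86989764584402, independent closed form


class TestCenterOfMass:
    def test_three_visible_points(self):
        conf = [1.0, 1.0, 1.0] + [0.0] * 14
        frame = frame_from_coords([(0, 0), (3, 0), (0, 3)] + [(0, 0)] * 14, confidences=conf)
        assert center_of_mass(frame) == (1.0, 1.0)

    def test_identity_all_same_point(self):
        frame = frame_from_coords([(7, 9)] * 17)
        assert center_of_mass(frame) == (7.0, 9.0)

    def test_matches_summation_oracle(self, rng):
        coords = rng.uniform(0, 640, (17, 2))
        frame = frame_from_coords(coords)
        # brute-force sum / N oracle
        ox = sum(c[0] for c in coords) / 17
        oy = sum(c[1] for c in coords) / 17
        cx, cy = center_of_mass(frame)
        assert abs(cx - ox) < 1e-12 and abs(cy - oy) < 1e-12

    def test_zero_visible_raises(self):
        frame = frame_from_coords([(0, 0)] * 17, confidences=[0.0] * 17)
        with pytest.raises(MissingKeypointError):
            center_of_mass(frame)


class TestShoulderNoseAngle:
    def test_orthogonal(self):
        frame = frame_from_named({"nose": (0, 0), "left_shoulder": (-1, 1), "right_shoulder": (1, 1)}, default=(9, 9))
        assert shoulder_nose_angle(frame) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_nose_between(self):
        frame = frame_from_named({"nose": (0, 0), "left_shoulder": (-1, 0), "right_shoulder": (1, 0)}, default=(9, 9))
        assert shoulder_nose_angle(frame) == pytest.approx(180.0, abs=1e-9)

    def test_matches_atan2_oracle(self):
        frame = frame_from_named({"nose": (0, 0), "left_shoulder": (2, 1), "right_shoulder": (3, -4)}, default=(9, 9))
        expected = oracle_angle_between((2, 1), (3, -4))
        assert shoulder_nose_angle(frame) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_shoulder_on_nose(self):
        frame = frame_from_named({"nose": (5, 5), "left_shoulder": (5, 5), "right_shoulder": (1, 1)}, default=(9, 9))
        with pytest.raises(DegenerateGeometryError):
            shoulder_nose_angle(frame)


class TestTorsoAngle:
    def test_upright(self):
        frame = frame_from_named({"nose": (100, 50), "left_hip": (90, 150), "right_hip": (110, 150)}, default=(9, 9))
        assert torso_angle(frame) == pytest.approx(0.0, abs=1e-9)

    def test_horizontal(self):
        frame = frame_from_named({"nose": (0, 100), "left_hip": (90, 100), "right_hip": (110, 100)}, default=(9, 9))
        assert torso_angle(frame) == pytest.approx(90.0, abs=1e-9)

    def test_arccos_four_fifths(self):
        frame = frame_from_named({"nose": (0, 0), "left_hip": (2, 4), "right_hip": (4, 4)}, default=(9, 9))
        # mid-hip (3, 4): v = (3, 4), angle = arccos(4/5)
        assert torso_angle(frame) == pytest.approx(ARCCOS_08_DEG, abs=1e-9)

    def test_degenerate(self):
        frame = frame_from_named({"nose": (3, 4), "left_hip": (2, 4), "right_hip": (4, 4)}, default=(9, 9))
        with pytest.raises(DegenerateGeometryError):
            torso_angle(frame)


class TestHipShoulderAngles:
    @pytest.mark.parametrize(
        "left,right,expected",
        [((0, 0), (2, 0), 0.0), ((0, 0), (0, 2), 90.0), ((0, 0), (-1, 1), 135.0)],
    )
    def test_hip_examples(self, left, right, expected):
        frame = frame_from_named({"left_hip": left, "right_hip": right}, default=(9, 9))
        assert hip_angle(frame) == pytest.approx(expected, abs=1e-9)

    def test_hip_range_not_folded(self):
        # flipped hip line distinguishes v_x sign: arccos(-1/sqrt(2)) = 135, not 45
        frame = frame_from_named({"left_hip": (0, 0), "right_hip": (-1, 1)}, default=(9, 9))
        assert hip_angle(frame) > 90.0

    @pytest.mark.parametrize(
        "left,right,expected",
        [((0, 0), (5, 0), 0.0), ((0, 0), (0, 5), 90.0)],
    )
    def test_shoulder_examples(self, left, right, expected):
        frame = frame_from_named({"left_shoulder": left, "right_shoulder": right}, default=(9, 9))
        assert shoulder_angle(frame) == pytest.approx(expected, abs=1e-9)

    def test_shoulder_oracle(self):
        frame = frame_from_named({"left_shoulder": (1, 1), "right_shoulder": (4, 5)}, default=(9, 9))
        assert shoulder_angle(frame) == pytest.approx(oracle_horizontal_angle((3, 4)), abs=1e-9)

    def test_coincident_hips_degenerate(self):
        frame = frame_from_named({"left_hip": (1, 1), "right_hip": (1, 1)}, default=(9, 9))
        with pytest.raises(DegenerateGeometryError):
            hip_angle(frame)


class TestLegAngle:
    def test_straight_leg(self):
        frame = frame_from_named({"left_hip": (0, 0), "left_knee": (0, 1), "left_ankle": (0, 2)}, default=(9, 9))
        assert leg_angle(frame, "left") == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_bend(self):
        frame = frame_from_named({"left_hip": (0, 0), "left_knee": (0, 1), "left_ankle": (1, 1)}, default=(9, 9))
        assert leg_angle(frame, "left") == pytest.approx(90.0, abs=1e-9)

    def test_random_triple_matches_oracle(self, rng):
        for _ in range(50):
            hip, knee, ankle = rng.uniform(0, 100, (3, 2))
            if np.hypot(*(knee - hip)) < 1e-6 or np.hypot(*(ankle - knee)) < 1e-6:
                continue
            frame = frame_from_named({"right_hip": tuple(hip), "right_knee": tuple(knee), "right_ankle": tuple(ankle)}, default=(9, 9))
            expected = oracle_angle_between(knee - hip, ankle - knee)
            assert leg_angle(frame, "right") == pytest.approx(expected, abs=1e-9)

    def test_bad_side(self):
        frame = frame_from_coords([(i, i) for i in range(17)])
        with pytest.raises(ValueError):
            leg_angle(frame, "middle")


class TestNoseToAnkleAngle:
    def test_upright(self):
        frame = frame_from_named({"nose": (0, 0), "left_ankle": (-1, 10), "right_ankle": (1, 10)}, default=(9, 9))
        assert nose_to_ankle_angle(frame) == pytest.approx(0.0, abs=1e-9)

    def test_horizontal(self):
        frame = frame_from_named({"nose": (0, 0), "left_ankle": (9, 0), "right_ankle": (11, 0)}, default=(9, 9))
        assert nose_to_ankle_angle(frame) == pytest.approx(90.0, abs=1e-9)

    def test_arccos_oracle(self):
        frame = frame_from_named({"nose": (0, 0), "left_ankle": (-7, 8), "right_ankle": (-5, 8)}, default=(9, 9))
        # mid-ankle (-6, 8): angle = arccos(8/10)
        assert nose_to_ankle_angle(frame) == pytest.approx(ARCCOS_08_DEG, abs=1e-9)


def _all_angles(frame):
    return {
        "shoulder_nose": shoulder_nose_angle(frame),
        "torso": torso_angle(frame),
        "hip": hip_angle(frame),
        "shoulder": shoulder_angle(frame),
        "left_leg": leg_angle(frame, "left"),
        "right_leg": leg_angle(frame, "right"),
        "nose_ankle": nose_to_ankle_angle(frame),
    }


def _oracle_angles(frame):
    def pt(n):
        kp = frame.keypoint(n)
        return np.array([kp.x, kp.y])

    mid_hip = (pt("left_hip") + pt("right_hip")) / 2
    mid_ankle = (pt("left_ankle") + pt("right_ankle")) / 2
    return {
        "shoulder_nose": oracle_angle_between(pt("left_shoulder") - pt("nose"), pt("right_shoulder") - pt("nose")),
        "torso": oracle_vertical_angle(mid_hip - pt("nose")),
        "hip": oracle_horizontal_angle(pt("right_hip") - pt("left_hip")),
        "shoulder": oracle_horizontal_angle(pt("right_shoulder") - pt("left_shoulder")),
        "left_leg": oracle_angle_between(pt("left_knee") - pt("left_hip"), pt("left_ankle") - pt("left_knee")),
        "right_leg": oracle_angle_between(pt("right_knee") - pt("right_hip"), pt("right_ankle") - pt("right_knee")),
        "nose_ankle": oracle_vertical_angle(mid_ankle - pt("nose")),
    }


class TestOracleEquivalence:
    def test_300_random_frames(self, rng):
        for _ in range(300):
            frame = random_nondegenerate_frame(rng)
            got = _all_angles(frame)
            want = _oracle_angles(frame)
            for name in got:
                assert abs(got[name] - want[name]) < 1e-9, name

    def test_all_outputs_in_range(self, rng):
        for _ in range(200):
            frame = random_nondegenerate_frame(rng)
            for name, value in _all_angles(frame).items():
                assert 0.0 <= value <= 180.0, name


class TestInvariances:
    def _transformed(self, frame, dx=0.0, dy=0.0, scale=1.0):
        return frame.with_keypoints(
            [Keypoint(kp.x * scale + dx, kp.y * scale + dy, kp.confidence) for kp in frame.keypoints]
        )

    def test_translation_and_scale_invariance(self, rng):
        for _ in range(200):
            frame = random_nondegenerate_frame(rng)
            moved = self._transformed(frame, dx=500.0, dy=300.0, scale=2.0)
            a, b = _all_angles(frame), _all_angles(moved)
            for name in a:
                assert abs(a[name] - b[name]) < 1e-9, name
            fa, fb = extract_features(frame), extract_features(moved)
            assert abs(fa.cm_x - fb.cm_x) < 1e-9 and abs(fa.cm_y - fb.cm_y) < 1e-9

    def test_rotation_covariance(self, rng):
        for _ in range(200):
            frame = random_nondegenerate_frame(rng)
            theta = float(rng.uniform(1.0, 89.0))
            center = tuple(rng.uniform(0, 640, 2))
            rotated = rotate_frame(frame, theta, center)

            def signed_vertical(f, names):
                def pt(n):
                    kp = f.keypoint(n)
                    return np.array([kp.x, kp.y])

                tip = (pt(names[1]) + pt(names[2])) / 2 - pt(names[0])
                return math.degrees(math.atan2(tip[0], tip[1]))

            for names in (("nose", "left_hip", "right_hip"), ("nose", "left_ankle", "right_ankle")):
                fn = torso_angle if "hip" in names[1] else nose_to_ankle_angle
                phi = signed_vertical(frame, names)
                wrapped = (phi + theta + 180.0) % 360.0 - 180.0
                assert fn(rotated) == pytest.approx(abs(wrapped), abs=1e-8)
                if phi >= 0 and phi + theta <= 180.0:
                    # no arccos fold: shift is exactly theta
                    assert fn(rotated) == pytest.approx(fn(frame) + theta, abs=1e-8)

            # relative angles are rotation-invariant
            assert shoulder_nose_angle(rotated) == pytest.approx(shoulder_nose_angle(frame), abs=1e-8)
            assert leg_angle(rotated, "left") == pytest.approx(leg_angle(frame, "left"), abs=1e-8)
            assert leg_angle(rotated, "right") == pytest.approx(leg_angle(frame, "right"), abs=1e-8)

    def test_horizontal_flip_symmetry(self, rng):
        for _ in range(200):
            frame = random_nondegenerate_frame(rng)
            coords = np.array([(kp.x, kp.y) for kp in frame.keypoints])
            coords[:, 0] = -coords[:, 0]
            order = list(range(17))
            for li, ri in LEFT_RIGHT_PAIRS:
                order[li], order[ri] = order[ri], order[li]
            flipped = frame.with_keypoints([Keypoint(*coords[i], 1.0) for i in order])
            assert leg_angle(flipped, "left") == pytest.approx(leg_angle(frame, "right"), abs=1e-9)
            assert leg_angle(flipped, "right") == pytest.approx(leg_angle(frame, "left"), abs=1e-9)
            assert torso_angle(flipped) == pytest.approx(torso_angle(frame), abs=1e-9)
            assert nose_to_ankle_angle(flipped) == pytest.approx(nose_to_ankle_angle(frame), abs=1e-9)


class TestExtractFeatures:
    def test_standing_template(self, standing_frame):
        fv = extract_features(standing_frame)
        assert fv.torso < 15.0
        assert fv.nose_ankle < 15.0
        assert fv.all_valid
        assert 0.0 <= fv.cm_x <= 1.0 and 0.0 <= fv.cm_y <= 1.0

    def test_missing_hips_flagged(self, standing_frame):
        kps = list(standing_frame.keypoints)
        for name in ("left_hip", "right_hip"):
            i = COCO_KEYPOINT_NAMES.index(name)
            kps[i] = Keypoint(kps[i].x, kps[i].y, 0.0)
        fv = extract_features(standing_frame.with_keypoints(kps))
        mask = dict(zip(FEATURE_NAMES, fv.validity_mask))
        assert not mask["torso"] and not mask["hip"]
        assert math.isnan(fv.torso) and math.isnan(fv.hip)
        for name in ("cm_x", "cm_y", "shoulder_nose", "shoulder", "nose_ankle"):
            assert mask[name], name

    def test_explicit_bbox_normalization(self, standing_frame):
        fv = extract_features(standing_frame, bbox=(0.0, 0.0, 640.0, 480.0))
        cx, cy = center_of_mass(standing_frame)
        assert fv.cm_x == pytest.approx(cx / 640.0)
        assert fv.cm_y == pytest.approx(cy / 480.0)

    def test_never_raises_on_fully_missing(self):
        frame = frame_from_coords([(0, 0)] * 17, confidences=[0.0] * 17)
        fv = extract_features(frame)
        assert not any(fv.validity_mask)
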