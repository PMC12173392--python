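"""Shared fixtures and independent geometric oracles.

The oracle functions are deliberately written with atan2 (not arccos)
so they exercise a different numerical path than the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pifr.keypoints import COCO_KEYPOINT_NAMES, Keypoint, PoseFrame


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_angle_between(v1, v2) -> float:
    """Unsigned angle between two vectors via atan2(cross, dot), degrees."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return abs(math.degrees(math.atan2(cross, dot)))


def oracle_vertical_angle(v) -> float:
    return oracle_angle_between(v, (0.0, 1.0))


def oracle_horizontal_angle(v) -> float:
    return oracle_angle_between(v, (1.0, 0.0))


def oracle_auc(labels, scores) -> float:
    """Exhaustive Mann-Whitney pair counting; ties count 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Frame builders
# ---------------------------------------------------------------------------


def frame_from_coords(coords, track_id="t0", frame_index=0, confidences=None) -> PoseFrame:
    """Build a PoseFrame from 17 (x, y) pairs (all visible unless stated)."""
    if confidences is None:
        confidences = [1.0] * 17
    kps = tuple(Keypoint(float(x), float(y), c) for (x, y), c in zip(coords, confidences))
    return PoseFrame(track_id=track_id, frame_index=frame_index, keypoints=kps)


def frame_from_named(named: dict, default=(0.0, 0.0), **kwargs) -> PoseFrame:
    """Build a frame by keypoint name; unnamed keypoints go to `default`."""
    coords = [named.get(name, default) for name in COCO_KEYPOINT_NAMES]
    return frame_from_coords(coords, **kwargs)


def random_nondegenerate_frame(rng: np.random.Generator) -> PoseFrame:
    """Random fully-visible frame with no coincident feature-relevant keypoints."""
    while True:
        coords = rng.uniform(0, 640, size=(17, 2))
        frame = frame_from_coords(coords)
        names = COCO_KEYPOINT_NAMES

        def pt(n):
            return coords[names.index(n)]

        pairs = [
            (pt("nose"), pt("left_shoulder")),
            (pt("nose"), pt("right_shoulder")),
            (pt("left_hip"), pt("right_hip")),
            (pt("left_shoulder"), pt("right_shoulder")),
            (pt("left_hip"), pt("left_knee")),
            (pt("left_knee"), pt("left_ankle")),
            (pt("right_hip"), pt("right_knee")),
            (pt("right_knee"), pt("right_ankle")),
            (pt("nose"), (pt("left_hip") + pt("right_hip")) / 2),
            (pt("nose"), (pt("left_ankle") + pt("right_ankle")) / 2),
        ]
        if all(np.hypot(*(a - b)) > 1e-6 for a, b in pairs):
            return frame


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def standing_frame() -> PoseFrame:
    from pifr.simulate import make_pose_template

    return make_pose_template("standing")


@pytest.fixture
def lying_frame() -> PoseFrame:
    from pifr.simulate import make_pose_template

    return make_pose_template("lying")
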