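"""Nine geometric pose features from a 17-keypoint skeleton.

Features: normalized center-of-mass x/y plus seven angles in degrees.
Vertical-reference angles (torso, nose-to-ankle) are arccos(v_y/|v|),
horizontal-reference angles (hip, shoulder) arccos(v_x/|v|); three-point
angles (shoulder-nose, both knees) use the standard two-vector arccos.
All arccos arguments are clamped to [-1, 1], so every angle lies in
[0, 180] for any finite input.  Angles are deliberately not folded to
[0, 90]: the v_x sign distinguishes a flipped hip/shoulder line.

In image coordinates (y down) an upright person has torso_angle ~ 0 and
a horizontal person ~ 90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pifr.errors import DegenerateGeometryError, MissingKeypointError
from pifr.keypoints import DEFAULT_VISIBILITY_THRESHOLD, Keypoint, PoseFrame, midpoint

#: Canonical feature order; matches the feature-table CSV columns.
FEATURE_NAMES: tuple[str, ...] = (
    "cm_x",
    "cm_y",
    "shoulder_nose",
    "torso",
    "hip",
    "shoulder",
    "left_leg",
    "right_leg",
    "nose_ankle",
)

#: CSV header for feature tables (label column optional).
TABLE_COLUMNS: tuple[str, ...] = ("track_id", "frame_index") + FEATURE_NAMES

ANGLE_NAMES: tuple[str, ...] = FEATURE_NAMES[2:]


@dataclass(frozen=True)
class FeatureVector:
    """The nine features of one frame plus a per-feature validity mask."""

    cm_x: float
    cm_y: float
    shoulder_nose: float
    torso: float
    hip: float
    shoulder: float
    left_leg: float
    right_leg: float
    nose_ankle: float
    validity_mask: tuple[bool, ...]

    def to_array(self) -> np.ndarray:
        """Values in FEATURE_NAMES order, NaN where invalid."""
        vals = np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)
        vals[~np.asarray(self.validity_mask, dtype=bool)] = np.nan
        return vals

    @property
    def all_valid(self) -> bool:
        return all(self.validity_mask)


def _xy(kp: Keypoint) -> np.ndarray:
    return np.array([kp.x, kp.y], dtype=float)


def _require_visible(frame: PoseFrame, names: tuple[str, ...], thr: float) -> None:
    for n in names:
        if not frame.keypoint(n).is_visible(thr):
            raise MissingKeypointError(f"keypoint {n!r} not visible")


def _clamped_arccos_deg(x: float) -> float:
    return math.degrees(math.acos(max(-1.0, min(1.0, x))))


def _vertical_angle(v: np.ndarray) -> float:
    norm = float(np.hypot(v[0], v[1]))
    if norm == 0.0:
        raise DegenerateGeometryError("zero-length vector against vertical axis")
    return _clamped_arccos_deg(v[1] / norm)


def _horizontal_angle(v: np.ndarray) -> float:
    norm = float(np.hypot(v[0], v[1]))
    if norm == 0.0:
        raise DegenerateGeometryError("zero-length vector against horizontal axis")
    return _clamped_arccos_deg(v[0] / norm)


def _between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = float(np.hypot(v1[0], v1[1]))
    n2 = float(np.hypot(v2[0], v2[1]))
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("zero-length segment in three-point angle")
    return _clamped_arccos_deg(float(np.dot(v1, v2)) / (n1 * n2))


def center_of_mass(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> tuple[float, float]:
    """Unweighted mean position of all visible keypoints (raw pixels)."""
    pts = [_xy(kp) for kp in frame.keypoints if kp.is_visible(visibility_threshold)]
    if not pts:
        raise MissingKeypointError("no visible keypoints for center of mass")
    mean = np.mean(pts, axis=0)
    return float(mean[0]), float(mean[1])


def shoulder_nose_angle(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Angle at the nose between the two nose->shoulder vectors."""
    _require_visible(frame, ("nose", "left_shoulder", "right_shoulder"), visibility_threshold)
    b = _xy(frame.keypoint("nose"))
    ba = _xy(frame.keypoint("left_shoulder")) - b
    bc = _xy(frame.keypoint("right_shoulder")) - b
    return _between(ba, bc)


def torso_angle(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Inclination of the nose -> mid-hip axis from image vertical."""
    _require_visible(frame, ("nose", "left_hip", "right_hip"), visibility_threshold)
    mid_hip = midpoint(frame.keypoint("left_hip"), frame.keypoint("right_hip"), visibility_threshold)
    v = np.array(mid_hip) - _xy(frame.keypoint("nose"))
    return _vertical_angle(v)


def hip_angle(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Angle of the left-hip -> right-hip line against image horizontal."""
    _require_visible(frame, ("left_hip", "right_hip"), visibility_threshold)
    v = _xy(frame.keypoint("right_hip")) - _xy(frame.keypoint("left_hip"))
    return _horizontal_angle(v)


def shoulder_angle(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Angle of the left-shoulder -> right-shoulder line against image horizontal."""
    _require_visible(frame, ("left_shoulder", "right_shoulder"), visibility_threshold)
    v = _xy(frame.keypoint("right_shoulder")) - _xy(frame.keypoint("left_shoulder"))
    return _horizontal_angle(v)


def leg_angle(frame: PoseFrame, side: str, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Knee bend: angle between hip->knee and knee->ankle directions; 0 = straight."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    hip, knee, ankle = (f"{side}_hip", f"{side}_knee", f"{side}_ankle")
    _require_visible(frame, (hip, knee, ankle), visibility_threshold)
    v1 = _xy(frame.keypoint(knee)) - _xy(frame.keypoint(hip))
    v2 = _xy(frame.keypoint(ankle)) - _xy(frame.keypoint(knee))
    return _between(v1, v2)


def nose_to_ankle_angle(frame: PoseFrame, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> float:
    """Inclination of the nose -> mid-ankle axis from image vertical."""
    _require_visible(frame, ("nose", "left_ankle", "right_ankle"), visibility_threshold)
    mid_ankle = midpoint(frame.keypoint("left_ankle"), frame.keypoint("right_ankle"), visibility_threshold)
    v = np.array(mid_ankle) - _xy(frame.keypoint("nose"))
    return _vertical_angle(v)


def _bbox_of_visible(frame: PoseFrame, thr: float) -> tuple[float, float, float, float] | None:
    pts = [(kp.x, kp.y) for kp in frame.keypoints if kp.is_visible(thr)]
    if not pts:
        return None
    xs, ys = zip(*pts)
    return min(xs), min(ys), max(xs), max(ys)


def extract_features(
    frame: PoseFrame,
    bbox: tuple[float, float, float, float] | None = None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> FeatureVector:
    """Assemble all nine features; failures are flagged in the mask, never imputed.

    Center-of-mass coordinates are normalized to [0, 1] within `bbox`
    (x_min, y_min, x_max, y_max) when given, else within the min/max
    extent of the visible keypoints — this is what makes the feature
    vector independent of bounding-box size and position.
    """
    values: dict[str, float] = {}
    mask: list[bool] = []

    def attempt(name: str, fn) -> None:
        try:
            values[name] = float(fn())
            mask.append(True)
        except (MissingKeypointError, DegenerateGeometryError):
            values[name] = math.nan
            mask.append(False)

    def com_norm() -> tuple[float, float]:
        cx, cy = center_of_mass(frame, visibility_threshold)
        box = bbox if bbox is not None else _bbox_of_visible(frame, visibility_threshold)
        assert box is not None  # center_of_mass succeeded, so >=1 visible point
        x0, y0, x1, y1 = box
        w = x1 - x0
        h = y1 - y0
        nx = (cx - x0) / w if w > 0 else 0.5
        ny = (cy - y0) / h if h > 0 else 0.5
        return nx, ny

    try:
        nx, ny = com_norm()
        values["cm_x"], values["cm_y"] = nx, ny
        mask.extend([True, True])
    except MissingKeypointError:
        values["cm_x"] = values["cm_y"] = math.nan
        mask.extend([False, False])

    attempt("shoulder_nose", lambda: shoulder_nose_angle(frame, visibility_threshold))
    attempt("torso", lambda: torso_angle(frame, visibility_threshold))
    attempt("hip", lambda: hip_angle(frame, visibility_threshold))
    attempt("shoulder", lambda: shoulder_angle(frame, visibility_threshold))
    attempt("left_leg", lambda: leg_angle(frame, "left", visibility_threshold))
    attempt("right_leg", lambda: leg_angle(frame, "right", visibility_threshold))
    attempt("nose_ankle", lambda: nose_to_ankle_angle(frame, visibility_threshold))

    return FeatureVector(validity_mask=tuple(mask), **values)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def frames_to_table(
    frames,
    labels=None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> pd.DataFrame:
    """Extract features for a sequence of PoseFrames into a tidy DataFrame.

    Invalid features are NaN.  `labels` (optional) is a parallel sequence
    of 0/1 posture labels attached as a `label` column.
    """
    rows = []
    for frame in frames:
        fv = extract_features(frame, visibility_threshold=visibility_threshold)
        row = {"track_id": frame.track_id, "frame_index": frame.frame_index}
        row.update(dict(zip(FEATURE_NAMES, fv.to_array())))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if labels is not None:
        df["label"] = list(labels)
    return df


def write_feature_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_feature_table(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df
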