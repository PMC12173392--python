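"""Synthetic COCO-17 skeleton sequences with exact ground truth.

Scenarios cover standing/walking, lying, fast and gradual
standing->lying transitions (falls), and a crouching confounder, with
per-keypoint Gaussian jitter and missing-keypoint dropout.  Skeletons
are built from anatomically plausible templates in image coordinates
(y down); fall kinds rotate the whole standing skeleton about the
mid-ankle point, so the ground-truth torso inclination is known exactly
per frame.  Frame labels switch from standing (1) to lying (0) the
moment the ground-truth inclination crosses the 45-degree boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pifr.classify import LYING, STANDING
from pifr.errors import ConfigError
from pifr.features import FEATURE_NAMES, frames_to_table
from pifr.keypoints import COCO_KEYPOINT_NAMES, Keypoint, PoseFrame, TrackStream

SCENARIO_KINDS = ("standing", "walking", "lying", "fall_fast", "fall_gradual", "crouch_confounder")
_TRANSITION_KINDS = ("fall_fast", "fall_gradual", "crouch_confounder")

#: Ground-truth posture boundary on torso inclination, degrees.
POSTURE_BOUNDARY_DEG = 45.0

# Template layouts as (x, y_up) fractions of body height, mid-ankle at the
# origin, person facing the camera (their left on image right).
_STANDING_LAYOUT: dict[str, tuple[float, float]] = {
    "nose": (0.00, 0.95),
    "left_eye": (0.02, 0.97),
    "right_eye": (-0.02, 0.97),
    "left_ear": (0.04, 0.95),
    "right_ear": (-0.04, 0.95),
    "left_shoulder": (0.12, 0.80),
    "right_shoulder": (-0.12, 0.80),
    "left_elbow": (0.16, 0.62),
    "right_elbow": (-0.16, 0.62),
    "left_wrist": (0.18, 0.45),
    "right_wrist": (-0.18, 0.45),
    "left_hip": (0.08, 0.50),
    "right_hip": (-0.08, 0.50),
    "left_knee": (0.08, 0.25),
    "right_knee": (-0.08, 0.25),
    "left_ankle": (0.08, 0.00),
    "right_ankle": (-0.08, 0.00),
}

# Side-view squat: knees forward and sharply bent, torso pitched ~35 deg.
_CROUCH_LAYOUT: dict[str, tuple[float, float]] = {
    "nose": (0.24, 0.73),
    "left_eye": (0.27, 0.76),
    "right_eye": (0.25, 0.76),
    "left_ear": (0.23, 0.74),
    "right_ear": (0.21, 0.74),
    "left_shoulder": (0.20, 0.66),
    "right_shoulder": (0.14, 0.66),
    "left_elbow": (0.27, 0.52),
    "right_elbow": (0.23, 0.52),
    "left_wrist": (0.32, 0.38),
    "right_wrist": (0.28, 0.38),
    "left_hip": (0.01, 0.38),
    "right_hip": (-0.05, 0.38),
    "left_knee": (0.25, 0.22),
    "right_knee": (0.19, 0.22),
    "left_ankle": (0.03, 0.00),
    "right_ankle": (-0.03, 0.00),
}


def _layout_to_frame(layout: dict[str, tuple[float, float]], height_px: float, anchor: tuple[float, float], track_id: str = "t0", frame_index: int = 0) -> PoseFrame:
    ax, ay = anchor
    kps = []
    for name in COCO_KEYPOINT_NAMES:
        fx, fy = layout[name]
        kps.append(Keypoint(ax + fx * height_px, ay - fy * height_px, 1.0))
    return PoseFrame(track_id=track_id, frame_index=frame_index, keypoints=tuple(kps))


def rotate_frame(frame: PoseFrame, theta_deg: float, center: tuple[float, float]) -> PoseFrame:
    """Rigid rotation of every keypoint about `center` (image coordinates).

    Positive theta tips an upright skeleton towards image-x, increasing
    its torso inclination by exactly theta until the 180-degree fold.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    cx, cy = center
    kps = []
    for kp in frame.keypoints:
        dx, dy = kp.x - cx, kp.y - cy
        # y grows downward, so this matrix rotates nose->hip away from vertical by +theta
        kps.append(Keypoint(cx + c * dx + s * dy, cy - s * dx + c * dy, kp.confidence))
    return frame.with_keypoints(kps)


def _mid_ankle(frame: PoseFrame) -> tuple[float, float]:
    la, ra = frame.keypoint("left_ankle"), frame.keypoint("right_ankle")
    return ((la.x + ra.x) / 2.0, (la.y + ra.y) / 2.0)


def make_pose_template(
    posture: str,
    height_px: float = 170.0,
    anchor: tuple[float, float] = (320.0, 400.0),
    track_id: str = "t0",
    frame_index: int = 0,
) -> PoseFrame:
    """Canonical skeleton for one posture, anchored at the mid-ankle point.

    standing: torso/nose-ankle/leg angles ~ 0; lying: torso and
    nose-ankle ~ 90 (standing layout rotated to horizontal); crouch:
    knees bent > 70 with torso pitched 20-50.
    """
    if height_px <= 0:
        raise ConfigError(f"height_px must be > 0, got {height_px}")
    if posture == "standing":
        return _layout_to_frame(_STANDING_LAYOUT, height_px, anchor, track_id, frame_index)
    if posture == "lying":
        upright = _layout_to_frame(_STANDING_LAYOUT, height_px, anchor, track_id, frame_index)
        return rotate_frame(upright, 90.0, anchor)
    if posture == "crouch":
        return _layout_to_frame(_CROUCH_LAYOUT, height_px, anchor, track_id, frame_index)
    raise ConfigError(f"unknown posture {posture!r}; expected standing/lying/crouch")


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic sequence: kind, timing, noise and seed."""

    kind: str
    duration_frames: int
    fps: float = 30.0
    transition_start: int | None = None
    transition_len_frames: int | None = None
    jitter_sd: float = 2.0
    dropout_prob: float = 0.0
    rng_seed: int = 0
    height_px: float = 170.0
    anchor: tuple[float, float] = (320.0, 400.0)
    #: Inclination band (degrees) where fall-kind frames lose all keypoints,
    #: emulating pose-estimator failure mid-fall; None disables.
    blur_band: tuple[float, float] | None = (15.0, 75.0)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        if self.duration_frames < 1:
            raise ConfigError("duration_frames must be >= 1")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.jitter_sd < 0 or not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigError("jitter_sd must be >= 0 and dropout_prob in [0, 1]")
        if self.kind in _TRANSITION_KINDS:
            if self.transition_start is None or self.transition_len_frames is None:
                raise ConfigError(f"{self.kind} requires transition_start and transition_len_frames")
            if self.transition_len_frames < 1 or self.transition_start < 0:
                raise ConfigError("transition window must be non-negative start with positive length")
            if self.transition_start + self.transition_len_frames > self.duration_frames:
                raise ConfigError("transition window must fit inside duration_frames")


def default_scenario(kind: str, fps: float = 30.0, seed: int = 0, jitter_sd: float = 2.0, dropout_prob: float = 0.0) -> ScenarioSpec:
    """Sensible timing defaults: fast falls ~0.5 s, gradual ~3.5 s, and a
    post-fall lying tail longer than the default 5 s time criterion."""
    if kind in ("fall_fast", "fall_gradual"):
        start = int(round(2 * fps))
        length = int(round((0.5 if kind == "fall_fast" else 3.5) * fps))
        tail = int(round(6 * fps))
        return ScenarioSpec(kind=kind, duration_frames=start + length + tail, fps=fps, transition_start=start, transition_len_frames=length, jitter_sd=jitter_sd, dropout_prob=dropout_prob, rng_seed=seed)
    if kind == "crouch_confounder":
        start = int(round(2 * fps))
        length = int(round(3 * fps))
        return ScenarioSpec(kind=kind, duration_frames=start + length + int(round(3 * fps)), fps=fps, transition_start=start, transition_len_frames=length, jitter_sd=jitter_sd, dropout_prob=dropout_prob, rng_seed=seed)
    return ScenarioSpec(kind=kind, duration_frames=int(round(8 * fps)), fps=fps, jitter_sd=jitter_sd, dropout_prob=dropout_prob, rng_seed=seed)


@dataclass
class LabeledSequence:
    """A generated stream plus its exact ground truth."""

    stream: TrackStream
    frame_labels: list[int]
    is_fall: bool
    fall_frame: int | None
    inclination_deg: list[float] = field(default_factory=list)

    def labels_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": [f.track_id for f in self.stream.frames],
                "frame_index": [f.frame_index for f in self.stream.frames],
                "label": self.frame_labels,
            }
        )


def _blend(a: PoseFrame, b: PoseFrame, u: float) -> PoseFrame:
    kps = [
        Keypoint((1 - u) * ka.x + u * kb.x, (1 - u) * ka.y + u * kb.y, 1.0)
        for ka, kb in zip(a.keypoints, b.keypoints)
    ]
    return a.with_keypoints(kps)


def _smoothstep(u: float) -> float:
    return u * u * (3 - 2 * u)


def generate(spec: ScenarioSpec, track_id: str = "seq0") -> LabeledSequence:
    """Generate one labeled sequence; deterministic per rng_seed.

    Fall kinds rotate the standing skeleton about its mid-ankle from 0
    to 90 degrees across the transition window (smoothstep easing); the
    crouch confounder blends standing->crouch->standing; walking drifts
    the anchor horizontally with a light arm/leg swing.  Jitter and
    dropout are applied after ground truth is recorded, so labels are
    exact.
    """
    rng = np.random.default_rng(spec.rng_seed)
    from pifr.features import torso_angle  # ground-truth inclination of clean frames

    standing = make_pose_template("standing", spec.height_px, spec.anchor, track_id)
    crouch = make_pose_template("crouch", spec.height_px, spec.anchor, track_id)
    pivot = _mid_ankle(standing)

    frames: list[PoseFrame] = []
    labels: list[int] = []
    inclinations: list[float] = []
    fall_frame: int | None = None

    for t in range(spec.duration_frames):
        if spec.kind in ("fall_fast", "fall_gradual"):
            if t < spec.transition_start:
                incl = 0.0
            elif t >= spec.transition_start + spec.transition_len_frames:
                incl = 90.0
            else:
                u = (t - spec.transition_start + 1) / spec.transition_len_frames
                incl = 90.0 * _smoothstep(u)
            clean = rotate_frame(standing, incl, pivot)
        elif spec.kind == "lying":
            incl = 90.0
            clean = rotate_frame(standing, 90.0, pivot)
        elif spec.kind == "crouch_confounder":
            if t < spec.transition_start:
                u = 0.0
            elif t >= spec.transition_start + spec.transition_len_frames:
                u = 0.0
            else:
                # down-and-up: peak crouch at the middle of the window
                phase = (t - spec.transition_start) / max(spec.transition_len_frames - 1, 1)
                u = math.sin(math.pi * phase)
            clean = _blend(standing, crouch, u)
            incl = torso_angle(clean)
        else:  # standing or walking
            incl = 0.0
            clean = standing
            if spec.kind == "walking":
                drift = 0.4 * spec.height_px * t / max(spec.fps * 8, 1)
                sway = 0.02 * spec.height_px * math.sin(2 * math.pi * t / spec.fps)
                clean = clean.with_keypoints(
                    [Keypoint(kp.x + drift + (sway if i >= 13 else 0.0), kp.y, 1.0) for i, kp in enumerate(clean.keypoints)]
                )

        label = STANDING if incl < POSTURE_BOUNDARY_DEG else LYING
        if label == LYING and fall_frame is None and spec.kind in ("fall_fast", "fall_gradual"):
            fall_frame = t

        blurred = (
            spec.blur_band is not None
            and spec.kind in ("fall_fast", "fall_gradual")
            and spec.blur_band[0] < incl < spec.blur_band[1]
        )
        kps = []
        for kp in clean.keypoints:
            x = kp.x + (rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0)
            y = kp.y + (rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0)
            conf = 0.0 if blurred or (spec.dropout_prob > 0 and rng.uniform() < spec.dropout_prob) else 1.0
            kps.append(Keypoint(x, y, conf))
        frames.append(PoseFrame(track_id=track_id, frame_index=t, keypoints=tuple(kps), timestamp_s=t / spec.fps))
        labels.append(label)
        inclinations.append(float(incl))

    stream = TrackStream(fps=spec.fps, frames=frames)
    is_fall = spec.kind in ("fall_fast", "fall_gradual")
    return LabeledSequence(stream=stream, frame_labels=labels, is_fall=is_fall, fall_frame=fall_frame, inclination_deg=inclinations)


def generate_training_table(n_per_class: int, jitter_sd: float = 3.0, seed: int = 0) -> pd.DataFrame:
    """Labeled feature table: n standing + n lying jittered template frames.

    Class-conditional torso-angle means sit ~90 degrees apart, so any
    reasonable classifier separates the classes.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    frames: list[PoseFrame] = []
    labels: list[int] = []
    for cls, posture in ((STANDING, "standing"), (LYING, "lying")):
        template = make_pose_template(posture)
        for i in range(n_per_class):
            kps = [
                Keypoint(kp.x + rng.normal(0.0, jitter_sd), kp.y + rng.normal(0.0, jitter_sd), 1.0)
                for kp in template.keypoints
            ] if jitter_sd > 0 else list(template.keypoints)
            frames.append(PoseFrame(track_id=f"train_{posture}", frame_index=i, keypoints=tuple(kps)))
            labels.append(cls)
    return frames_to_table(frames, labels=labels)


def merge_streams(sequences: list[LabeledSequence], fps: float | None = None) -> TrackStream:
    """Concatenate single-person sequences (distinct track ids) into one stream."""
    frames: list[PoseFrame] = []
    for seq in sequences:
        frames.extend(seq.stream.frames)
    fps = fps if fps is not None else (sequences[0].stream.fps if sequences else 30.0)
    return TrackStream(fps=fps, frames=frames)
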