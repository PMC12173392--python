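"""Canonical skeleton data model and keypoint-stream I/O.

Coordinates follow image conventions: origin top-left, x rightward,
y downward.  A keypoint with confidence 0 is "missing" and its
coordinates carry no meaning.  Any pose-estimation backend sits behind
this module; the core never touches pixels.
"""

from __future__ import annotations

import json
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from pifr.errors import SchemaError, StreamIntegrityError, StreamParseError

#: COCO 17-landmark ordering; index in this tuple == index in PoseFrame.keypoints.
COCO_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_KEYPOINTS = 17

#: (left index, right index) pairs swapped under a horizontal flip.
LEFT_RIGHT_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2),  # eyes
    (3, 4),  # ears
    (5, 6),  # shoulders
    (7, 8),  # elbows
    (9, 10),  # wrists
    (11, 12),  # hips
    (13, 14),  # knees
    (15, 16),  # ankles
)

#: Default confidence below which a keypoint is treated as missing.
DEFAULT_VISIBILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class Keypoint:
    """One 2-D landmark with a detection confidence in [0, 1]."""

    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise SchemaError(f"keypoint confidence {self.confidence!r} outside [0, 1]")
        if self.confidence > 0 and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"visible keypoint has non-finite coordinates ({self.x}, {self.y})")

    def is_visible(self, threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> bool:
        return self.confidence >= threshold


@dataclass(frozen=True)
class PoseFrame:
    """One person in one frame: exactly 17 keypoints in COCO order."""

    track_id: str
    frame_index: int
    keypoints: tuple[Keypoint, ...]
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise SchemaError(
                f"track {self.track_id!r} frame {self.frame_index}: "
                f"expected {N_KEYPOINTS} keypoints, got {len(self.keypoints)}"
            )
        if self.frame_index < 0:
            raise SchemaError(f"negative frame_index {self.frame_index}")
        object.__setattr__(self, "keypoints", tuple(self.keypoints))

    def keypoint(self, name: str) -> Keypoint:
        return self.keypoints[COCO_KEYPOINT_NAMES.index(name)]

    def with_keypoints(self, keypoints: Sequence[Keypoint]) -> "PoseFrame":
        return replace(self, keypoints=tuple(keypoints))


@dataclass
class TrackStream:
    """Per-track, frame-ordered collection of PoseFrames at a fixed fps."""

    fps: float
    frames: list[PoseFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        self.frames = sorted(self.frames, key=lambda f: (f.track_id, f.frame_index))
        seen: set[tuple[str, int]] = set()
        for f in self.frames:
            key = (f.track_id, f.frame_index)
            if key in seen:
                raise StreamIntegrityError(f"duplicate (track, frame) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.frames)

    def track_ids(self) -> list[str]:
        return sorted({f.track_id for f in self.frames})

    def by_track(self) -> "OrderedDict[str, list[PoseFrame]]":
        out: OrderedDict[str, list[PoseFrame]] = OrderedDict()
        for f in self.frames:
            out.setdefault(f.track_id, []).append(f)
        return out

    def extend(self, frames: Iterable[PoseFrame]) -> None:
        self.frames.extend(frames)
        self.__post_init__()


def midpoint(a: Keypoint, b: Keypoint, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD) -> tuple[float, float]:
    """Midpoint of two visible keypoints.

    Raises MissingKeypointError if either keypoint is below the
    visibility threshold.
    """
    from pifr.errors import MissingKeypointError

    if not (a.is_visible(visibility_threshold) and b.is_visible(visibility_threshold)):
        raise MissingKeypointError("midpoint requires both keypoints visible")
    return ((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)


# ---------------------------------------------------------------------------
# JSONL dialect (canonical): one object per line with keys track_id,
# frame_index, optional timestamp_s, keypoints = flat list of 51 floats
# (x1, y1, c1, ..., x17, y17, c17).  A top-level header object with key
# "fps" is written first and expected (but not required) on read.
# ---------------------------------------------------------------------------


def _frame_from_record(rec: dict, where: str) -> PoseFrame:
    try:
        track_id = str(rec["track_id"])
        frame_index = int(rec["frame_index"])
        flat = rec["keypoints"]
    except (KeyError, TypeError, ValueError) as exc:
        raise StreamParseError(f"{where}: missing/invalid field ({exc})") from exc
    if not isinstance(flat, list) or len(flat) != 3 * N_KEYPOINTS:
        raise SchemaError(f"{where}: keypoints must be a flat list of {3 * N_KEYPOINTS} numbers, got {len(flat) if isinstance(flat, list) else type(flat).__name__}")
    kps = tuple(Keypoint(float(flat[i]), float(flat[i + 1]), float(flat[i + 2])) for i in range(0, 3 * N_KEYPOINTS, 3))
    ts = rec.get("timestamp_s")
    return PoseFrame(track_id=track_id, frame_index=frame_index, keypoints=kps, timestamp_s=None if ts is None else float(ts))


def _read_jsonl(path: Path) -> TrackStream:
    fps = 30.0
    frames: list[PoseFrame] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(rec, dict):
                raise StreamParseError(f"{path}:{lineno}: expected a JSON object")
            if "fps" in rec and "track_id" not in rec:
                fps = float(rec["fps"])
                continue
            frames.append(_frame_from_record(rec, f"{path}:{lineno}"))
    return TrackStream(fps=fps, frames=frames)


def _write_jsonl(stream: TrackStream, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"fps": stream.fps}) + "\n")
        for f in stream.frames:
            flat: list[float] = []
            for kp in f.keypoints:
                flat.extend((kp.x, kp.y, kp.confidence))
            rec: dict = {"track_id": f.track_id, "frame_index": f.frame_index, "keypoints": flat}
            if f.timestamp_s is not None:
                rec["timestamp_s"] = f.timestamp_s
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# COCO keypoint JSON (read-only subset): images + annotations with
# "keypoints" arrays of 51 numbers; v-flag mapped to confidence 0/0.5/1.
# ---------------------------------------------------------------------------

_V_FLAG_CONFIDENCE = {0: 0.0, 1: 0.5, 2: 1.0}


def _read_coco_json(path: Path) -> TrackStream:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise StreamParseError(f"{path}: invalid JSON ({exc.msg})") from exc
    if not isinstance(doc, dict) or "annotations" not in doc:
        raise StreamParseError(f"{path}: not a COCO keypoint document (no 'annotations')")
    image_order: dict[int, int] = {}
    for i, img in enumerate(doc.get("images", [])):
        image_order[int(img["id"])] = int(img.get("frame_index", i))
    frames: list[PoseFrame] = []
    for n, ann in enumerate(doc["annotations"]):
        flat = ann.get("keypoints")
        if not isinstance(flat, list) or len(flat) != 3 * N_KEYPOINTS:
            raise SchemaError(f"{path}: annotation {n}: keypoints must have {3 * N_KEYPOINTS} entries")
        kps = []
        for i in range(0, 3 * N_KEYPOINTS, 3):
            v = int(flat[i + 2])
            conf = _V_FLAG_CONFIDENCE.get(v)
            if conf is None:
                raise SchemaError(f"{path}: annotation {n}: visibility flag {v} not in {{0,1,2}}")
            kps.append(Keypoint(float(flat[i]), float(flat[i + 1]), conf))
        image_id = int(ann["image_id"])
        frame_index = image_order.get(image_id, image_id)
        track = str(ann.get("track_id", ann.get("id", n)))
        frames.append(PoseFrame(track_id=track, frame_index=frame_index, keypoints=tuple(kps)))
    fps = float(doc.get("info", {}).get("fps", 30.0)) if isinstance(doc.get("info"), dict) else 30.0
    return TrackStream(fps=fps, frames=frames)


_DIALECTS = ("jsonl", "coco-json")


def read_keypoint_stream(path: str | Path, dialect: str = "jsonl") -> TrackStream:
    """Read and validate a keypoint stream.

    Out-of-order frames within a track are sorted; duplicate
    (track, frame) pairs raise StreamIntegrityError; malformed records
    raise StreamParseError or SchemaError naming the offending record.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    return _read_coco_json(path)


def write_keypoint_stream(stream: TrackStream, path: str | Path, dialect: str = "jsonl") -> None:
    """Write a TrackStream; only the canonical JSONL dialect is writable."""
    if dialect != "jsonl":
        raise ValueError(f"write supports only the 'jsonl' dialect, got {dialect!r}")
    _write_jsonl(stream, Path(path))


# Pose-backend adapter: anything callable on an image yielding PoseFrames.
PoseBackend = Callable[[object, int], Iterable[PoseFrame]]


def null_backend(image: object, frame_index: int) -> Iterator[PoseFrame]:
    """Adapter stub that detects nobody; real detector bindings are extras."""
    return iter(())
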