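"""Temporal fall confirmation: per-track state over frame-level posture labels.

Three configurable criteria turn a run of lying-labeled frames into a
confirmed fall event:

* time rule — the lying run has lasted >= time_threshold_s seconds;
* frame rule — the lying run spans >= frame_threshold frames;
* speed rule — the standing->lying transition took <= speed_threshold
  frames AND the run has persisted >= confirm_frames (flicker guard).

Enabled rules combine with any/all semantics; one lying run yields at
most one event; a standing label clears the fall flag and resets the
run.  A track that vanishes for more than gap_tolerance frames has its
state reset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pifr.classify import LYING, STANDING, EvalReport, report_from_counts
from pifr.errors import ConfigError, SequencingError

logger = logging.getLogger(__name__)

#: Fixed reporting order for satisfied criteria.
CRITERION_ORDER = ("time", "frame", "speed")


@dataclass(frozen=True)
class FallCriteria:
    """Configurable temporal rules; None disables a rule.

    Defaults enable only the 5-second time rule.
    """

    time_threshold_s: float | None = 5.0
    frame_threshold: int | None = None
    speed_threshold_frames: int | None = None
    confirm_frames: int = 15
    combine_mode: str = "any"
    gap_tolerance: int = 30

    def __post_init__(self) -> None:
        if self.combine_mode not in ("any", "all"):
            raise ConfigError(f"combine_mode must be 'any' or 'all', got {self.combine_mode!r}")
        if not self.enabled_criteria():
            raise ConfigError("at least one fall criterion must be enabled")
        for name, value in (
            ("time_threshold_s", self.time_threshold_s),
            ("frame_threshold", self.frame_threshold),
            ("speed_threshold_frames", self.speed_threshold_frames),
        ):
            if value is not None and value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.confirm_frames < 1:
            raise ConfigError(f"confirm_frames must be >= 1, got {self.confirm_frames}")
        if self.gap_tolerance < 0:
            raise ConfigError(f"gap_tolerance must be >= 0, got {self.gap_tolerance}")

    def enabled_criteria(self) -> tuple[str, ...]:
        enabled = []
        if self.time_threshold_s is not None:
            enabled.append("time")
        if self.frame_threshold is not None:
            enabled.append("frame")
        if self.speed_threshold_frames is not None:
            enabled.append("speed")
        return tuple(enabled)


@dataclass
class TrackState:
    """Rolling classification history of one person track."""

    track_id: str
    last_label: int | None = None
    lying_run_start: int | None = None
    last_standing_frame: int | None = None
    fall_flagged: bool = False
    last_seen_frame: int | None = None
    frames_since_seen: int = 0

    def reset(self) -> None:
        self.last_label = None
        self.lying_run_start = None
        self.last_standing_frame = None
        self.fall_flagged = False
        self.frames_since_seen = 0


@dataclass(frozen=True)
class FallEvent:
    """A confirmed fall for one track."""

    track_id: str
    trigger_frame: int
    lying_onset_frame: int
    criterion: tuple[str, ...]
    transition_duration_frames: int | None = None

    def __post_init__(self) -> None:
        if self.trigger_frame < self.lying_onset_frame:
            raise ValueError("trigger_frame must be >= lying_onset_frame")

    def to_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "trigger_frame": self.trigger_frame,
            "lying_onset_frame": self.lying_onset_frame,
            "criterion": list(self.criterion),
            "transition_duration_frames": self.transition_duration_frames,
        }


def step(
    state: TrackState,
    frame_index: int,
    label: int,
    criteria: FallCriteria,
    fps: float,
) -> tuple[TrackState, FallEvent | None]:
    """Advance one track by one labeled frame; mutates and returns `state`.

    Frame indices must be strictly increasing per track.  Criteria are
    evaluated on every lying frame until the run fires once.
    """
    if label not in (LYING, STANDING):
        raise ValueError(f"label must be 0 (lying) or 1 (standing), got {label!r}")
    if state.last_seen_frame is not None:
        if frame_index <= state.last_seen_frame:
            raise SequencingError(
                f"track {state.track_id!r}: frame {frame_index} not after {state.last_seen_frame}"
            )
        state.frames_since_seen = frame_index - state.last_seen_frame - 1
        if state.frames_since_seen > criteria.gap_tolerance:
            logger.debug("track %s: gap of %d frames, state reset", state.track_id, state.frames_since_seen)
            state.reset()
    state.last_seen_frame = frame_index

    event: FallEvent | None = None
    if label == STANDING:
        state.lying_run_start = None
        state.last_standing_frame = frame_index
        state.fall_flagged = False
    else:
        if state.lying_run_start is None:
            state.lying_run_start = frame_index
        if not state.fall_flagged:
            run_len = frame_index - state.lying_run_start + 1
            transition: int | None = None
            if state.last_standing_frame is not None:
                transition = state.lying_run_start - state.last_standing_frame
            satisfied = []
            if criteria.time_threshold_s is not None and run_len / fps >= criteria.time_threshold_s:
                satisfied.append("time")
            if criteria.frame_threshold is not None and run_len >= criteria.frame_threshold:
                satisfied.append("frame")
            if (
                criteria.speed_threshold_frames is not None
                and transition is not None
                and transition <= criteria.speed_threshold_frames
                and run_len >= criteria.confirm_frames
            ):
                satisfied.append("speed")
            enabled = criteria.enabled_criteria()
            fired = bool(satisfied) if criteria.combine_mode == "any" else set(satisfied) == set(enabled)
            if fired:
                state.fall_flagged = True
                event = FallEvent(
                    track_id=state.track_id,
                    trigger_frame=frame_index,
                    lying_onset_frame=state.lying_run_start,
                    criterion=tuple(c for c in CRITERION_ORDER if c in satisfied),
                    transition_duration_frames=transition,
                )
                logger.info("Falling Detected: track=%s frame=%d criterion=%s", state.track_id, frame_index, "+".join(event.criterion))
    state.last_label = label
    return state, event


LabeledFrames = Sequence[tuple[int, int]]  # (frame_index, label) pairs


def detect(
    track_labels: Mapping[str, LabeledFrames] | pd.DataFrame,
    criteria: FallCriteria | None = None,
    fps: float = 30.0,
) -> list[FallEvent]:
    """Fold `step` over every track independently; events sorted by trigger frame.

    Accepts either a mapping track_id -> [(frame_index, label), ...] or a
    DataFrame with track_id / frame_index / label columns.
    """
    criteria = criteria or FallCriteria()
    if isinstance(track_labels, pd.DataFrame):
        grouped: dict[str, list[tuple[int, int]]] = {}
        for tid, sub in track_labels.groupby("track_id", sort=True):
            grouped[str(tid)] = list(zip(sub["frame_index"].astype(int), sub["label"].astype(int)))
        track_labels = grouped
    events: list[FallEvent] = []
    for track_id, labeled in track_labels.items():
        state = TrackState(track_id=str(track_id))
        for frame_index, label in labeled:
            state, event = step(state, int(frame_index), int(label), criteria, fps)
            if event is not None:
                events.append(event)
    return sorted(events, key=lambda e: (e.trigger_frame, e.track_id))


def events_to_report(events: Iterable[FallEvent], truth: Mapping[str, bool]) -> EvalReport:
    """Sequence-level confusion over per-sequence fall/no-fall ground truth.

    `truth` maps sequence (track) id -> whether a fall truly occurs.  A
    sequence counts TP when >= 1 event fires on a fall sequence, FP when
    one fires on a no-fall sequence, and so on.
    """
    flagged = {e.track_id for e in events}
    unknown = flagged - set(truth)
    if unknown:
        raise ConfigError(f"events reference ids absent from ground truth: {sorted(unknown)}")
    tp = sum(1 for sid, fall in truth.items() if fall and sid in flagged)
    fn = sum(1 for sid, fall in truth.items() if fall and sid not in flagged)
    fp = sum(1 for sid, fall in truth.items() if not fall and sid in flagged)
    tn = sum(1 for sid, fall in truth.items() if not fall and sid not in flagged)
    return report_from_counts(tp, tn, fp, fn, auc=None)


def write_events(events: Sequence[FallEvent], path) -> None:
    """Write events.json: a JSON list of event objects with sorted keys."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=2, sort_keys=True)
        fh.write("\n")
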