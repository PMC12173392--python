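"""End-to-end orchestration: extract -> preprocess -> classify -> detect."""

from __future__ import annotations

import json
import logging

import pandas as pd

from pifr.classify import FittedModel, load_model, predict
from pifr.config import PipelineConfig
from pifr.detect import FallEvent, detect, events_to_report, write_events
from pifr.errors import ConfigError
from pifr.features import frames_to_table
from pifr.keypoints import TrackStream, read_keypoint_stream
from pifr.preprocess import resolve_missing, smooth_features

logger = logging.getLogger(__name__)


def label_stream(stream: TrackStream, model: FittedModel, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features + per-frame labels for every track of a stream.

    Returns (feature table, label table); the label table has
    track_id / frame_index / label columns ready for `detect`.
    Smoothing and missing-data policy run per track in frame order;
    the model applies its own fitted normalization.
    """
    cfg = config.preprocess
    all_features = []
    labeled = []
    for track_id, frames in stream.by_track().items():
        table = frames_to_table(frames, visibility_threshold=cfg.visibility_threshold)
        all_features.append(table)
        table = smooth_features(table, cfg)
        table = resolve_missing(table, cfg)
        if table.empty:
            logger.warning("track %s: no usable frames after preprocessing", track_id)
            continue
        labels = predict(model, table)
        labeled.append(pd.DataFrame({"track_id": table["track_id"], "frame_index": table["frame_index"], "label": labels}))
    features = pd.concat(all_features, ignore_index=True) if all_features else frames_to_table([])
    label_table = (
        pd.concat(labeled, ignore_index=True)
        if labeled
        else pd.DataFrame(columns=["track_id", "frame_index", "label"])
    )
    return features, label_table


def run_pipeline(config: PipelineConfig) -> tuple[list[FallEvent], dict]:
    """Full run driven by config.paths; returns (events, reports).

    Required paths: keypoints (stream to analyse) and model (fitted
    artifact).  Optional outputs: features, labels, events, report;
    optional truth_manifest (CSV sequence_id,is_fall) enables a
    sequence-level evaluation report.
    """
    paths = config.paths
    for required in ("keypoints", "model"):
        if required not in paths:
            raise ConfigError(f"paths.{required} is required for a pipeline run")

    stream = read_keypoint_stream(paths["keypoints"])
    fps = config.fps if config.fps is not None else stream.fps
    if config.criteria.time_threshold_s is not None and fps is None:
        raise ConfigError("fps is required when the time criterion is enabled")
    model = load_model(paths["model"])
    logger.info("pipeline: %d frames, %d tracks, fps=%s", len(stream), len(stream.track_ids()), fps)

    features, label_table = label_stream(stream, model, config)
    events = detect(label_table, config.criteria, fps)

    reports: dict = {"n_events": len(events)}
    if "truth_manifest" in paths:
        manifest = pd.read_csv(paths["truth_manifest"])
        truth = {str(r.sequence_id): bool(r.is_fall) for r in manifest.itertuples()}
        report = events_to_report(events, truth)
        reports["sequence_report"] = report.to_dict()

    if "features" in paths:
        features.to_csv(paths["features"], index=False)
    if "labels" in paths:
        label_table.to_csv(paths["labels"], index=False)
    if "events" in paths:
        write_events(events, paths["events"])
    if "report" in paths:
        with open(paths["report"], "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return events, reports
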