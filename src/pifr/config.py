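"""YAML-backed pipeline configuration with fail-fast validation.

Unknown keys are rejected at parse time so typos never silently fall
back to defaults.  serialize(parse(yaml)) is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from pifr.classify import ClassifierSpec
from pifr.detect import FallCriteria
from pifr.errors import ConfigError
from pifr.preprocess import AugmentConfig, PreprocessConfig

_KNOWN_PATH_KEYS = {"keypoints", "model", "features", "events", "labels", "report", "out_dir", "truth_manifest"}


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")


def _preprocess_from(d: dict) -> PreprocessConfig:
    _check_keys("preprocess", d, {"smoothing_window", "smoothing_mode", "angle_norm", "missing_policy", "visibility_threshold"})
    return PreprocessConfig(**d)


def _augment_from(d: dict) -> AugmentConfig:
    _check_keys("augment", d, {"rotation_range", "scale_range", "hflip_prob", "noise_sigma", "rng_seed"})
    d = dict(d)
    for key in ("rotation_range", "scale_range"):
        if key in d:
            d[key] = tuple(d[key])
    return AugmentConfig(**d)


def _classifier_from(d: dict) -> ClassifierSpec:
    _check_keys("classifier", d, {"family", "hyperparameters", "rng_seed"})
    return ClassifierSpec(**d)


def _criteria_from(d: dict) -> FallCriteria:
    _check_keys("criteria", d, {"time_threshold_s", "frame_threshold", "speed_threshold_frames", "confirm_frames", "combine_mode", "gap_tolerance"})
    return FallCriteria(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs for an end-to-end extract -> classify -> detect run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    criteria: FallCriteria = field(default_factory=FallCriteria)
    fps: float | None = None
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fps is not None and self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        _check_keys("paths", self.paths, _KNOWN_PATH_KEYS)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys("config", d, {"preprocess", "augment", "classifier", "criteria", "fps", "paths", "log_level"})
        return cls(
            preprocess=_preprocess_from(d.get("preprocess", {}) or {}),
            augment=_augment_from(d.get("augment", {}) or {}),
            classifier=_classifier_from(d.get("classifier", {}) or {}),
            criteria=_criteria_from(d.get("criteria", {}) or {}),
            fps=d.get("fps"),
            paths=dict(d.get("paths", {}) or {}),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        return {
            "preprocess": {
                "smoothing_window": self.preprocess.smoothing_window,
                "smoothing_mode": self.preprocess.smoothing_mode,
                "angle_norm": self.preprocess.angle_norm,
                "missing_policy": self.preprocess.missing_policy,
                "visibility_threshold": self.preprocess.visibility_threshold,
            },
            "augment": {
                "rotation_range": list(self.augment.rotation_range),
                "scale_range": list(self.augment.scale_range),
                "hflip_prob": self.augment.hflip_prob,
                "noise_sigma": self.augment.noise_sigma,
                "rng_seed": self.augment.rng_seed,
            },
            "classifier": {
                "family": self.classifier.family,
                "hyperparameters": dict(self.classifier.hyperparameters),
                "rng_seed": self.classifier.rng_seed,
            },
            "criteria": {
                "time_threshold_s": self.criteria.time_threshold_s,
                "frame_threshold": self.criteria.frame_threshold,
                "speed_threshold_frames": self.criteria.speed_threshold_frames,
                "confirm_frames": self.criteria.confirm_frames,
                "combine_mode": self.criteria.combine_mode,
                "gap_tolerance": self.criteria.gap_tolerance,
            },
            "fps": self.fps,
            "paths": dict(self.paths),
            "log_level": self.log_level,
        }


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return PipelineConfig.from_dict(doc or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
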