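"""Smoothing, normalization, keypoint-space augmentation, missing-data policy.

Feature series are pandas DataFrames with the columns of
``features.FEATURE_NAMES`` (NaN marks an invalid entry), one track at a
time, in frame order.  Augmentation operates on keypoints, not pixels:
rotation/scale/flip/noise in keypoint space are the exact geometric
images of the corresponding image-space transforms, and they are meant
for training data only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pifr.errors import ConfigError
from pifr.features import ANGLE_NAMES, FEATURE_NAMES
from pifr.keypoints import DEFAULT_VISIBILITY_THRESHOLD, LEFT_RIGHT_PAIRS, Keypoint, PoseFrame

logger = logging.getLogger(__name__)

_SMOOTHING_MODES = ("causal", "centered")
_ANGLE_NORMS = ("degrees_over_180", "zscore", "none")
_MISSING_POLICIES = ("drop_frame", "forward_fill")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the smoothing/normalization/missing-data stage.

    Defaults favour online use: a short causal window (no future frames)
    and the deterministic degrees/180 normalization.
    """

    smoothing_window: int = 5
    smoothing_mode: str = "causal"
    angle_norm: str = "degrees_over_180"
    missing_policy: str = "drop_frame"
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ConfigError(f"smoothing_window must be >= 1, got {self.smoothing_window}")
        if self.smoothing_mode not in _SMOOTHING_MODES:
            raise ConfigError(f"smoothing_mode must be one of {_SMOOTHING_MODES}, got {self.smoothing_mode!r}")
        if self.angle_norm not in _ANGLE_NORMS:
            raise ConfigError(f"angle_norm must be one of {_ANGLE_NORMS}, got {self.angle_norm!r}")
        if self.missing_policy not in _MISSING_POLICIES:
            raise ConfigError(f"missing_policy must be one of {_MISSING_POLICIES}, got {self.missing_policy!r}")
        if not 0.0 <= self.visibility_threshold <= 1.0:
            raise ConfigError(f"visibility_threshold must be in [0, 1], got {self.visibility_threshold}")


@dataclass(frozen=True)
class AugmentConfig:
    """Keypoint-space augmentation ranges (training data only)."""

    rotation_range: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.75, 1.25)
    hflip_prob: float = 0.5
    noise_sigma: float = 0.01  # fraction of the person bbox diagonal
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_range", "scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered (low <= high), got ({lo}, {hi})")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ConfigError(f"hflip_prob must be in [0, 1], got {self.hflip_prob}")
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def smooth_features(series: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Moving-average filter over every feature channel of one track.

    Invalid (NaN) entries are excluded from each window's average; an
    entry that was invalid stays invalid (imputation is the job of
    resolve_missing).  Window 1 is the identity.  Windows are truncated
    at the series edges.
    """
    if series.empty:
        return series.copy()
    out = series.copy()
    cols = [c for c in FEATURE_NAMES if c in series.columns]
    block = series[cols]
    if cfg.smoothing_mode == "centered":
        smoothed = block.rolling(cfg.smoothing_window, min_periods=1, center=True).mean()
    else:
        smoothed = block.rolling(cfg.smoothing_window, min_periods=1).mean()
    smoothed = smoothed.where(block.notna())  # keep invalid entries invalid
    out[cols] = smoothed
    return out


class FeatureNormalizer:
    """Fitted normalization transform applied identically at train and inference.

    degrees_over_180: angles / 180 (stateless); zscore: per-channel
    standardization with population statistics learned from the training
    table; none: identity.
    """

    def __init__(self, mode: str = "degrees_over_180"):
        if mode not in _ANGLE_NORMS:
            raise ConfigError(f"unknown angle_norm {mode!r}")
        self.mode = mode
        self.means_: pd.Series | None = None
        self.stds_: pd.Series | None = None

    def fit(self, series: pd.DataFrame) -> "FeatureNormalizer":
        if self.mode == "zscore":
            cols = [c for c in FEATURE_NAMES if c in series.columns]
            self.means_ = series[cols].mean()
            stds = series[cols].std(ddof=0)
            zero = stds == 0
            if zero.any():
                logger.warning("zscore: zero-variance channels %s left with unit divisor", list(stds.index[zero]))
                stds[zero] = 1.0
            self.stds_ = stds
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        out = series.copy()
        if self.mode == "none":
            return out
        if self.mode == "degrees_over_180":
            cols = [c for c in ANGLE_NAMES if c in series.columns]
            out[cols] = out[cols] / 180.0
            return out
        if self.means_ is None or self.stds_ is None:
            raise ConfigError("zscore normalizer used before fit()")
        cols = list(self.means_.index)
        out[cols] = (out[cols] - self.means_) / self.stds_
        return out

    def fit_transform(self, series: pd.DataFrame) -> pd.DataFrame:
        return self.fit(series).transform(series)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "means": None if self.means_ is None else self.means_.to_dict(),
            "stds": None if self.stds_ is None else self.stds_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        obj = cls(d["mode"])
        if d.get("means") is not None:
            obj.means_ = pd.Series(d["means"])
            obj.stds_ = pd.Series(d["stds"])
        return obj


def normalize_features(series: pd.DataFrame, cfg: PreprocessConfig, normalizer: FeatureNormalizer | None = None) -> pd.DataFrame:
    """Normalize a (smoothed) feature series.

    For zscore a fitted normalizer must be supplied (statistics come
    from the training set); for the stateless modes one is built on the
    fly.
    """
    if normalizer is None:
        normalizer = FeatureNormalizer(cfg.angle_norm)
        if cfg.angle_norm == "zscore":
            normalizer.fit(series)
    return normalizer.transform(series)


def resolve_missing(series: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Resolve NaN features: drop the frame, or forward-fill short gaps.

    forward_fill carries the last valid value across gaps of at most
    ``smoothing_window`` frames; longer gaps drop the frame.
    """
    cols = [c for c in FEATURE_NAMES if c in series.columns]
    if series.empty:
        return series.copy()
    if cfg.missing_policy == "drop_frame":
        out = series.dropna(subset=cols)
    else:
        filled = series.copy()
        filled[cols] = filled[cols].ffill(limit=cfg.smoothing_window)
        out = filled.dropna(subset=cols)
    if out.empty and not series.empty:
        logger.warning("resolve_missing: all %d frames dropped", len(series))
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Keypoint-space augmentation
# ---------------------------------------------------------------------------


def _visible_coords(frame: PoseFrame, thr: float) -> np.ndarray:
    return np.array([(kp.x, kp.y) for kp in frame.keypoints if kp.is_visible(thr)], dtype=float)


def augment_keypoints(
    frame: PoseFrame,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> PoseFrame:
    """Random rotation, scaling, horizontal flip, and coordinate noise.

    Applied in that order, all about the visible-keypoint centroid;
    confidences are untouched, so the output is a valid PoseFrame.
    Deterministic for a given generator state.
    """
    coords = np.array([(kp.x, kp.y) for kp in frame.keypoints], dtype=float)
    visible = _visible_coords(frame, visibility_threshold)
    center = visible.mean(axis=0) if len(visible) else coords.mean(axis=0)

    theta = math.radians(rng.uniform(*cfg.rotation_range))
    scale = rng.uniform(*cfg.scale_range)
    do_flip = rng.uniform() < cfg.hflip_prob

    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    coords = (coords - center) @ rot.T * scale + center

    order = np.arange(len(frame.keypoints))
    if do_flip:
        coords[:, 0] = 2 * center[0] - coords[:, 0]
        for li, ri in LEFT_RIGHT_PAIRS:
            order[li], order[ri] = order[ri], order[li]

    if cfg.noise_sigma > 0 and len(visible):
        span = visible.max(axis=0) - visible.min(axis=0)
        diag = float(np.hypot(span[0], span[1]))
        if diag > 0:
            coords = coords + rng.normal(0.0, cfg.noise_sigma * diag, size=coords.shape)

    new_kps = []
    for i in order:
        src = frame.keypoints[i]
        x, y = coords[i]
        if src.confidence == 0.0 and not (math.isfinite(x) and math.isfinite(y)):
            x, y = 0.0, 0.0  # missing keypoints carry no meaning
        new_kps.append(Keypoint(float(x), float(y), src.confidence))
    return frame.with_keypoints(new_kps)


def augment_frames(frames, cfg: AugmentConfig, visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD):
    """Augment a sequence of frames with a fresh seeded generator."""
    rng = np.random.default_rng(cfg.rng_seed)
    return [augment_keypoints(f, cfg, rng, visibility_threshold) for f in frames]
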