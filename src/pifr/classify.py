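"""Frame-level standing/lying classifier: train, persist, apply, evaluate.

Class coding: 0 = lying, 1 = standing.  The shipped default is a
soft-margin SVM with an RBF kernel (C = 1.0, gamma = 0.1); decision
tree, random forest and gradient-boosting families are available behind
the same interface for comparison.  The fitted normalization transform
travels with the model so inference inputs are transformed identically.
"""

from __future__ import annotations

import datetime
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from pifr.errors import ConfigError, ModelIOError
from pifr.features import FEATURE_NAMES
from pifr.preprocess import FeatureNormalizer

try:  # the gradient-boosting family prefers xgboost when present
    from xgboost import XGBClassifier  # type: ignore

    _HAVE_XGBOOST = True
except ImportError:  # pragma: no cover - depends on environment
    from sklearn.ensemble import GradientBoostingClassifier

    _HAVE_XGBOOST = False

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

LYING, STANDING = 0, 1

_FAMILY_DEFAULTS: dict[str, dict] = {
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": 0.1},
    "decision_tree": {"max_depth": 5, "min_samples_split": 2},
    "random_forest": {"n_estimators": 100, "max_features": "sqrt", "max_depth": 10},
    "xgboost": {"n_estimators": 200, "learning_rate": 0.0045, "max_depth": 4},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Family + hyperparameters; unspecified values fall back to the defaults above."""

    family: str = "svm"
    hyperparameters: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_DEFAULTS:
            raise ConfigError(f"unknown classifier family {self.family!r}; expected one of {sorted(_FAMILY_DEFAULTS)}")
        params = self.resolved_hyperparameters()
        for key in ("C", "gamma", "learning_rate"):
            if key in params and not params[key] > 0:
                raise ConfigError(f"{key} must be > 0, got {params[key]}")
        for key in ("max_depth", "min_samples_split", "n_estimators"):
            if key in params and params[key] is not None and int(params[key]) <= 0:
                raise ConfigError(f"{key} must be a positive integer, got {params[key]}")

    def resolved_hyperparameters(self) -> dict:
        params = dict(_FAMILY_DEFAULTS[self.family])
        unknown = set(self.hyperparameters) - set(params)
        if unknown:
            raise ConfigError(f"unknown hyperparameters for family {self.family!r}: {sorted(unknown)}")
        params.update(self.hyperparameters)
        return params

    def build_estimator(self, class_weight=None):
        p = self.resolved_hyperparameters()
        if self.family == "svm":
            return SVC(C=p["C"], kernel=p["kernel"], gamma=p["gamma"], class_weight=class_weight, random_state=self.rng_seed)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(
                max_depth=p["max_depth"], min_samples_split=p["min_samples_split"], class_weight=class_weight, random_state=self.rng_seed
            )
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=p["n_estimators"],
                max_features=p["max_features"],
                max_depth=p["max_depth"],
                class_weight=class_weight,
                random_state=self.rng_seed,
            )
        # gradient boosting: xgboost when installed, sklearn otherwise
        if _HAVE_XGBOOST:  # pragma: no cover - depends on environment
            return XGBClassifier(
                n_estimators=p["n_estimators"], learning_rate=p["learning_rate"], max_depth=p["max_depth"], random_state=self.rng_seed
            )
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"], learning_rate=p["learning_rate"], max_depth=p["max_depth"], random_state=self.rng_seed
        )


@dataclass
class FittedModel:
    """Trained classifier plus the transform and metadata needed to reuse it."""

    spec: ClassifierSpec
    normalizer: FeatureNormalizer
    estimator: object
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the derived rates; auc is None when undefined."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float | None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def report_from_counts(tp: int, tn: int, fp: int, fn: int, auc: float | None = None) -> EvalReport:
    """Build an EvalReport from a confusion table using the standard formulas."""
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy, precision=precision, recall=recall, f1=f1, specificity=specificity, auc=auc)


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ConfigError(f"feature table missing columns: {missing}")
    x = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature table contains NaN; resolve missing features before training/prediction")
    return x


def train(
    table: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    angle_norm: str = "degrees_over_180",
    class_weight=None,
) -> FittedModel:
    """Fit a posture classifier on a labeled feature table.

    The table must hold the nine feature columns plus a `label` column
    of 0/1 with at least one sample of each class; NaN features are a
    validation error (resolve them upstream).  Deterministic under a
    fixed spec.rng_seed.
    """
    spec = spec or ClassifierSpec()
    if "label" not in table.columns:
        raise ConfigError("training table must have a 'label' column")
    y = table["label"].to_numpy(dtype=int)
    if not set(np.unique(y)) <= {LYING, STANDING}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(set(y))}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class; need both lying and standing samples")

    normalizer = FeatureNormalizer(angle_norm)
    normalized = normalizer.fit_transform(table[list(FEATURE_NAMES)])
    x = _feature_matrix(normalized)

    estimator = spec.build_estimator(class_weight=class_weight)
    estimator.fit(x, y)
    n = len(y)
    model = FittedModel(
        spec=spec,
        normalizer=normalizer,
        estimator=estimator,
        metadata={
            "n_samples": n,
            "n_lying": int((y == LYING).sum()),
            "n_standing": int((y == STANDING).sum()),
            "seed": spec.rng_seed,
            "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )
    logger.info("trained %s on %d samples", spec.family, n)
    return model


def predict(model: FittedModel, table: pd.DataFrame, return_scores: bool = False):
    """Predict one 0/1 posture label per row; optionally a real-valued score.

    Scores (SVM margin or positive-class probability) order frames by
    standing-ness and feed the ROC/AUC computation.
    """
    if table.empty:
        labels = np.array([], dtype=int)
        return (labels, np.array([])) if return_scores else labels
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ConfigError(f"feature table missing columns: {missing}")
    x = _feature_matrix(model.normalizer.transform(table[list(FEATURE_NAMES)]))
    labels = np.asarray(model.estimator.predict(x), dtype=int)
    if not return_scores:
        return labels
    if hasattr(model.estimator, "decision_function"):
        scores = np.asarray(model.estimator.decision_function(x), dtype=float)
    else:
        scores = np.asarray(model.estimator.predict_proba(x)[:, 1], dtype=float)
    return labels, scores


def evaluate(model: FittedModel, table: pd.DataFrame) -> EvalReport:
    """Confusion counts, accuracy/precision/recall/F1, and trapezoidal ROC AUC.

    Standing (1) is the positive class.  AUC is reported as None with a
    warning when the evaluation set holds a single class.
    """
    if "label" not in table.columns:
        raise ConfigError("evaluation table must have a 'label' column")
    y = table["label"].to_numpy(dtype=int)
    pred, scores = predict(model, table, return_scores=True)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if len(np.unique(y)) < 2:
        logger.warning("evaluate: single-class evaluation set, AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(y, scores))
    return report_from_counts(tp, tn, fp, fn, auc=auc)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model as a single versioned artifact."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": {"family": model.spec.family, "hyperparameters": model.spec.hyperparameters, "rng_seed": model.spec.rng_seed},
        "normalizer": model.normalizer.to_dict(),
        "estimator": model.estimator,
        "metadata": model.metadata,
    }
    try:
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)
    except OSError as exc:
        raise ModelIOError(f"cannot write model to {path}: {exc}") from exc


def load_model(path: str | Path) -> FittedModel:
    """Load a model artifact; load(save(m)) predicts identically to m."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except OSError as exc:
        raise ModelIOError(f"cannot read model from {path}: {exc}") from exc
    except (pickle.UnpicklingError, EOFError, AttributeError, ImportError, IndexError) as exc:
        raise ModelIOError(f"corrupt or incompatible model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelIOError(f"{path}: not a model artifact")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelIOError(f"{path}: model format version {version} != supported {MODEL_FORMAT_VERSION}")
    spec = ClassifierSpec(**payload["spec"])
    return FittedModel(
        spec=spec,
        normalizer=FeatureNormalizer.from_dict(payload["normalizer"]),
        estimator=payload["estimator"],
        metadata=payload.get("metadata", {}),
    )
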