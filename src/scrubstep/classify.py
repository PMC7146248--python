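"""Multiclass gradient-boosted step classifier and prediction streams.

A boosted tree ensemble (softmax-probability objective) maps selected
window features to one of the performable step classes.  ``NONE``-labeled
windows are excluded from training; the classifier predicts performable
steps only.  Training is deterministic given the seed in single-thread
mode.
"""

from __future__ import annotations

import dataclasses
import json
import tempfile
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np
import xgboost as xgb

from .features import FeatureMatrix
from .labels import StepLabel

DEFAULT_CLASSIFIER_PARAMS = {
    "num_boost_round": 200,
    "max_depth": 6,
    "learning_rate": 0.1,
}


@dataclasses.dataclass
class ClassifierModel:
    """A trained ensemble plus the metadata needed to apply it safely."""

    booster: xgb.Booster
    classes: np.ndarray          # sorted StepLabel indices the model predicts
    feature_names: List[str]     # training column order
    params: dict
    seed: int


@dataclasses.dataclass
class PredictionStream:
    """Time-ordered per-window class-probability vectors."""

    window_times: np.ndarray
    probs: np.ndarray            # (windows, classes), rows sum to 1
    classes: np.ndarray          # StepLabel indices for the prob columns

    @property
    def argmax_labels(self) -> np.ndarray:
        """Per-window argmax label (ties resolve to the smallest class
        index because classes are sorted ascending)."""
        return self.classes[np.argmax(self.probs, axis=1)]


def train_classifier(
    train: FeatureMatrix,
    params: Optional[dict] = None,
    seed: int = 0,
    exclude_none: bool = True,
) -> ClassifierModel:
    """Fit the boosted ensemble on training windows.

    Default hyperparameters: 200 trees, depth 6, learning rate 0.1,
    softmax-probability objective, single-thread histogram trees.
    """
    merged = dict(DEFAULT_CLASSIFIER_PARAMS)
    if params:
        merged.update(params)

    y = np.asarray(train.window_labels)
    X = train.values
    if exclude_none:
        keep = y != int(StepLabel.NONE)
        X, y = X[keep], y[keep]
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    rare = classes[counts < 2]
    if rare.size:
        warnings.warn(
            "classes with fewer than 2 training windows: "
            + ", ".join(StepLabel(int(c)).name for c in rare)
        )

    ymap = np.searchsorted(classes, y)
    fnames = [f"f{i}" for i in range(X.shape[1])]
    dtrain = xgb.DMatrix(X, label=ymap, feature_names=fnames)
    fit_params = dict(merged)
    num_round = int(fit_params.pop("num_boost_round"))
    fit_params["eta"] = fit_params.pop("learning_rate", 0.1)
    xgb_params = {
        "objective": "multi:softprob",
        "num_class": int(classes.size),
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
        "verbosity": 0,
        **fit_params,
    }
    booster = xgb.train(xgb_params, dtrain, num_boost_round=num_round)
    return ClassifierModel(
        booster=booster,
        classes=classes,
        feature_names=list(train.feature_names),
        params=merged,
        seed=seed,
    )


def predict_stream(
    model: ClassifierModel,
    features: FeatureMatrix,
    window_times: Optional[np.ndarray] = None,
) -> PredictionStream:
    """Emit the prediction stream for a session's windows.

    Columns are aligned to the model's training features by name, so a
    permuted (but identically named) feature matrix yields identical output.
    """
    if window_times is None:
        window_times = features.window_times
    incoming = features.feature_names
    if incoming != model.feature_names:
        missing = [n for n in model.feature_names if n not in incoming]
        extra = [n for n in incoming if n not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature columns do not match the model: "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        pos = {n: i for i, n in enumerate(incoming)}
        X = features.values[:, [pos[n] for n in model.feature_names]]
    else:
        X = features.values
    fnames = [f"f{i}" for i in range(X.shape[1])]
    probs = model.booster.predict(xgb.DMatrix(X, feature_names=fnames))
    probs = np.atleast_2d(probs)
    return PredictionStream(
        window_times=np.asarray(window_times, dtype=float),
        probs=probs,
        classes=model.classes.copy(),
    )


def save_model(model: ClassifierModel, path) -> Path:
    """Serialize a model to a self-describing JSON file."""
    path = Path(path)
    with tempfile.NamedTemporaryFile(suffix=".json", delete=False) as tmp:
        tmp_path = Path(tmp.name)
    model.booster.save_model(tmp_path)
    payload = {
        "format": "scrubstep-classifier-v1",
        "classes": [int(c) for c in model.classes],
        "feature_names": model.feature_names,
        "params": model.params,
        "seed": model.seed,
        "booster": json.loads(tmp_path.read_text()),
    }
    tmp_path.unlink()
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "scrubstep-classifier-v1":
        raise ValueError(f"{path}: not a scrubstep classifier file")
    with tempfile.NamedTemporaryFile(suffix=".json", mode="w", delete=False) as tmp:
        json.dump(payload["booster"], tmp)
        tmp_path = Path(tmp.name)
    booster = xgb.Booster()
    booster.load_model(tmp_path)
    tmp_path.unlink()
    return ClassifierModel(
        booster=booster,
        classes=np.array(payload["classes"], dtype=np.int64),
        feature_names=list(payload["feature_names"]),
        params=dict(payload["params"]),
        seed=int(payload["seed"]),
    )
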