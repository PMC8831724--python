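"""Stage classification and wake-substage assignment.

A random forest over the twelve handcrafted epoch features predicts
wake/NREM/REM per 8-s epoch; its headline number is stratified 10-fold
cross-validated accuracy.  Wake epochs are then split into active and quiet
substages by within-epoch movement duration: more than 1 s of
supra-threshold motion makes the epoch ACTIVE.  A transparent rule-based
scorer (motion high -> wake; delta-dominant -> NREM; theta-dominant -> REM)
serves as a baseline and as a sanity oracle on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .core import ACTIVE, NA, NREM, QUIET, REM, STAGES, WAKE, EpochGrid, Hypnogram, Recording, epoch_view
from .features import FEATURE_COLUMNS

__all__ = [
    "StageModel",
    "MovementParams",
    "train_classifier",
    "cross_validate",
    "predict_stages",
    "heuristic_stage",
    "movement_duration",
    "movement_threshold_from_baseline",
    "split_wake_substages",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class StageModel:
    """A trained stage classifier plus the metadata needed to apply it safely."""

    forest: RandomForestClassifier
    feature_order: tuple[str, ...]
    class_labels: tuple[str, ...]
    n_trees: int
    train_seed: int


@dataclass
class MovementParams:
    """Movement-duration detection parameters.

    The motion magnitude is high-passed by subtracting the epoch median
    (removes the gravity offset), rectified, smoothed with a
    ``smoothing_window_s`` moving average, and thresholded at
    ``movement_threshold`` (G above baseline).  ``min_active_duration_s``
    is the active-wake rule: more than 1 s of movement within the 8-s
    epoch marks it ACTIVE.
    """

    movement_threshold: float = 0.1
    min_active_duration_s: float = 1.0
    smoothing_window_s: float = 0.25


def _feature_matrix(features: pd.DataFrame, order: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in order if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    return features.loc[:, list(order)].to_numpy()


def train_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> StageModel:
    """Fit the random forest (100 trees, sqrt-feature splits, unlimited depth)."""
    labels = np.asarray(labels, dtype="<U6")
    if len(labels) != len(features):
        raise ValueError("one label per feature row required")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training needs at least two classes")
    order = tuple(c for c in FEATURE_COLUMNS if c in features.columns)
    if len(order) == 0:
        raise ValueError("feature table has no recognized feature columns")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed) % 2**31,
        n_jobs=1,
    )
    forest.fit(_feature_matrix(features, order), labels)
    return StageModel(
        forest=forest,
        feature_order=order,
        class_labels=tuple(forest.classes_),
        n_trees=n_trees,
        train_seed=int(seed),
    )


def predict_stages(model: StageModel, features: pd.DataFrame) -> np.ndarray:
    """Predict one stage per epoch.

    Prediction is the majority vote across trees; exact ties are broken by
    the fixed stage order WAKE < NREM < REM, not by sklearn's alphabetical
    class order, so results are deterministic and documented.
    """
    if len(features) == 0:
        return np.array([], dtype="<U6")
    proba = model.forest.predict_proba(_feature_matrix(features, model.feature_order))
    order = [s for s in STAGES if s in model.class_labels]
    cols = [list(model.class_labels).index(s) for s in order]
    best = np.argmax(proba[:, cols], axis=1)  # argmax takes the first of tied maxima
    return np.asarray(order, dtype="<U6")[best]


def cross_validate(
    features: pd.DataFrame,
    labels: np.ndarray,
    k: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> float:
    """Mean accuracy over k stratified folds (epoch-level splits).

    Folds are stratified by stage where class counts allow; for k larger
    than the smallest class (e.g. leave-one-out) plain shuffled k-fold is
    used instead.  Returns the mean over folds of the fraction of correctly
    predicted epochs.
    """
    labels = np.asarray(labels, dtype="<U6")
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    _, counts = np.unique(labels, return_counts=True)
    seed = int(seed) % 2**31
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        model = train_classifier(
            features.iloc[train_idx], labels[train_idx], n_trees=n_trees,
            seed=seed + fold,
        )
        pred = predict_stages(model, features.iloc[test_idx])
        accs.append(float(np.mean(pred == labels[test_idx])))
    return float(np.mean(accs))


def heuristic_stage(
    row: pd.Series | dict,
    motion_threshold: float = 0.05,
    dominance_ratio: float = 1.5,
) -> str:
    """Rule-based stage for one epoch's features.

    High motion SD -> WAKE (frequent body movements).  Otherwise the
    delta/theta mean-amplitude ratio decides: delta dominance -> NREM
    (high-amplitude slow waves), theta dominance -> REM (regular theta with
    low motion), neither -> WAKE (mixed-frequency quiet wakefulness).
    """
    if row["motion_sd"] > motion_threshold:
        return WAKE
    delta, theta = row["delta_mean_amp"], row["theta_mean_amp"]
    if delta > dominance_ratio * theta:
        return NREM
    if theta > dominance_ratio * delta:
        return REM
    return WAKE


def movement_threshold_from_baseline(
    motion: np.ndarray,
    grid: EpochGrid,
    motion_rate_hz: float,
    k: float = 3.0,
    smoothing_window_s: float = 0.25,
) -> float:
    """Recording-level movement threshold: k x the quiet-baseline SD.

    The baseline SD is the median across epochs of the SD of the smoothed,
    median-subtracted magnitude — robust because most epochs (sleep, quiet
    wake) contain no movement bursts.
    """
    epochs = epoch_view(motion, grid, rate_hz=motion_rate_hz)
    sds = []
    for ep in epochs:
        sds.append(np.std(_smoothed_excursion(ep, motion_rate_hz, smoothing_window_s)))
    return float(k * np.median(sds))


def _smoothed_excursion(epoch_motion: np.ndarray, rate_hz: float,
                        smoothing_window_s: float) -> np.ndarray:
    x = np.abs(np.asarray(epoch_motion, dtype=float) - np.median(epoch_motion))
    w = int(round(smoothing_window_s * rate_hz))
    if w > 1:
        x = np.convolve(x, np.ones(w) / w, mode="same")
    return x


def movement_duration(
    epoch_motion: np.ndarray,
    params: MovementParams,
    rate_hz: float = 128.0,
) -> float:
    """Seconds of supra-threshold movement within one epoch."""
    x = _smoothed_excursion(epoch_motion, rate_hz, params.smoothing_window_s)
    return float(np.count_nonzero(x > params.movement_threshold) / rate_hz)


def split_wake_substages(
    stages: np.ndarray,
    motion_epochs: np.ndarray,
    params: MovementParams,
    rate_hz: float = 128.0,
) -> Hypnogram:
    """Assign ACTIVE/QUIET to wake epochs by the 1-s movement rule.

    ``motion_epochs`` is the (n_epochs, samples) motion magnitude view.
    WAKE epochs with movement_duration > min_active_duration_s become
    ACTIVE, other WAKE epochs QUIET; non-wake epochs get NA regardless of
    motion (movement during scored sleep is left to the stage label).
    """
    stages = np.asarray(stages, dtype="<U6")
    if len(stages) != len(motion_epochs):
        raise ValueError("stages and motion epochs must be aligned")
    substages = np.full(stages.shape, NA, dtype="<U6")
    for i, stage in enumerate(stages):
        if stage == WAKE:
            dur = movement_duration(motion_epochs[i], params, rate_hz=rate_hz)
            substages[i] = ACTIVE if dur > params.min_active_duration_s else QUIET
    return Hypnogram(stages=stages, substages=substages)


def save_model(model: StageModel, path) -> None:
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "forest": model.forest,
            "feature_order": model.feature_order,
            "class_labels": model.class_labels,
            "n_trees": model.n_trees,
            "train_seed": model.train_seed,
        },
        path,
    )


def load_model(path) -> StageModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return StageModel(
        forest=payload["forest"],
        feature_order=tuple(payload["feature_order"]),
        class_labels=tuple(payload["class_labels"]),
        n_trees=payload["n_trees"],
        train_seed=payload["train_seed"],
    )
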