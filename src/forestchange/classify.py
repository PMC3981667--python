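"""RBF-kernel SVM classification of the six-plane tasseled-cap stack.

Hyperparameters (C, γ) are found by exhaustive search over a log2 grid
(C exponents −5..15 step 2, γ exponents −15..3 step 2) scored by stratified
cross-validated accuracy; ties break toward the smaller C then the smaller
γ, so the search is deterministic.  Features are standardized with
statistics from the training set (stored with the model) because the
tasseled-cap planes have unequal ranges and RBF kernels are scale
sensitive.  Multi-class handling is libsvm's one-vs-one composition.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .features import FeatureStack
from .masking import MaskSet
from .training import TrainingSet

logger = logging.getLogger(__name__)

#: sentinel written to masked pixels of a predicted label plane
PREDICT_SENTINEL = -1


@dataclass(frozen=True)
class SVMParams:
    C: float
    gamma: float
    cv_accuracy: float


@dataclass
class TrainedModel:
    svc: SVC
    scaler: StandardScaler
    params: SVMParams
    classes: np.ndarray
    n_training_samples: int
    seed: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        if features.ndim != 2 or features.shape[1] != self.scaler.mean_.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model expects "
                f"{self.scaler.mean_.shape[0]}, got {features.shape}"
            )
        return self.svc.predict(self.scaler.transform(features))

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, TrainedModel):
            raise TypeError("file does not contain a TrainedModel")
        return model


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, n_folds: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        svc = SVC(kernel="rbf", C=C, gamma=gamma)
        svc.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = svc.predict(scaler.transform(X[test_idx]))
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)


def grid_search(ts: TrainingSet, cfg: PipelineConfig) -> SVMParams:
    """Best (C, γ) on the configured log2 grid by stratified CV accuracy."""
    y = ts.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search requires at least two classes")
    X = ts.features
    rng = np.random.default_rng(cfg.rng_seed + 2)
    if len(y) > cfg.grid_search_max_samples:
        idx = _stratified_cap(y, cfg.grid_search_max_samples, rng)
        X, y = X[idx], y[idx]
    n_folds = min(cfg.grid_cv_folds, int(np.bincount(y).clip(min=1).min()), len(y))
    n_folds = max(n_folds, 2)
    best: SVMParams | None = None
    for C in cfg.c_grid():
        for gamma in cfg.gamma_grid():
            acc = _cv_accuracy(X, y, C, gamma, n_folds, cfg.rng_seed)
            # strict improvement only: grid order gives smaller C, then γ, on ties
            if best is None or acc > best.cv_accuracy:
                best = SVMParams(C=C, gamma=gamma, cv_accuracy=acc)
    assert best is not None
    logger.info(
        "grid search selected C=2^%g, gamma=2^%g (CV accuracy %.3f)",
        np.log2(best.C), np.log2(best.gamma), best.cv_accuracy,
    )
    return best


def _stratified_cap(y: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """At most ``cap`` samples overall, preserving class proportions."""
    out = []
    n = len(y)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        take = max(1, int(round(cap * len(idx) / n)))
        out.append(rng.choice(idx, size=min(take, len(idx)), replace=False))
    return np.sort(np.concatenate(out))


def train(ts: TrainingSet, params: SVMParams, cfg: PipelineConfig) -> TrainedModel:
    if len(ts) == 0:
        raise ValueError("cannot train on an empty training set")
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    scaler = StandardScaler().fit(ts.features)
    svc = SVC(kernel="rbf", C=params.C, gamma=params.gamma)
    svc.fit(scaler.transform(ts.features), ts.labels)
    return TrainedModel(
        svc=svc,
        scaler=scaler,
        params=params,
        classes=classes,
        n_training_samples=len(ts),
        seed=cfg.rng_seed,
    )


def predict_map(
    model: TrainedModel, stack: FeatureStack, masks: MaskSet, chunk: int = 100_000
) -> np.ndarray:
    """Per-pixel labels over the valid region; masked pixels get the sentinel."""
    h, w = stack.shape
    out = np.full((h, w), PREDICT_SENTINEL, dtype=np.int64)
    rows, cols = np.nonzero(masks.valid)
    for start in range(0, len(rows), chunk):
        r = rows[start : start + chunk]
        c = cols[start : start + chunk]
        out[r, c] = model.predict(stack.vectors(r, c))
    return out
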