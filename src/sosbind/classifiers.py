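"""Probabilistic-classifier contract used by the SOS filter and the
prediction pipeline.

Two implementations satisfy the contract:

* ``gaussian_svm`` -- an RBF-kernel SVM whose regularization parameter C and
  kernel width gamma are selected by stratified k-fold grid search maximizing
  mean fold MCC, then refit on all data.  Confidence is the Platt-style
  probability estimate of the engine.
* ``mock`` -- wraps a user-supplied confidence function; the required test
  double that makes the SOS acceptance loop fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import joblib
import numpy as np
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from sosbind.errors import ValidationError
from sosbind.sampling import MINORITY, LabeledDataset

MODEL_FORMAT_VERSION = 1

# libsvm-style default grids (powers of 4)
DEFAULT_C_GRID = [float(2**p) for p in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [float(2**p) for p in range(-15, 4, 2)]


@dataclass
class ClassifierSpec:
    """Declarative description of the classifier to fit."""

    kind: str = "gaussian_svm"  # gaussian_svm | mock
    c_grid: list = field(default_factory=lambda: list(DEFAULT_C_GRID))
    gamma_grid: list = field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    cv_folds: int = 10
    seed: int = 0
    mock_fn: Optional[Callable[[np.ndarray], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_svm", "mock"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "gaussian_svm":
            if not self.c_grid or not self.gamma_grid:
                raise ValidationError("grids must be non-empty for gaussian_svm")
            if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
                raise ValidationError("grid values must be positive")
            if self.cv_folds < 2:
                raise ValidationError("cv_folds must be >= 2")
        if self.kind == "mock" and self.mock_fn is None:
            raise ValidationError("mock classifier requires mock_fn")


@dataclass
class Model:
    """Fitted classifier state plus training metadata.

    ``estimator`` is None for mock models.  ``confidence`` output is always a
    finite value in [0, 1].
    """

    kind: str
    dim: int
    estimator: Optional[SVC] = None
    mock_fn: Optional[Callable[[np.ndarray], float]] = None
    chosen_c: Optional[float] = None
    chosen_gamma: Optional[float] = None
    fold_scores: Optional[dict] = None
    positive_index: Optional[int] = None


def _mean_cv_mcc(
    features: np.ndarray,
    labels: np.ndarray,
    c: float,
    gamma: float,
    folds: int,
    seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(features, labels):
        clf = SVC(kernel="rbf", C=c, gamma=gamma, random_state=seed)
        clf.fit(features[train_idx], labels[train_idx])
        scores.append(matthews_corrcoef(labels[test_idx], clf.predict(features[test_idx])))
    return float(np.mean(scores))


def grid_search_fit(dataset: LabeledDataset, spec: ClassifierSpec) -> Model:
    """Fit a model per the spec; for gaussian_svm run the (C, gamma) grid
    search under stratified cross-validation (objective: mean fold MCC, ties
    to smaller C then smaller gamma) and refit the winner on all data.
    """
    if spec.kind == "mock":
        return Model(kind="mock", dim=dataset.d, mock_fn=spec.mock_fn)

    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("grid search requires both classes present")
    min_count = int(counts.min())
    folds = spec.cv_folds
    if min_count < folds:
        folds = max(2, min_count)
        import logging

        logging.getLogger(__name__).warning(
            "reducing cv folds from %d to %d (smallest class has %d members)",
            spec.cv_folds, folds, min_count,
        )

    best = None
    fold_scores = {}
    for c in sorted(spec.c_grid):
        for gamma in sorted(spec.gamma_grid):
            score = _mean_cv_mcc(dataset.features, labels, c, gamma, folds, spec.seed)
            fold_scores[(c, gamma)] = score
            # strict > keeps the smallest (C, gamma) on ties
            if best is None or score > best[0]:
                best = (score, c, gamma)

    _, c, gamma = best
    import warnings as _warnings

    with _warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True; it remains the engine's
        # native Platt-style estimate on this pinned version
        _warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(kernel="rbf", C=c, gamma=gamma, probability=True, random_state=spec.seed)
        clf.fit(dataset.features, labels)
    pos_index = int(np.where(clf.classes_ == MINORITY)[0][0])
    return Model(
        kind="gaussian_svm",
        dim=dataset.d,
        estimator=clf,
        chosen_c=c,
        chosen_gamma=gamma,
        fold_scores=fold_scores,
        positive_index=pos_index,
    )


def confidence(model: Model, x: np.ndarray) -> float:
    """Minority-membership confidence of a single sample, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValidationError(f"expected a {model.dim}-vector, got shape {x.shape}")
    if model.kind == "mock":
        return float(np.clip(model.mock_fn(x), 0.0, 1.0))
    proba = model.estimator.predict_proba(x[None, :])[0, model.positive_index]
    return float(np.clip(proba, 0.0, 1.0))


def confidence_batch(model: Model, features: np.ndarray) -> np.ndarray:
    """Vectorized ``confidence`` over the rows of a matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.dim:
        raise ValidationError(
            f"expected an n x {model.dim} matrix, got shape {features.shape}"
        )
    if model.kind == "mock":
        return np.clip([float(model.mock_fn(row)) for row in features], 0.0, 1.0)
    proba = model.estimator.predict_proba(features)[:, model.positive_index]
    return np.clip(proba, 0.0, 1.0)


def save_model(model: Model, path) -> None:
    """Persist a fitted model (single portable file, versioned)."""
    if model.kind == "mock":
        raise ValidationError("mock models are not persistable")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "dim": model.dim,
        "chosen_c": model.chosen_c,
        "chosen_gamma": model.chosen_gamma,
        "positive_index": model.positive_index,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path) -> Model:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version {version}")
    return Model(
        kind=payload["kind"],
        dim=payload["dim"],
        estimator=payload["estimator"],
        chosen_c=payload["chosen_c"],
        chosen_gamma=payload["chosen_gamma"],
        positive_index=payload["positive_index"],
    )
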