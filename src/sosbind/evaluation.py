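"""Imbalance-aware evaluation: threshold-dependent metrics, threshold
selection policies, ROC/AUC, and a leakage-safe cross-validation harness.

Conventions
-----------
* Prediction rule: a sample is called positive iff ``score >= t``.
* Any metric whose denominator vanishes is defined as 0, which keeps the
  threshold scans total.
* ``max_mcc`` policy reports metrics at the candidate threshold maximizing
  MCC (ties: greater specificity, then smaller t); ``balanced`` minimizes
  |Sen - Spe| (ties: greater MCC, then smaller t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from sosbind.errors import ValidationError
from sosbind.sampling import MINORITY, LabeledDataset, apply_sampler


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ScoredPredictions:
    """Per-sample minority-confidence scores with true labels."""

    scores: np.ndarray
    labels: np.ndarray
    group_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValidationError("scores and labels must have equal length")
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise ValidationError(f"labels must be in {{+1, -1}}; found {sorted(bad)}")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if self.group_ids.shape != self.labels.shape:
                raise ValidationError("group_ids length mismatch")


@dataclass
class ThresholdPolicy:
    mode: str = "max_mcc"  # max_mcc | balanced | fixed
    fixed_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("max_mcc", "balanced", "fixed"):
            raise ValidationError(f"unknown policy {self.mode!r}")
        if (self.mode == "fixed") != (self.fixed_value is not None):
            raise ValidationError("fixed_value present iff mode='fixed'")


def confusion(preds: ScoredPredictions, t: float) -> ConfusionCounts:
    """Confusion counts under the rule score >= t => predicted positive."""
    called = preds.scores >= t
    pos = preds.labels == 1
    return ConfusionCounts(
        tp=int(np.sum(called & pos)),
        fp=int(np.sum(called & ~pos)),
        tn=int(np.sum(~called & ~pos)),
        fn=int(np.sum(~called & pos)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sen, Spe, Acc, MCC); 0/0 denominators map to 0."""
    if c.n < 1:
        raise ValidationError("empty confusion counts")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / c.n
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return sen, spe, acc, mcc


def roc_auc(preds: ScoredPredictions) -> float:
    """Probability a random positive outscores a random negative, ties 1/2.

    Computed by the Mann-Whitney rank formulation; equals the trapezoidal
    area under the ROC curve.
    """
    pos = preds.labels == 1
    n_pos = int(pos.sum())
    n_neg = len(preds.labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(preds.scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus below/above sentinels."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def select_threshold(
    preds: ScoredPredictions, policy: ThresholdPolicy
) -> tuple[float, tuple[float, float, float, float]]:
    """Pick a threshold per policy; returns (t, (sen, spe, acc, mcc)) at t."""
    if not ((preds.labels == 1).any() and (preds.labels == -1).any()):
        raise ValidationError("threshold selection requires both classes present")
    if policy.mode == "fixed":
        t = float(policy.fixed_value)
        return t, metrics(confusion(preds, t))

    best_t = None
    best_metrics = None
    best_key = None
    for t in _candidate_thresholds(preds.scores):
        sen, spe, acc, mcc = metrics(confusion(preds, t))
        if policy.mode == "max_mcc":
            key = (mcc, spe, -t)  # maximize mcc, then spe, then smaller t
        else:
            key = (-abs(sen - spe), mcc, -t)
        if best_key is None or key > best_key:
            best_key = key
            best_t = float(t)
            best_metrics = (sen, spe, acc, mcc)
    return best_t, best_metrics


# ---------------------------------------------------------------------------
# dataset bookkeeping
# ---------------------------------------------------------------------------


def class_ratio(num_positive: int, num_negative: int) -> float:
    """Majority-to-minority imbalance ratio numN / numP."""
    if num_positive <= 0:
        raise ValidationError("positive count must be > 0")
    return num_negative / num_positive


def dataset_report(labels: np.ndarray) -> dict:
    """Counts and imbalance ratio of a labeled sample set."""
    labels = np.asarray(labels, dtype=int)
    num_p = int(np.sum(labels == 1))
    num_n = int(np.sum(labels == -1))
    ratio = class_ratio(num_p, num_n)
    return {
        "num_positive": num_p,
        "num_negative": num_n,
        "ratio": ratio,
        "ratio_rounded": round(ratio),
    }


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    threshold: float
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float
    n_test: int
    test_groups: list = field(default_factory=list)


@dataclass
class CVReport:
    folds: list
    pooled: dict
    seed: int

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "folds": [vars(f) for f in self.folds],
            "pooled": self.pooled,
        }


def _group_folds(groups: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Partition samples into k folds at group (protein) granularity."""
    unique = np.unique(groups)
    if len(unique) < k:
        raise ValidationError(f"{len(unique)} groups < {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    assignments = {g: i % k for i, g in enumerate(shuffled)}
    fold_of = np.array([assignments[g] for g in groups])
    return [np.flatnonzero(fold_of == i) for i in range(k)]


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    if len(labels) < k:
        raise ValidationError(f"{len(labels)} samples < {k} folds")
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((len(labels), 1)), labels)]


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    groups: Optional[np.ndarray] = None,
    *,
    sampler: str = "none",
    sampler_params: Optional[dict] = None,
    classifier_spec=None,
    policy: Optional[ThresholdPolicy] = None,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """k-fold cross-validation with over-sampling on the training folds only.

    Folds are group-level (all residues of a protein stay together) when
    ``groups`` is given, else stratified sample-level.  Each fold's test
    scores are produced by a classifier fit on the (optionally over-sampled)
    training portion; metrics are reported at the policy-selected threshold
    per fold and for the pooled scores.
    """
    from sosbind.classifiers import ClassifierSpec, confidence_batch, grid_search_fit

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if classifier_spec is None:
        classifier_spec = ClassifierSpec()
    if policy is None:
        policy = ThresholdPolicy(mode="max_mcc")

    if groups is not None:
        groups = np.asarray(groups)
        folds = _group_folds(groups, k, seed)
    else:
        folds = _stratified_folds(labels, k, seed)

    all_idx = np.arange(len(labels))
    fold_results = []
    pooled_scores = np.empty(len(labels))
    pooled_mask = np.zeros(len(labels), dtype=bool)

    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        train = LabeledDataset(features[train_idx], labels[train_idx])
        augmented, _ = apply_sampler(
            train, sampler, sampler_params, classifier_spec=classifier_spec,
            seed=seed + fold_id,
        )
        model = grid_search_fit(augmented, classifier_spec)
        scores = confidence_batch(model, features[test_idx])
        pooled_scores[test_idx] = scores
        pooled_mask[test_idx] = True

        preds = ScoredPredictions(scores=scores, labels=labels[test_idx])
        t, (sen, spe, acc, mcc) = select_threshold(preds, policy)
        fold_results.append(
            FoldResult(
                fold=fold_id, threshold=t, sen=sen, spe=spe, acc=acc, mcc=mcc,
                auc=roc_auc(preds), n_test=len(test_idx),
                test_groups=sorted(set(groups[test_idx].tolist())) if groups is not None else [],
            )
        )

    assert pooled_mask.all(), "every sample must be scored exactly once"
    pooled_preds = ScoredPredictions(scores=pooled_scores, labels=labels)
    t, (sen, spe, acc, mcc) = select_threshold(pooled_preds, policy)
    pooled = {
        "threshold": t,
        "sen": sen,
        "spe": spe,
        "acc": acc,
        "mcc": mcc,
        "auc": roc_auc(pooled_preds),
        "n": len(labels),
    }
    return CVReport(folds=fold_results, pooled=pooled, seed=seed)


def roc_points(preds: ScoredPredictions) -> np.ndarray:
    """ROC curve points as an (m, 2) array of (FPR, TPR), for plotting."""
    out = []
    for t in _candidate_thresholds(preds.scores)[::-1]:
        c = confusion(preds, t)
        fpr = c.fp / (c.fp + c.tn) if c.fp + c.tn else 0.0
        tpr = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        out.append((fpr, tpr))
    return np.array(out)
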