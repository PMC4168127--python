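"""Over-sampling algorithms for two-class imbalanced data.

Implements four minority over-samplers over a shared ``LabeledDataset``
representation (+1 = minority/positive, -1 = majority/negative):

* ``random_oversample`` -- exact replication of randomly chosen minority rows;
* ``smote`` -- interpolation toward minority k-nearest neighbors, with a
  round-robin base allocation so per-sample synthesis counts differ by at
  most one;
* ``adasyn`` -- neighborhood-density-weighted synthesis counts
  (``adasyn_plan``) followed by SMOTE-style interpolation;
* ``sos`` -- supervised over-sampling: pair interpolation between random
  minority samples, filtered by an initial classifier's minority-confidence
  so only samples whose confidence lies in ``[c_low, c_high]`` are kept.

RNG contract: every sampler builds one ``numpy.random.Generator`` from its
seed and draws in a documented order (base/pair indices first, then neighbor
choice, then lambda), so tests can replay the stream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.spatial.distance import cdist

from sosbind.errors import AttemptsExhaustedError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from sosbind.classifiers import ClassifierSpec, Model

MINORITY = 1
MAJORITY = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """n x d feature matrix with labels in {+1 minority, -1 majority}."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValidationError("dataset needs at least one row and one column")
        if self.labels.shape != (n,):
            raise ValidationError(
                f"labels length {self.labels.shape} does not match {n} rows"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain non-finite values")
        bad = set(np.unique(self.labels)) - {MINORITY, MAJORITY}
        if bad:
            raise ValidationError(f"labels must be in {{+1, -1}}; found {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class SOSConfig:
    """Parameters of the supervised over-sampler.

    alpha is the over-sampling coefficient: minority size after over-sampling
    divided by the original minority size.  ``max_attempts=None`` expands to
    ``200 * n_target`` at run time.
    """

    alpha: float
    c_low: float = 0.5
    c_high: float = 0.95
    max_attempts: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValidationError(f"alpha must be >= 1, got {self.alpha}")
        if not (0 <= self.c_low < self.c_high <= 1):
            raise ValidationError(
                f"need 0 <= c_low < c_high <= 1, got [{self.c_low}, {self.c_high}]"
            )
        if self.max_attempts is not None and self.max_attempts < 1:
            raise ValidationError("max_attempts must be positive")


@dataclass
class SmoteConfig:
    k: int = 5
    n_synth: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be a positive integer")
        if self.n_synth < 0:
            raise ValidationError("n_synth must be non-negative")


@dataclass
class AdasynPlan:
    """Per-minority-sample synthesis allocation.

    ``weights`` is the normalized neighborhood-density distribution; ``counts``
    allocates ``total_g`` samples by largest remainder so the counts sum
    exactly to ``total_g``.
    """

    total_g: int
    weights: np.ndarray
    counts: np.ndarray
    z: float


@dataclass
class SyntheticBatch:
    """m synthesized vectors with their interpolation provenance.

    Every vector satisfies ``v = parent_a + lam * (parent_b - parent_a)``
    where parents index into the minority matrix.  ``confidences`` is present
    only for SOS batches.
    """

    vectors: np.ndarray
    parent_indices: np.ndarray  # m x 2 ints
    lambdas: np.ndarray
    confidences: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.parent_indices = np.asarray(self.parent_indices, dtype=int)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.confidences is not None:
            self.confidences = np.asarray(self.confidences, dtype=float)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def empty(cls, d: int) -> "SyntheticBatch":
        return cls(
            vectors=np.empty((0, d)),
            parent_indices=np.empty((0, 2), dtype=int),
            lambdas=np.empty(0),
        )


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def split_by_class(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Partition rows into (minority, majority) matrices, order preserved."""
    minority = dataset.features[dataset.labels == MINORITY]
    majority = dataset.features[dataset.labels == MAJORITY]
    if minority.shape[0] == 0:
        raise ValidationError("minority class empty")
    if majority.shape[0] == 0:
        raise ValidationError("majority class empty")
    return minority, majority


def interpolate(a: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Return ``a + lam * (b - a)`` for ``lam`` in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if not (0.0 <= lam <= 1.0):
        raise ValidationError(f"lambda must lie in [0, 1], got {lam}")
    return a + lam * (b - a)


def random_oversample(minority: np.ndarray, n_extra: int, seed: int = 0) -> SyntheticBatch:
    """Replicate ``n_extra`` uniformly chosen minority rows (exact copies)."""
    minority = np.asarray(minority, dtype=float)
    if minority.shape[0] == 0:
        raise ValidationError("minority class empty")
    if n_extra < 0:
        raise ValidationError("n_extra must be non-negative")
    d = minority.shape[1]
    if n_extra == 0:
        return SyntheticBatch.empty(d)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, minority.shape[0], size=n_extra)
    return SyntheticBatch(
        vectors=minority[idx].copy(),
        parent_indices=np.column_stack([idx, idx]),
        lambdas=np.zeros(n_extra),
    )


def knn_minority(minority: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest rows to row ``i`` (Euclidean), excluding ``i``.

    Ties break toward the lower index (stable sort on distance).
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if not (1 <= k <= n - 1):
        raise ValidationError(f"k={k} out of range for {n} minority rows")
    dists = np.linalg.norm(minority - minority[i], axis=1)
    dists[i] = np.inf
    order = np.argsort(dists, kind="stable")
    return order[:k]


def _knn_table(minority: np.ndarray, k: int) -> np.ndarray:
    """All-rows k-NN table (n x k) with the same tie rule as knn_minority."""
    d = cdist(minority, minority)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def smote(minority: np.ndarray, cfg: SmoteConfig) -> SyntheticBatch:
    """SMOTE: interpolate each base row toward a random one of its k-NN.

    Base rows are cycled round-robin in input order, so per-row synthesis
    counts differ by at most one; the remainder goes to the earliest rows.
    Draw order per sample: neighbor choice, then lambda.
    """
    minority = np.asarray(minority, dtype=float)
    n, d = minority.shape
    if n < 2:
        raise ValidationError("SMOTE needs at least 2 minority samples")
    if cfg.k > n - 1:
        raise ValidationError(f"k={cfg.k} exceeds |minority|-1={n - 1}")
    if cfg.n_synth == 0:
        return SyntheticBatch.empty(d)
    rng = np.random.default_rng(cfg.seed)
    neighbors = _knn_table(minority, cfg.k)
    vectors = np.empty((cfg.n_synth, d))
    parents = np.empty((cfg.n_synth, 2), dtype=int)
    lambdas = np.empty(cfg.n_synth)
    for m in range(cfg.n_synth):
        i = m % n
        j = neighbors[i, rng.integers(cfg.k)]
        lam = rng.random()
        vectors[m] = minority[i] + lam * (minority[j] - minority[i])
        parents[m] = (i, j)
        lambdas[m] = lam
    return SyntheticBatch(vectors=vectors, parent_indices=parents, lambdas=lambdas)


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` by largest remainder, ties to lower index."""
    raw = weights * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = raw - counts
        # stable sort descending on remainder -> ties resolved to lower index
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def adasyn_plan(
    minority: np.ndarray, majority: np.ndarray, beta: float = 1.0, k: int = 5
) -> AdasynPlan:
    """Density-weighted synthesis allocation.

    G = round(beta * (|majority| - |minority|)).  Each minority row's weight
    is the fraction of majority samples among its k nearest neighbors in the
    WHOLE training set, normalized to a distribution.  If every neighborhood
    is majority-free the weights fall back to uniform.
    """
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    n_min, n_maj = minority.shape[0], majority.shape[0]
    if n_min == 0 or n_maj == 0:
        raise ValidationError("both classes must be non-empty")
    if not (0 < beta <= 1):
        raise ValidationError(f"beta must lie in (0, 1], got {beta}")
    if not (1 <= k <= n_min + n_maj - 1):
        raise ValidationError(f"k={k} out of range for {n_min + n_maj} samples")

    if n_maj <= n_min:
        warnings.warn("majority not larger than minority: nothing to balance (G=0)")
        return AdasynPlan(
            total_g=0,
            weights=np.full(n_min, 1.0 / n_min),
            counts=np.zeros(n_min, dtype=int),
            z=float(n_min),
        )

    g_total = int(round(beta * (n_maj - n_min)))
    pool = np.vstack([minority, majority])  # minority rows come first
    dists = cdist(minority, pool)
    for i in range(n_min):
        dists[i, i] = np.inf  # exclude self
    nn = np.argsort(dists, axis=1, kind="stable")[:, :k]
    delta = (nn >= n_min).sum(axis=1)  # majority neighbors

    z = float(delta.sum()) / k
    if z == 0.0:
        weights = np.full(n_min, 1.0 / n_min)
        z = float(n_min)  # degenerate fallback: uniform distribution
    else:
        weights = (delta / k) / z
    counts = _largest_remainder(weights, g_total)
    return AdasynPlan(total_g=g_total, weights=weights, counts=counts, z=z)


def adasyn(
    minority: np.ndarray,
    majority: np.ndarray,
    beta: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> SyntheticBatch:
    """ADASYN synthesis: per-row counts from ``adasyn_plan``, interpolation
    toward minority-only k-NN.  Draw order per sample: neighbor, then lambda.
    """
    minority = np.asarray(minority, dtype=float)
    plan = adasyn_plan(minority, majority, beta=beta, k=k)
    n, d = minority.shape
    if plan.total_g == 0:
        return SyntheticBatch.empty(d)
    if n < 2:
        raise ValidationError("ADASYN synthesis needs at least 2 minority samples")
    k_syn = min(k, n - 1)
    rng = np.random.default_rng(seed)
    neighbors = _knn_table(minority, k_syn)
    vectors = np.empty((plan.total_g, d))
    parents = np.empty((plan.total_g, 2), dtype=int)
    lambdas = np.empty(plan.total_g)
    m = 0
    for i in range(n):
        for _ in range(plan.counts[i]):
            j = neighbors[i, rng.integers(k_syn)]
            lam = rng.random()
            vectors[m] = minority[i] + lam * (minority[j] - minority[i])
            parents[m] = (i, j)
            lambdas[m] = lam
            m += 1
    return SyntheticBatch(vectors=vectors, parent_indices=parents, lambdas=lambdas)


# ---------------------------------------------------------------------------
# supervised over-sampling
# ---------------------------------------------------------------------------


def sos_target_count(alpha: float, n_minority: int) -> int:
    """Number of samples to synthesize: ceil((alpha - 1) * |P|)."""
    return math.ceil((alpha - 1.0) * n_minority)


def sos(
    dataset: LabeledDataset,
    clf: "ClassifierSpec",
    cfg: SOSConfig,
) -> tuple[LabeledDataset, SyntheticBatch, "Model"]:
    """Supervised over-sampling.

    Trains an initial model on the original dataset, then repeatedly draws two
    distinct minority samples, interpolates with lambda ~ U[0,1], and accepts
    the synthetic sample iff the model's minority-confidence lies in
    ``[c_low, c_high]``; stops after ``ceil((alpha-1)*|P|)`` acceptances.

    Draw order per attempt: first parent index, second parent index (from the
    remaining n-1), then lambda.

    Returns the augmented dataset (original rows first, accepted rows appended
    with label +1), the accepted batch with its confidences, and the initial
    model.
    """
    from sosbind.classifiers import confidence, grid_search_fit

    minority, _ = split_by_class(dataset)
    n_min = minority.shape[0]
    n_target = sos_target_count(cfg.alpha, n_min)

    model = grid_search_fit(dataset, clf)
    if n_target == 0:
        return dataset, SyntheticBatch.empty(dataset.d), model
    if n_min < 2:
        raise ValidationError("SOS needs at least 2 minority samples")

    max_attempts = cfg.max_attempts if cfg.max_attempts is not None else 200 * n_target
    rng = np.random.default_rng(cfg.seed)

    vectors, parents, lambdas, confs = [], [], [], []
    attempts = 0
    while len(vectors) < n_target:
        if attempts >= max_attempts:
            rate = len(vectors) / attempts
            raise AttemptsExhaustedError(
                f"accepted {len(vectors)}/{n_target} after {attempts} attempts "
                f"(acceptance rate {rate:.4f}); widen [{cfg.c_low}, {cfg.c_high}]",
                acceptance_rate=rate,
                interval=(cfg.c_low, cfg.c_high),
            )
        attempts += 1
        i = int(rng.integers(n_min))
        j = int(rng.integers(n_min - 1))
        if j >= i:  # distinct-index draw without rejection
            j += 1
        lam = float(rng.random())
        x_new = minority[i] + lam * (minority[j] - minority[i])
        conf = confidence(model, x_new)
        if cfg.c_low <= conf <= cfg.c_high:
            vectors.append(x_new)
            parents.append((i, j))
            lambdas.append(lam)
            confs.append(conf)

    batch = SyntheticBatch(
        vectors=np.array(vectors),
        parent_indices=np.array(parents, dtype=int),
        lambdas=np.array(lambdas),
        confidences=np.array(confs),
    )
    augmented = LabeledDataset(
        features=np.vstack([dataset.features, batch.vectors]),
        labels=np.concatenate([dataset.labels, np.full(len(batch), MINORITY)]),
    )
    return augmented, batch, model


# ---------------------------------------------------------------------------
# sampler dispatch (used by CV harness and CLI)
# ---------------------------------------------------------------------------


def apply_sampler(
    dataset: LabeledDataset,
    sampler: str,
    params: Optional[dict] = None,
    classifier_spec: Optional["ClassifierSpec"] = None,
    seed: int = 0,
) -> tuple[LabeledDataset, Optional[SyntheticBatch]]:
    """Apply a named sampler to a dataset, returning the augmented dataset.

    ``sampler`` is one of none|ros|smote|adasyn|sos.  For size-parameterized
    samplers, missing size parameters default to full balance.
    """
    params = dict(params or {})
    if sampler == "none":
        return dataset, None
    minority, majority = split_by_class(dataset)
    n_min, n_maj = minority.shape[0], majority.shape[0]

    if sampler == "ros":
        n_extra = int(params.get("n_extra", max(n_maj - n_min, 0)))
        batch = random_oversample(minority, n_extra, seed=params.get("seed", seed))
    elif sampler == "smote":
        cfg = SmoteConfig(
            k=int(params.get("k", min(5, max(n_min - 1, 1)))),
            n_synth=int(params.get("n_synth", max(n_maj - n_min, 0))),
            seed=int(params.get("seed", seed)),
        )
        batch = smote(minority, cfg)
    elif sampler == "adasyn":
        batch = adasyn(
            minority,
            majority,
            beta=float(params.get("beta", 1.0)),
            k=int(params.get("k", 5)),
            seed=int(params.get("seed", seed)),
        )
    elif sampler == "sos":
        if classifier_spec is None:
            raise ValidationError("SOS requires a classifier spec")
        cfg = SOSConfig(
            alpha=float(params.get("alpha", n_maj / n_min)),
            c_low=float(params.get("c_low", 0.5)),
            c_high=float(params.get("c_high", 0.95)),
            max_attempts=params.get("max_attempts"),
            seed=int(params.get("seed", seed)),
        )
        augmented, batch, _ = sos(dataset, classifier_spec, cfg)
        return augmented, batch
    else:
        raise ValidationError(f"unknown sampler {sampler!r}")

    if len(batch) == 0:
        return dataset, batch
    augmented = LabeledDataset(
        features=np.vstack([dataset.features, batch.vectors]),
        labels=np.concatenate([dataset.labels, np.full(len(batch), MINORITY)]),
    )
    return augmented, batch
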