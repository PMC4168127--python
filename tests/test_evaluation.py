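"""Metric, threshold-policy and cross-validation tests, each checked against
an independent brute-force oracle where the contract demands it."""

import itertools

import numpy as np
import pytest

from sosbind.classifiers import ClassifierSpec
from sosbind.errors import ValidationError
from sosbind.evaluation import (
    ConfusionCounts,
    ScoredPredictions,
    ThresholdPolicy,
    class_ratio,
    confusion,
    cross_validate,
    dataset_report,
    metrics,
    roc_auc,
    roc_points,
    select_threshold,
)


def random_preds(rng, n=None):
    n = n or int(rng.integers(4, 60))
    scores = rng.random(n)
    if rng.random() < 0.3:
        scores = np.round(scores, 1)  # force ties
    labels = rng.choice([1, -1], size=n)
    if not (labels == 1).any():
        labels[0] = 1
    if not (labels == -1).any():
        labels[-1] = -1
    return ScoredPredictions(scores=scores, labels=labels)


class TestConfusion:
    def test_threshold_above_all(self):
        p = ScoredPredictions(scores=[0.1, 0.5], labels=[1, -1])
        c = confusion(p, 0.9)
        assert (c.tp, c.fp) == (0, 0)

    def test_threshold_below_all(self):
        p = ScoredPredictions(scores=[0.1, 0.5], labels=[1, -1])
        c = confusion(p, 0.05)
        assert (c.tn, c.fn) == (0, 0)

    def test_hand_count(self):
        p = ScoredPredictions(scores=[0.9, 0.4, 0.5, 0.1], labels=[1, 1, -1, -1])
        c = confusion(p, 0.45)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_boundary_equality_counts_positive(self):
        p = ScoredPredictions(scores=[0.5], labels=[1])
        assert confusion(p, 0.5).tp == 1


class TestMetrics:
    def test_perfect(self):
        assert metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0)) == (1, 1, 1, 1)

    def test_no_association(self):
        _, _, _, mcc = metrics(ConfusionCounts(tp=5, fp=5, tn=5, fn=5))
        assert mcc == 0

    def test_hand_computed_example(self):
        sen, spe, acc, mcc = metrics(ConfusionCounts(tp=40, fn=10, tn=90, fp=10))
        assert sen == pytest.approx(0.8)
        assert spe == pytest.approx(0.9)
        assert acc == pytest.approx(0.86666667)
        assert mcc == pytest.approx(0.7)

    def test_zero_denominator_convention(self):
        sen, spe, acc, mcc = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert (sen, mcc) == (0.0, 0.0)

    def test_mcc_bounds_random(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 30, size=4)
            if counts.sum() == 0:
                continue
            sen, spe, acc, mcc = metrics(ConfusionCounts(*map(int, counts)))
            assert -1 <= mcc <= 1
            assert 0 <= acc <= 1

    def test_label_inversion_negates_mcc(self, rng):
        """Flipping the true labels while keeping predictions maps
        (tp,fp,tn,fn) -> (fp,tp,fn,tn) and negates MCC."""
        for _ in range(50):
            p = random_preds(rng)
            t = float(rng.random())
            c = confusion(p, t)
            inv = ConfusionCounts(tp=c.fp, fp=c.tp, tn=c.fn, fn=c.tn)
            m, mi = metrics(c), metrics(inv)
            assert mi[3] == pytest.approx(0.0 if m[3] == 0 else -m[3])

    def test_threshold_complement_swaps_sen_spe(self, rng):
        """Inverting labels AND complementing scores/threshold swaps
        Sen <-> Spe (and leaves |MCC| unchanged)."""
        for _ in range(50):
            p = random_preds(rng)
            t = float(rng.random())
            if np.any(np.isclose(p.scores, t)):
                continue  # boundary equality would break the flip
            q = ScoredPredictions(scores=1.0 - p.scores, labels=-p.labels)
            m = metrics(confusion(p, t))
            mq = metrics(confusion(q, 1.0 - t))
            assert mq[0] == pytest.approx(m[1])
            assert mq[1] == pytest.approx(m[0])
            assert abs(mq[3]) == pytest.approx(abs(m[3]))


class TestRocAuc:
    def test_perfectly_separated(self):
        p = ScoredPredictions(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, -1, -1])
        assert roc_auc(p) == 1.0

    def test_all_ties(self):
        p = ScoredPredictions(scores=[0.5] * 6, labels=[1, 1, 1, -1, -1, -1])
        assert roc_auc(p) == 0.5

    def test_hand_pairs(self):
        p = ScoredPredictions(scores=[0.9, 0.4, 0.5, 0.1], labels=[1, 1, -1, -1])
        assert roc_auc(p) == pytest.approx(0.75)

    def test_one_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc(ScoredPredictions(scores=[0.1, 0.2], labels=[1, 1]))

    def test_brute_force_pair_oracle(self, rng):
        for _ in range(500):
            p = random_preds(rng)
            pos = p.scores[p.labels == 1]
            neg = p.scores[p.labels == -1]
            wins = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a, b in itertools.product(pos, neg)
            )
            assert roc_auc(p) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        for _ in range(20):
            p = random_preds(rng)
            q = ScoredPredictions(scores=np.exp(3 * p.scores), labels=p.labels)
            assert roc_auc(q) == pytest.approx(roc_auc(p))

    def test_trapezoid_equivalence(self, rng):
        for _ in range(20):
            p = random_preds(rng)
            pts = roc_points(p)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert roc_auc(p) == pytest.approx(area)


def _oracle_select(preds, mode):
    """Exhaustive scan over all candidate thresholds."""
    s = np.unique(preds.scores)
    candidates = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2, [s[-1] + 1.0]])
    best = None
    for t in candidates:
        sen, spe, acc, mcc = metrics(confusion(preds, t))
        key = (mcc, spe, -t) if mode == "max_mcc" else (-abs(sen - spe), mcc, -t)
        if best is None or key > best[0]:
            best = (key, t, (sen, spe, acc, mcc))
    return best[1], best[2]


class TestSelectThreshold:
    def test_separated_gives_mcc_one(self):
        p = ScoredPredictions(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, -1, -1])
        t, (sen, spe, acc, mcc) = select_threshold(p, ThresholdPolicy("max_mcc"))
        assert mcc == 1.0
        assert 0.2 < t < 0.8

    def test_max_mcc_dominates_all_candidates(self, rng):
        p = random_preds(rng, n=40)
        _, (_, _, _, best_mcc) = select_threshold(p, ThresholdPolicy("max_mcc"))
        for t in np.linspace(-0.5, 1.5, 101):
            assert metrics(confusion(p, t))[3] <= best_mcc + 1e-12

    @pytest.mark.parametrize("mode", ["max_mcc", "balanced"])
    def test_matches_exhaustive_oracle(self, rng, mode):
        for _ in range(200):
            p = random_preds(rng)
            t, m = select_threshold(p, ThresholdPolicy(mode))
            t_o, m_o = _oracle_select(p, mode)
            assert t == pytest.approx(t_o)
            assert np.allclose(m, m_o)

    def test_fixed_policy(self):
        p = ScoredPredictions(scores=[0.9, 0.4, 0.5, 0.1], labels=[1, 1, -1, -1])
        t, m = select_threshold(p, ThresholdPolicy("fixed", fixed_value=0.45))
        assert t == 0.45

    def test_balanced_minimizes_gap(self, rng):
        p = random_preds(rng, n=50)
        _, (sen, spe, _, _) = select_threshold(p, ThresholdPolicy("balanced"))
        gaps = [
            abs(metrics(confusion(p, t))[0] - metrics(confusion(p, t))[1])
            for t in np.linspace(-0.5, 1.5, 201)
        ]
        assert abs(sen - spe) <= min(gaps) + 1e-12


class TestBookkeeping:
    def test_class_ratio_printed_counts(self):
        assert round(class_ratio(3104, 59226)) == 19
        assert round(class_ratio(4688, 121158)) == 26

    def test_dataset_report(self):
        labels = np.concatenate([np.ones(10, dtype=int), -np.ones(250, dtype=int)])
        rep = dataset_report(labels)
        assert rep["num_positive"] == 10
        assert rep["num_negative"] == 250
        assert rep["ratio_rounded"] == 25

    def test_zero_positive_errors(self):
        with pytest.raises(ValidationError):
            class_ratio(0, 10)


class TestCrossValidate:
    @pytest.fixture
    def grouped_data(self, rng):
        """10 groups x 20 samples, scores driven by one informative feature."""
        X, y, g = [], [], []
        for p in range(10):
            n_pos = 4
            X.append(rng.normal(size=(20, 3)))
            labels = -np.ones(20, dtype=int)
            labels[:n_pos] = 1
            X[-1][:n_pos, 0] += 2.5
            y.append(labels)
            g += [f"prot{p}"] * 20
        return np.vstack(X), np.concatenate(y), np.array(g)

    def mock_spec(self):
        return ClassifierSpec(
            kind="mock",
            mock_fn=lambda x: 1.0 / (1.0 + np.exp(-x[0])),
        )

    def test_group_partition(self, grouped_data):
        X, y, g = grouped_data
        rep = cross_validate(X, y, g, classifier_spec=self.mock_spec(), k=5, seed=0)
        seen = [grp for f in rep.folds for grp in f.test_groups]
        assert sorted(seen) == sorted(set(g))  # each protein in exactly one fold

    def test_pooled_counts_sum(self, grouped_data):
        X, y, g = grouped_data
        rep = cross_validate(X, y, g, classifier_spec=self.mock_spec(), k=5, seed=1)
        assert sum(f.n_test for f in rep.folds) == len(y) == rep.pooled["n"]

    def test_no_synthetic_leakage(self, grouped_data):
        """Test folds keep their original size whether or not a sampler runs."""
        X, y, g = grouped_data
        for sampler in ("none", "smote"):
            rep = cross_validate(
                X, y, g, sampler=sampler, sampler_params={"k": 3},
                classifier_spec=self.mock_spec(), k=5, seed=2,
            )
            assert sum(f.n_test for f in rep.folds) == len(y)

    def test_determinism(self, grouped_data):
        X, y, g = grouped_data
        r1 = cross_validate(X, y, g, classifier_spec=self.mock_spec(), k=5, seed=3)
        r2 = cross_validate(X, y, g, classifier_spec=self.mock_spec(), k=5, seed=3)
        assert r1.as_dict() == r2.as_dict()

    def test_fewer_groups_than_folds(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.concatenate([np.ones(10, dtype=int), -np.ones(10, dtype=int)])
        g = np.array(["a", "b"] * 10)
        with pytest.raises(ValidationError, match="groups < "):
            cross_validate(X, y, g, classifier_spec=self.mock_spec(), k=5)

    def test_sample_level_when_no_groups(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.where(rng.random(60) < 0.3, 1, -1)
        y[:5] = 1
        y[-5:] = -1
        rep = cross_validate(X, y, None, classifier_spec=self.mock_spec(), k=5, seed=4)
        assert sum(f.n_test for f in rep.folds) == 60
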