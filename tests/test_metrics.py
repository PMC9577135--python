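"""Masked cross-entropy, pooled Dice, one-vs-all AUC, and report assembly,
checked against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

from alseg.legend import LabelMap
from alseg.metrics import (
    ConfusionCounts,
    MetricError,
    accumulate_confusion,
    build_report,
    dice_per_class,
    masked_cross_entropy,
    roc_auc_one_vs_all,
    smooth_loss_curve,
)
from conftest import make_sample


def brute_force_auc(pos, neg):
    """Exhaustive pair counting: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def hand_confusion(pred, truth, n_classes, avoid):
    """Per-pixel loop over the confusion definition."""
    tp = np.zeros(n_classes, int)
    fp = np.zeros(n_classes, int)
    fn = np.zeros(n_classes, int)
    for p, t in zip(pred.ravel(), truth.ravel()):
        if t == avoid:
            continue
        if p == t:
            tp[t] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    return tp, fp, fn


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        labels = np.array([[0, 1], [2, 1]])
        probs = np.zeros((3, 2, 2))
        for i in range(2):
            for j in range(2):
                probs[labels[i, j], i, j] = 1.0
        assert masked_cross_entropy(probs, labels, avoid_index=3) == 0.0

    def test_uniform_prediction_is_log_c(self):
        c = 11
        probs = np.full((c, 4, 4), 1.0 / c)
        labels = np.random.default_rng(0).integers(0, c, size=(4, 4))
        assert abs(masked_cross_entropy(probs, labels, c) - np.log(c)) < 1e-9

    def test_hand_softmax_arithmetic(self):
        logits = np.array([2.0, 0.0, 0.0])
        p = np.exp(logits) / np.exp(logits).sum()
        probs = p[:, None, None] * np.ones((3, 1, 1))
        labels = np.zeros((1, 1), int)
        expected = -np.log(np.exp(2) / (np.exp(2) + 2))
        assert abs(masked_cross_entropy(probs, labels, 3) - expected) < 1e-12
        assert round(expected, 4) == 0.2395

    def test_avoid_pixels_contribute_nothing(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(6, 6))
        labels[labels == 0] = 3  # a third of pixels become avoid
        probs = rng.dirichlet(np.ones(3), size=(6, 6)).transpose(2, 0, 1)
        base = masked_cross_entropy(probs, labels, 3)
        probs2 = probs.copy()
        probs2[:, labels == 3] = rng.dirichlet(np.ones(3), size=int((labels == 3).sum())).T
        assert masked_cross_entropy(probs2, labels, 3) == base

    def test_all_avoid_errors(self):
        with pytest.raises(MetricError):
            masked_cross_entropy(np.full((2, 2, 2), 0.5), np.full((2, 2), 9), 9)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.zeros((2, 1, 1))
        probs[1] = 1.0
        with pytest.warns(UserWarning):
            loss = masked_cross_entropy(probs, np.zeros((1, 1), int), 2)
        assert np.isfinite(loss)

    def test_monotone_in_true_class_mass(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, size=(5, 5))
        probs = rng.dirichlet(np.ones(4), size=(5, 5)).transpose(2, 0, 1)
        losses = []
        for w in [0.0, 0.3, 0.6, 0.9]:
            onehot = np.zeros_like(probs)
            np.put_along_axis(onehot, labels[None], 1.0, axis=0)
            mixed = (1 - w) * probs + w * onehot
            losses.append(masked_cross_entropy(mixed, labels, 4))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestConfusion:
    def test_perfect_prediction(self, legend):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 11, size=(8, 8))
        c = accumulate_confusion(t, t, legend)
        assert (c.fp == 0).all() and (c.fn == 0).all()
        assert c.n_evaluated_pixels == 64

    def test_four_pixel_hand_count(self, legend):
        T, S, A = legend.index_of("Tumor"), legend.index_of("Stroma"), legend.avoid_index
        truth = np.array([[T, T, S, A]])
        pred = np.array([[T, S, S, T]])
        c = accumulate_confusion(pred, truth, legend)
        assert c.tp[T] == 1 and c.fn[T] == 1 and c.fp[T] == 0
        assert c.tp[S] == 1 and c.fp[S] == 1 and c.fn[S] == 0
        assert c.n_evaluated_pixels == 3

    def test_additivity_matches_concatenation(self, legend):
        rng = np.random.default_rng(3)
        t1, t2 = rng.integers(0, 12, size=(2, 6, 6))
        p1, p2 = rng.integers(0, 11, size=(2, 6, 6))
        for t in (t1, t2):
            t[t == 11] = legend.avoid_index
        run = accumulate_confusion(p1, t1, legend)
        run = accumulate_confusion(p2, t2, legend, run)
        cat = accumulate_confusion(
            np.concatenate([p1, p2]), np.concatenate([t1, t2]), legend
        )
        for attr in ("tp", "fp", "fn", "tn"):
            assert (getattr(run, attr) == getattr(cat, attr)).all()

    def test_shape_mismatch(self, legend):
        with pytest.raises(MetricError):
            accumulate_confusion(np.zeros((2, 2), int), np.zeros((3, 3), int), legend)


class TestDice:
    def test_printed_formula(self):
        c = ConfusionCounts(1, tp=np.array([6]), fp=np.array([2]), fn=np.array([2]),
                            tn=np.array([0]))
        d, _ = dice_per_class(c)
        assert d[0] == 0.75

    def test_perfect_class(self):
        c = ConfusionCounts(1, tp=np.array([10]), fp=np.array([0]), fn=np.array([0]),
                            tn=np.array([5]))
        assert dice_per_class(c)[0][0] == 1.0

    def test_zero_tp_with_errors_scores_zero(self):
        c = ConfusionCounts(1, tp=np.array([0]), fp=np.array([3]), fn=np.array([1]),
                            tn=np.array([0]))
        assert dice_per_class(c)[0][0] == 0.0

    def test_absent_class_flagged_undefined_not_zero(self):
        c = ConfusionCounts(2, tp=np.array([5, 0]), fp=np.array([0, 0]),
                            fn=np.array([0, 0]), tn=np.array([0, 5]))
        d, undefined = dice_per_class(c)
        assert 1 not in d and undefined == {1}

    def test_symmetric_under_pred_truth_swap(self, legend):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 11, size=(10, 10))
        b = rng.integers(0, 11, size=(10, 10))
        da, _ = dice_per_class(accumulate_confusion(a, b, legend))
        db, _ = dice_per_class(accumulate_confusion(b, a, legend))
        assert da == db


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        truth = np.array([1, 1, 0, 0])
        assert roc_auc_one_vs_all(scores, truth) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc_one_vs_all(np.full(6, 0.3), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_hand_pair_count(self):
        scores = np.array([0.8, 0.3, 0.6, 0.2])
        truth = np.array([1, 1, 0, 0])
        assert roc_auc_one_vs_all(scores, truth) == 0.75

    def test_single_class_truth_undefined(self):
        assert roc_auc_one_vs_all(np.array([0.1, 0.2]), np.array([1, 1])) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # heavy ties
        truth = rng.integers(0, 2, size=n)
        if truth.all() or not truth.any():
            truth[0] = 1 - truth[0]
        expected = brute_force_auc(scores[truth == 1], scores[truth == 0])
        assert abs(roc_auc_one_vs_all(scores, truth) - expected) < 1e-12


class TestSmoothing:
    def test_truncated_window_means(self):
        assert np.allclose(smooth_loss_curve([3, 2, 1], 3), [2.5, 2.0, 1.5])

    def test_constant_series_unchanged(self):
        assert np.allclose(smooth_loss_curve([4.0] * 7, 3), 4.0)

    def test_window_one_is_identity(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        assert np.allclose(smooth_loss_curve(x, 1), x)

    def test_empty_errors(self):
        with pytest.raises(MetricError):
            smooth_loss_curve([], 3)


class TestReport:
    def _holdout(self, legend, seed=0, n=3):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            idx = rng.integers(0, 12, size=(12, 12)).astype(np.int16)
            idx[idx == 11] = legend.avoid_index
            out.append(make_sample(f"h{i}", f"hp{i}", idx, legend, rng=rng))
        return out

    @staticmethod
    def _one_hot_predictor(legend):
        def predict(sample):
            idx = sample.labels.indices.copy()
            idx[idx == legend.avoid_index] = 0  # arbitrary tissue for avoid pixels
            probs = np.zeros((legend.n_classes,) + idx.shape)
            np.put_along_axis(probs, idx[None], 1.0, axis=0)
            return probs

        return predict

    def test_oracle_predictor_scores_one(self, legend):
        holdout = self._holdout(legend)
        rep = build_report(holdout, self._one_hot_predictor(legend), None, legend)
        assert all(v == 1.0 for v in rep.dice.values())
        assert rep.mean_dice == 1.0

    def test_constant_predictor_closed_form(self, legend):
        holdout = self._holdout(legend, seed=5)
        cls = legend.index_of("Tumor")

        def predict(sample):
            probs = np.full((legend.n_classes,) + sample.labels.shape, 1e-6)
            probs[cls] = 1.0
            return probs / probs.sum(axis=0)

        rep = build_report(holdout, predict, None, legend)
        truth = np.concatenate([s.labels.indices.ravel() for s in holdout])
        truth = truth[truth != legend.avoid_index]
        p = (truth == cls).mean()
        assert rep.dice["Tumor"] == pytest.approx(2 * p / (p + 1))
        assert all(v == 0.0 for k, v in rep.dice.items() if k != "Tumor")

    def test_report_covers_present_classes_only(self, legend):
        holdout = self._holdout(legend, seed=6)
        rep = build_report(holdout, self._one_hot_predictor(legend), None, legend)
        present = set()
        for s in holdout:
            idx = s.labels.indices
            present |= {legend.name_of(c) for c in np.unique(idx[idx != legend.avoid_index])}
        assert set(rep.dice) == present
        assert rep.classes_absent == {n for n in legend.class_names if n not in present}
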