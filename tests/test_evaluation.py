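"""Metrics, fitness criterion and the cross-validation harness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hostsieve.evaluation import (
    ConfusionCounts,
    CVResult,
    accuracy,
    auc,
    confusion_from_scores,
    cross_validate,
    fitness,
    mcc,
    roc_points,
    stratified_folds,
)
from hostsieve.models import Hyperparameters


def mann_whitney_auc(scores, labels):
    """Independent oracle: pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0

    def test_numerator_cancels(self):
        assert mcc(ConfusionCounts(tp=1, fp=1, tn=1, fn=1)) == 0.0

    def test_closed_form_spot_check(self):
        # (3*4 - 1*2) / sqrt(4*5*5*6) = 10 / sqrt(600)
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc(c) == pytest.approx(10 / np.sqrt(600))
        assert mcc(c) == pytest.approx(0.4082, abs=1e-4)

    def test_zero_denominator_factor_gives_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=5)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_symmetric_under_class_swap(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        a = mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        b = mcc(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert a == pytest.approx(b)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        c = ConfusionCounts(
            tp=int(((pred == 1) & (y == 1)).sum()),
            fp=int(((pred == 1) & (y == 0)).sum()),
            tn=int(((pred == 0) & (y == 0)).sum()),
            fn=int(((pred == 0) & (y == 1)).sum()),
        )
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_chance(self):
        assert auc([0.5] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_three_of_four_concordant_pairs(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_trapezoid_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            # discretized scores so ties actually occur
            scores = np.round(rng.random(n), 1)
            assert auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        fpr, tpr, _ = roc_points(labels, scores)
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestFitness:
    def test_direct_arithmetic(self):
        cv = CVResult(
            fold_mcc=[0.9, 0.9], fold_auc=[0.95, 0.95], fold_accuracy=[0.9, 0.9]
        )
        assert fitness(cv) == pytest.approx(0.9 + 0.95)
        # general case with explicit SDs
        cv2 = CVResult(
            fold_mcc=[0.86, 0.94], fold_auc=[0.93, 0.97], fold_accuracy=[0.9, 0.9]
        )
        assert fitness(cv2) == pytest.approx(0.9 + 0.95 - 0.04 / 4 - 0.02 / 4)
        assert fitness(cv2) == pytest.approx(1.835)

    def test_global_maximum_is_two(self):
        cv = CVResult(
            fold_mcc=[1.0] * 5, fold_auc=[1.0] * 5, fold_accuracy=[1.0] * 5
        )
        assert fitness(cv) == 2.0

    def test_monotone_in_means_and_antitone_in_sds(self):
        base = CVResult(
            fold_mcc=[0.7, 0.8, 0.9], fold_auc=[0.8, 0.85, 0.9],
            fold_accuracy=[0.8] * 3,
        )
        higher_mean = CVResult(
            fold_mcc=[0.75, 0.85, 0.95], fold_auc=base.fold_auc,
            fold_accuracy=[0.8] * 3,
        )
        wider_spread = CVResult(
            fold_mcc=[0.6, 0.8, 1.0], fold_auc=base.fold_auc,
            fold_accuracy=[0.8] * 3,
        )
        assert fitness(higher_mean) > fitness(base)
        assert fitness(wider_spread) < fitness(base)  # same mean, larger SD

    def test_population_sd_is_used(self):
        cv = CVResult(
            fold_mcc=[0.8, 1.0], fold_auc=[0.9, 0.9], fold_accuracy=[0.9, 0.9]
        )
        assert cv.sd_mcc == pytest.approx(0.1)  # population SD, not ddof=1

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            CVResult(fold_mcc=[0.9], fold_auc=[0.9], fold_accuracy=[0.9])


class TestCrossValidation:
    def test_folds_partition_every_sample_once(self):
        y = np.array([0, 1] * 50)
        folds = stratified_folds(y, n_folds=5, seed=0)
        assert len(folds) == 100
        sizes = np.bincount(folds)
        assert sizes.sum() == 100 and len(sizes) == 5
        assert sizes.max() - sizes.min() <= 1

    def test_separable_corpus_reaches_high_auc(self, corpus_Xy):
        X, y = corpus_Xy
        cv = cross_validate(X, y, Hyperparameters("lr"), seed=0)
        assert len(cv.fold_auc) == 5
        assert cv.mean_auc > 0.9

    def test_label_randomized_data_is_at_chance(self, corpus_Xy):
        X, y = corpus_Xy
        rng = np.random.default_rng(99)
        y_perm = rng.permutation(y)
        cv = cross_validate(X, y_perm, Hyperparameters("lr"), seed=0)
        assert abs(cv.mean_auc - 0.5) < 0.1

    def test_deterministic_given_seed(self, corpus_Xy):
        X, y = corpus_Xy
        a = cross_validate(X, y, Hyperparameters("qda"), seed=7)
        b = cross_validate(X, y, Hyperparameters("qda"), seed=7)
        assert np.array_equal(a.fold_auc, b.fold_auc)
        assert np.array_equal(a.fold_mcc, b.fold_mcc)

    def test_fold_missing_a_class_raises(self, corpus_Xy):
        X, y = corpus_Xy
        bad_folds = np.where(y == 1, 0, 1)  # fold 0 all-positive
        with pytest.raises(ValueError, match="lacks"):
            cross_validate(X, y, Hyperparameters("lr"), folds=bad_folds)


class TestConfusionAndAccuracy:
    def test_threshold_binarization(self):
        c = confusion_from_scores([1, 0, 1, 0], [0.7, 0.3, 0.4, 0.6])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)
        assert accuracy(c) == 0.5

    def test_phage_probability_point_seven_is_positive_call(self):
        c = confusion_from_scores([1], [0.7])
        assert c.tp == 1 and c.fn == 0
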