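"""AUC, Cohen's kappa, max-kappa thresholding and cross-validation."""

import numpy as np
import pytest

from extrisk import (
    ConfusionMatrix,
    ForestConfig,
    auc,
    cohens_kappa,
    confusion_at,
    cross_validate,
    max_kappa_threshold,
    stratified_folds,
)
from extrisk.evaluate import _candidate_thresholds, roc_points


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_computed_three_quarters(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 concordant of 4 pairs
        assert auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(auc([0.1, 0.2], [1, 1]))

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = (rng.random(n) < 0.5).astype(float)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_matches_roc_integral(self, rng):
        # trapezoidal integral of the ROC curve equals the rank formula
        for _ in range(20):
            scores = rng.random(40)
            labels = (rng.random(40) < 0.4).astype(float)
            if labels.sum() in (0, 40):
                continue
            pts = roc_points(scores, labels)
            integral = np.trapezoid(pts["tpr"], pts["fpr"])
            assert integral == pytest.approx(auc(scores, labels), abs=1e-9)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(float)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionMatrix(tp=10, fp=0, fn=0, tn=15)) == 1.0

    def test_chance_level_all_positive(self):
        assert cohens_kappa(ConfusionMatrix(tp=25, fp=25, fn=0, tn=0)) == 0.0

    def test_hand_value_symmetric_case(self):
        assert cohens_kappa(ConfusionMatrix(tp=40, fp=10, fn=10, tn=40)) == pytest.approx(0.6)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        y = (rng.random(300) < 0.4).astype(int)
        pred = (rng.random(300) < 0.5).astype(int)
        cm = ConfusionMatrix(
            tp=np.sum((pred == 1) & (y == 1)), fp=np.sum((pred == 1) & (y == 0)),
            fn=np.sum((pred == 0) & (y == 1)), tn=np.sum((pred == 0) & (y == 0)),
        )
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(y, pred))


class TestMaxKappaThreshold:
    def test_clean_separation_midpoint(self):
        thr = max_kappa_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert thr == pytest.approx(0.5)  # midpoint of 0.2 and 0.8
        assert cohens_kappa(confusion_at([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], thr)) == 1.0

    def test_uninformative_scores_return_smallest_sentinel(self):
        scores = [0.4] * 6
        thr = max_kappa_threshold(scores, [1, 0, 1, 0, 1, 0])
        assert thr == min(_candidate_thresholds(np.array(scores)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            max_kappa_threshold([0.1, 0.9], [1, 1])

    def test_maximizes_over_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 2)
            labels = (rng.random(n) < 0.5).astype(float)
            if labels.sum() in (0, n):
                continue
            thr = max_kappa_threshold(scores, labels)
            k_at = cohens_kappa(confusion_at(scores, labels, thr))
            for cand in _candidate_thresholds(scores):
                assert k_at >= cohens_kappa(confusion_at(scores, labels, cand)) - 1e-12

    def test_mirrored_problem_achieves_same_max_kappa(self, rng):
        # swapping labels and negating scores mirrors the scan exactly
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(float)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        thr1 = max_kappa_threshold(scores, labels)
        thr2 = max_kappa_threshold(-scores, 1 - labels)
        k1 = cohens_kappa(confusion_at(scores, labels, thr1))
        k2 = cohens_kappa(confusion_at(-scores, 1 - labels, thr2))
        assert k1 == pytest.approx(k2, abs=1e-9)


class TestConfusionMetrics:
    def test_derived_rates_recompute_exactly(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(float)
        cm = confusion_at(scores, labels, 0.5)
        assert cm.sensitivity == (cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else np.nan)
        assert cm.specificity == cm.tn / (cm.tn + cm.fp)
        assert cm.accuracy == (cm.tp + cm.tn) / cm.n
        assert cm.n == 50


class TestFolds:
    def test_fold_sizes_103_by_10(self, rng):
        labels = (rng.random(103) < 0.3).astype(float)
        folds = stratified_folds(labels, 10, seed=1)
        sizes = sorted(np.bincount(folds, minlength=10))
        assert sizes == [10] * 7 + [11] * 3

    def test_leave_one_out(self, rng):
        labels = np.array([0, 1] * 6, dtype=float)
        folds = stratified_folds(labels, 12, seed=0)
        assert sorted(np.bincount(folds)) == [1] * 12

    def test_stratification_balance(self, rng):
        labels = (rng.random(200) < 0.25).astype(float)
        folds = stratified_folds(labels, 10, seed=3)
        per_fold_pos = [labels[folds == f].sum() for f in range(10)]
        assert max(per_fold_pos) - min(per_fold_pos) <= 1


class TestCrossValidate:
    def _data(self, rng, n=200):
        X = rng.standard_normal((n, 4))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(float)
        return X, y

    def test_reproducible_and_consistent(self, rng):
        X, y = self._data(rng)
        cfg = ForestConfig(n_trees=20)
        cv1 = cross_validate(X, y, list("abcd"), ["n"] * 4, k=5, config=cfg, seed=2)
        cv2 = cross_validate(X, y, list("abcd"), ["n"] * 4, k=5, config=cfg, seed=2)
        assert np.array_equal(cv1.scores, cv2.scores)
        assert cv1.pooled == cv2.pooled
        # reported metrics recompute bit-exactly from the stored confusion matrix
        cm = cv1.confusion
        assert cv1.pooled["accuracy"] == (cm.tp + cm.tn) / cm.n
        assert cv1.pooled["sensitivity"] == cm.tp / (cm.tp + cm.fn)
        assert cv1.pooled["specificity"] == cm.tn / (cm.tn + cm.fp)
        assert cv1.pooled["kappa"] == cohens_kappa(cm)
        assert set(np.bincount(cv1.folds)) <= {40}

    def test_unlabeled_rows_rejected(self, rng):
        X, y = self._data(rng, n=50)
        y[0] = np.nan
        with pytest.raises(ValueError):
            cross_validate(X, y, list("abcd"), ["n"] * 4, k=5)
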