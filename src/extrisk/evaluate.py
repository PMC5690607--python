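"""Classifier evaluation: ROC AUC, Cohen's kappa, max-kappa thresholding,
and stratified k-fold cross-validation of the forest.

The forest outputs a probability of being assessed "at risk"; a species
is *called* at risk when its score strictly exceeds the threshold that
maximizes Cohen's kappa against the Red-List-derived binary labels.
Model skill is summarised by pooled holdout AUC, accuracy, sensitivity,
specificity and kappa from 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cif import ConditionalInferenceForest, ForestConfig

__all__ = [
    "ConfusionMatrix",
    "auc",
    "cohens_kappa",
    "max_kappa_threshold",
    "confusion_at",
    "CVResult",
    "cross_validate",
    "stratified_folds",
]


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with predicted at-risk as "positive"."""

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via pairwise concordance.

    Equals (concordant pairs + 0.5 * tied pairs) / (n+ * n-), computed
    through midranks.  With a single class present the AUC is undefined
    and returned as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; returning NaN")
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    When expected agreement p_e is 1 (degenerate marginals) kappa is 0 by
    convention.
    """
    n = cm.n
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if abs(1.0 - pe) < 1e-15:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionMatrix:
    """Confusion counts under the rule ``score > threshold -> at risk``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=float(np.sum(pred & pos)),
        fp=float(np.sum(pred & ~pos)),
        fn=float(np.sum(~pred & pos)),
        tn=float(np.sum(~pred & ~pos)),
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    below = distinct[0] - 1.0
    above = distinct[-1] + 1.0
    return np.concatenate([[below], mids, [above]])


def max_kappa_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing Cohen's kappa.

    Candidates are the midpoints between consecutive distinct scores plus
    sentinels below the minimum and above the maximum; the smallest
    candidate achieving the maximum kappa is returned.  Both classes must
    be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("max-kappa threshold requires both classes")
    best_thr, best_kappa = None, -np.inf
    for thr in _candidate_thresholds(scores):
        k = cohens_kappa(confusion_at(scores, labels, thr))
        if k > best_kappa + 1e-15:
            best_thr, best_kappa = float(thr), k
    return best_thr


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve as (threshold, fpr, tpr) rows over all candidate cuts."""
    rows = []
    for thr in _candidate_thresholds(np.asarray(scores, dtype=float)):
        cm = confusion_at(scores, labels, thr)
        rows.append({"threshold": thr, "fpr": 1.0 - cm.specificity, "tpr": cm.sensitivity})
    return pd.DataFrame(rows).sort_values(["fpr", "tpr"], ignore_index=True)


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment with fold sizes differing by <= 1.

    Cases are shuffled within class, concatenated class by class, and
    dealt round-robin; this keeps both the overall fold sizes and the
    per-class allocations as equal as possible.
    """
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    rng = np.random.default_rng(seed)
    order = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        order.append(rng.permutation(idx))
    order = np.concatenate(order)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


@dataclass
class CVResult:
    """Cross-validated performance of the forest.

    ``threshold`` is the max-kappa cutoff chosen on the pooled holdout
    scores (canonical); ``refit_threshold`` is the same scan on a
    full-data refit's in-sample scores, reported alongside.
    """

    folds: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    threshold: float
    pooled: dict
    per_fold: pd.DataFrame
    confusion: ConfusionMatrix
    refit_threshold: float | None = None
    notes: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = dict(self.pooled)
        return pd.DataFrame({"metric": list(rows), "value": list(rows.values())})


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    kinds: list[str],
    k: int = 10,
    config: ForestConfig | None = None,
    seed: int = 0,
    refit_full: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the conditional forest.

    Each fold is held out in turn, the forest is fitted on the remainder
    and the holdout is scored.  Pooled holdout scores give the AUC and
    the max-kappa threshold; accuracy, sensitivity, specificity and
    kappa are reported at that threshold.  A training fold that loses a
    class triggers a logged re-stratification with a shifted seed.
    """
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("cross_validate expects labeled cases only")
    n = len(y)
    notes: list[str] = []
    folds = stratified_folds(y, k, seed)
    for attempt in range(10):
        bad = any(len(np.unique(y[folds != f])) < 2 for f in range(k))
        if not bad:
            break
        notes.append(f"re-stratified folds (seed offset {attempt + 1}): single-class training fold")
        folds = stratified_folds(y, k, seed + attempt + 1)
    else:
        raise ValueError("could not stratify folds with both classes in every training set")

    scores = np.empty(n, dtype=float)
    for f in range(k):
        hold = folds == f
        forest = ConditionalInferenceForest.fit(
            X[~hold], y[~hold], feature_names, kinds, config=config, seed=seed * 1009 + f,
        )
        scores[hold] = forest.predict_proba(X[hold])

    threshold = max_kappa_threshold(scores, y)
    cm = confusion_at(scores, y, threshold)
    pooled = {
        "auc": auc(scores, y),
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "kappa": cohens_kappa(cm),
        "threshold": threshold,
    }
    rows = []
    for f in range(k):
        hold = folds == f
        cm_f = confusion_at(scores[hold], y[hold], threshold)
        single = len(np.unique(y[hold])) < 2
        rows.append({
            "fold": f,
            "n": int(hold.sum()),
            "auc": float("nan") if single else auc(scores[hold], y[hold]),
            "accuracy": cm_f.accuracy,
            "sensitivity": cm_f.sensitivity,
            "specificity": cm_f.specificity,
            "kappa": cohens_kappa(cm_f),
        })
    per_fold = pd.DataFrame(rows)

    refit_threshold = None
    if refit_full:
        forest = ConditionalInferenceForest.fit(
            X, y, feature_names, kinds, config=config, seed=seed * 1009 + k,
        )
        refit_threshold = max_kappa_threshold(forest.predict_proba(X), y)

    return CVResult(
        folds=folds, scores=scores, labels=y, threshold=threshold,
        pooled=pooled, per_fold=per_fold, confusion=cm,
        refit_threshold=refit_threshold, notes=notes,
    )
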