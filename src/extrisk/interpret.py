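"""Model interpretation: permutation variable importance and partial
dependence at a fixed reference profile.

Partial dependence here substitutes each grid value into a single
reference profile (numeric features at their means, categorical features
at their modal level) and scores it, rather than averaging over the
data; the geographic attribution maps reuse the identical construction
so the two surfaces are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cif import ConditionalInferenceForest
from .zonal import FeatureMatrix

__all__ = [
    "reference_profile",
    "permutation_importance",
    "partial_dependence",
    "PDCurve",
    "ImportanceTable",
]


def reference_profile(features: FeatureMatrix) -> dict:
    """Global reference profile: numeric means, categorical modes.

    Means are over non-missing values; modal ties break toward the
    smallest encoded level.  A feature with no observed value at all is
    an error naming the feature.
    """
    profile: dict = {}
    for name, kind in features.kinds.items():
        col = features.data[name].dropna()
        if len(col) == 0:
            raise ValueError(f"feature {name!r} is entirely missing; no reference value")
        if kind == "numeric":
            profile[name] = float(col.mean())
        else:
            levels, counts = np.unique(col.to_numpy(), return_counts=True)
            order = {lev: i for i, lev in enumerate(features.levels[name])}
            best = min(
                (lev for lev, c in zip(levels, counts) if c == counts.max()),
                key=lambda lev: order.get(lev, np.inf),
            )
            profile[name] = best
    return profile


def _profile_matrix(features: FeatureMatrix, profile: dict, n_rows: int) -> np.ndarray:
    """Encode the reference profile as n_rows identical feature rows."""
    row = pd.DataFrame([profile] * n_rows, columns=features.feature_names)
    fm = FeatureMatrix(
        data=row, kinds=dict(features.kinds),
        levels={k: list(v) for k, v in features.levels.items()},
    )
    X, _, _ = fm.to_matrix()
    return X


@dataclass
class ImportanceTable:
    """Permutation importance: mean decrease in out-of-subsample accuracy."""

    table: pd.DataFrame  # feature, importance, sd, rank
    n_reps: int

    def __repr__(self) -> str:
        return f"ImportanceTable(n_reps={self.n_reps})\n{self.table.to_string(index=False)}"


def permutation_importance(
    forest: ConditionalInferenceForest,
    X: np.ndarray,
    y: np.ndarray,
    n_reps: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Out-of-subsample permutation importance.

    For every tree, accuracy (at the 0.5 probability cut) on the rows
    the tree did not see is compared with accuracy after permuting one
    feature among those rows; the importance of the feature is the mean
    drop over trees and ``n_reps`` permutation replicates.  A constant
    feature scores exactly 0.  Ranks are 1..p by decreasing importance.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    labeled = ~np.isnan(y)
    Xl, yl = X[labeled], y[labeled]
    n = len(yl)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    # per (rep, feature): mean over trees of (oob acc - permuted oob acc)
    drops = np.zeros((n_reps, p))
    counts = np.zeros(p)
    all_idx = np.arange(n)
    for tree, sub in zip(forest.trees, forest.subsamples):
        oob = np.setdiff1d(all_idx, sub, assume_unique=False)
        if len(oob) == 0:
            continue
        Xo, yo = Xl[oob], yl[oob]
        base_acc = np.mean((tree.predict_proba(Xo) > 0.5) == (yo == 1))
        counts += 1
        for j in range(p):
            col = Xo[:, j]
            if np.all(col == col[0]) or np.all(np.isnan(col)):
                continue  # permutation is a no-op in distribution
            for r in range(n_reps):
                perm = rng.permutation(len(oob))
                Xp = Xo.copy()
                Xp[:, j] = col[perm]
                acc = np.mean((tree.predict_proba(Xp) > 0.5) == (yo == 1))
                drops[r, j] += base_acc - acc
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = drops / np.maximum(counts, 1)
    importance = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(p)
    order = np.argsort(-importance, kind="mergesort")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame({
        "feature": forest.feature_names,
        "importance": importance,
        "sd": sd,
        "rank": rank,
    }).sort_values("rank", ignore_index=True)
    return ImportanceTable(table=table, n_reps=n_reps)


@dataclass
class PDCurve:
    feature: str
    kind: str
    grid: np.ndarray  # numeric values or encoded category codes
    labels: list | None  # category labels for categorical features
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        x = self.labels if self.labels is not None else self.grid
        return pd.DataFrame({self.feature: x, "probability": self.probability})


def partial_dependence(
    forest: ConditionalInferenceForest,
    features: FeatureMatrix,
    feature: str,
    n_grid: int = 50,
    profile: dict | None = None,
) -> PDCurve:
    """Risk probability along one feature, others fixed at the profile.

    Numeric features are evaluated on the 0.01..0.99 quantile grid of
    their observed values (``n_grid`` points, sorted); categorical
    features get one prediction per observed level.
    """
    if feature not in forest.feature_names:
        raise ValueError(f"feature {feature!r} is not in the model")
    if profile is None:
        profile = reference_profile(features)
    kind = features.kinds[feature]
    j = forest.feature_names.index(feature)
    if kind == "numeric":
        obs = features.data[feature].dropna().to_numpy(dtype=float)
        if len(obs) == 0:
            raise ValueError(f"feature {feature!r} has no observed values")
        grid = np.unique(np.quantile(obs, np.linspace(0.01, 0.99, n_grid)))
        Xp = _profile_matrix(features, profile, len(grid))
        Xp[:, j] = grid
        prob = forest.predict_proba(Xp)
        return PDCurve(feature=feature, kind=kind, grid=grid, labels=None, probability=prob)
    levels = features.levels[feature]
    Xp = _profile_matrix(features, profile, len(levels))
    Xp[:, j] = np.arange(len(levels), dtype=float)
    prob = forest.predict_proba(Xp)
    return PDCurve(
        feature=feature, kind=kind, grid=np.arange(len(levels), dtype=float),
        labels=list(levels), probability=prob,
    )
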