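"""Conditional inference trees and forests for a binary response.

This is the package's modelling core: recursive partitioning in which the
split *variable* at each node is chosen by a permutation-test association
p-value rather than by exhaustive impurity search, which removes the
classical selection bias toward variables offering many split points.

For a feature x with influence g(x) (the raw values for numeric features,
indicator coding for categorical ones) and binary labels y with case
weights w, the linear statistic is

    T = sum_i w_i g(x_i) y_i .

Under the permutation null (y randomly permuted against x, holding both
marginals fixed) T has conditional mean and covariance

    mu    = E_w(y) * sum_i w_i g(x_i)
    Sigma = V_w(y) * ( W * S_gg - s_g s_g^T ) / (W - 1)

with W = sum w_i, E_w/V_w the weighted mean/variance of y,
S_gg = sum w_i g g^T and s_g = sum w_i g.  The standardized quadratic
form c = (T - mu)^T Sigma^+ (T - mu) is referred to a chi-square
distribution with df = rank(Sigma).  Cases with missing x are excluded
from the statistic; at a fitted split they are routed by weight instead
of being imputed.

Splits within the selected variable maximize the analogous two-sample
standardized statistic over candidate cutpoints (numeric) or binary
level partitions (categorical).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg as sla
from scipy.stats import chi2

__all__ = [
    "ForestConfig",
    "SplitTest",
    "TreeNode",
    "ConditionalInferenceTree",
    "ConditionalInferenceForest",
    "split_pvalue",
    "select_split_variable",
    "best_split_point",
    "route_case",
]

_EPS = 1e-12


@dataclass
class ForestConfig:
    """Hyperparameters of the conditional inference forest.

    Defaults follow the conventional settings of permutation-test
    forests: 500 trees, split-selection level alpha = 0.05 with
    Bonferroni adjustment over the mtry candidates, per-tree subsamples
    of fraction 0.632 drawn *without* replacement, and node-size floors
    of 20 (to attempt a split) and 7 (per child).
    """

    n_trees: int = 500
    alpha: float = 0.05
    mtry: int = 5
    subsample_fraction: float = 0.632
    min_split: float = 20.0
    min_leaf: float = 7.0
    max_depth: int | None = None
    #: exhaustive binary-partition search for categorical features with at
    #: most this many observed levels; above it, levels are ordered by
    #: class rate and scanned like a numeric feature
    exhaustive_cat_max: int = 12

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.min_leaf < 1 or self.min_split < 2:
            raise ValueError("node size limits too small")


@dataclass
class SplitTest:
    """Association test of one candidate feature at a node."""

    feature: int | None
    statistic: float
    p_value: float
    adj_p_value: float
    n_used: int


# ---------------------------------------------------------------------------
# association p-values


def _weighted_label_moments(y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    W = float(w.sum())
    if W <= 0:
        return 0.0, 0.0, 0.0
    eh = float((w * y).sum()) / W
    vh = eh * (1.0 - eh)
    return W, eh, vh


def _numeric_test(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """(statistic, p) for a numeric feature; (nan, 1) when degenerate."""
    W, eh, vh = _weighted_label_moments(y, w)
    if W <= 1 or vh <= _EPS:
        return float("nan"), 1.0
    if x.min() == x.max():
        return float("nan"), 1.0
    sx = float((w * x).sum())
    sxx = float((w * x * x).sum())
    t = float((w * x * y).sum())
    sigma2 = vh * (W * sxx - sx * sx) / (W - 1.0)
    if sigma2 <= _EPS * max(1.0, sxx):
        return float("nan"), 1.0
    stat = (t - eh * sx) ** 2 / sigma2
    return stat, float(chi2.sf(stat, 1))


def _categorical_test(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """(statistic, p) for a categorical feature via the quadratic form."""
    W, eh, vh = _weighted_label_moments(y, w)
    if W <= 1 or vh <= _EPS:
        return float("nan"), 1.0
    codes = x.astype(np.int64)
    n_lev = codes.max() + 1
    s = np.bincount(codes, weights=w, minlength=n_lev)
    t = np.bincount(codes, weights=w * y, minlength=n_lev)
    present = s > 0
    if present.sum() < 2:
        return float("nan"), 1.0
    s, t = s[present], t[present]
    d = t - eh * s
    sigma = vh * (W * np.diag(s) - np.outer(s, s)) / (W - 1.0)
    evals, evecs = sla.eigh(sigma)
    tol = max(evals.max(), 0.0) * len(s) * np.finfo(float).eps
    keep = evals > max(tol, _EPS)
    rank = int(keep.sum())
    if rank == 0:
        return float("nan"), 1.0
    proj = evecs[:, keep].T @ d
    stat = float(np.sum(proj * proj / evals[keep]))
    return stat, float(chi2.sf(stat, rank))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, kind: str) -> float | None:
    """Exact permutation p by complete enumeration of label assignments.

    Applicable to small unweighted nodes; enumerates every placement of
    the class-1 labels and counts assignments whose standardized
    statistic is at least the observed one.  Returns ``None`` when the
    configuration is degenerate.
    """
    from itertools import combinations

    n = len(y)
    n1 = int(round(y.sum()))
    if n1 == 0 or n1 == n:
        return None
    combos = np.array(list(combinations(range(n), n1)), dtype=np.int64)
    if kind == "c":
        codes = x.astype(np.int64)
        codes = np.unique(codes, return_inverse=True)[1]  # compact 0..k-1
        k = codes.max() + 1
        if k < 2:
            return None
        onehot = np.eye(k)[codes]  # (n, k)
        s = onehot.sum(axis=0)
        eh = n1 / n
        vh = eh * (1 - eh)
        sigma = vh * (n * np.diag(s) - np.outer(s, s)) / (n - 1)
        evals, evecs = sla.eigh(sigma)
        keep = evals > max(evals.max() * k * np.finfo(float).eps, _EPS)
        if not keep.any():
            return None
        inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
        t_all = onehot[combos].sum(axis=1)  # (m, k)
        d = t_all - eh * s
        stats = np.einsum("ij,jk,ik->i", d, inv, d)
        d_obs = np.bincount(codes, weights=y, minlength=k) - eh * s
        obs = float(d_obs @ inv @ d_obs)
    else:
        sx = x.sum()
        eh = n1 / n
        stats = np.abs(x[combos].sum(axis=1) - eh * sx)
        obs = abs(float(x @ y) - eh * sx)
    return float(np.mean(stats >= obs - 1e-9))


#: largest node size at which the exact enumeration test is used
EXACT_MAX_N = 14


def split_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    kind: str = "n",
    exact_max_n: int = EXACT_MAX_N,
) -> SplitTest:
    """Permutation-test association p-value between one feature and y.

    Cases with missing x are excluded.  The p-value comes from the
    chi-square reference of the standardized quadratic form; for small
    unweighted nodes (at most ``exact_max_n`` cases) the permutation
    null is enumerated exactly instead, where the asymptotic reference
    is unreliable.  A feature that is constant after missing removal
    (or otherwise degenerate) gets the sentinel p = 1 and is never
    selected for splitting.  The test is invariant to swapping the two
    class labels and, for categorical x, to any relabeling of the
    category codes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ok = ~np.isnan(x)
    x, yv, wv = x[ok], y[ok], w[ok]
    n_used = int(ok.sum())
    if n_used < 2:
        return SplitTest(None, float("nan"), 1.0, 1.0, n_used)
    if kind == "c":
        stat, p = _categorical_test(x, yv, wv)
    else:
        stat, p = _numeric_test(x, yv, wv)
    if (
        p < 1.0
        and n_used <= exact_max_n
        and np.allclose(wv, wv[0])
        and x.min() != x.max()
    ):
        p_exact = _exact_permutation_p(x, yv, kind)
        if p_exact is not None:
            p = p_exact
    return SplitTest(None, stat, p, p, n_used)


def select_split_variable(
    X: np.ndarray,
    y: np.ndarray,
    candidates: np.ndarray,
    kinds: list[str],
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[int, SplitTest] | None:
    """Pick the candidate feature with the smallest association p-value.

    Candidates are compared on raw p-values (ties toward the smallest
    feature index); the winner's Bonferroni-adjusted p over the number
    of candidates must reach ``alpha``, else the node stops.  Returns
    ``None`` (stop) when no candidate passes or every candidate is
    degenerate.
    """
    candidates = np.sort(np.asarray(candidates, dtype=int))
    if candidates.size == 0:
        return None
    m = len(candidates)
    best: tuple[int, SplitTest] | None = None
    for j in candidates:
        t = split_pvalue(X[:, j], y, weights, kind=kinds[j])
        if t.p_value >= 1.0:
            continue  # degenerate sentinel, never selected
        t.adj_p_value = min(1.0, t.p_value * m)
        t.feature = int(j)
        if best is None or t.p_value < best[1].p_value:
            best = (int(j), t)
    if best is None or best[1].adj_p_value > alpha:
        return None
    return best


# ---------------------------------------------------------------------------
# split-point search within the selected variable


def best_split_point(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    kind: str = "n",
    min_leaf: float = 7.0,
    exhaustive_cat_max: int = 12,
):
    """Best admissible split of the already-selected variable.

    Numeric: the cutpoint (midpoint between consecutive distinct values)
    maximizing the two-sample standardized statistic, subject to a
    weighted ``min_leaf`` on both sides; rule is ``value <= cut -> left``.
    Categorical: the binary partition of observed levels maximizing the
    statistic (exhaustive up to ``exhaustive_cat_max`` levels, class-rate
    ordered scan above); returns the sorted array of left-side codes.

    Returns a float cutpoint, an ``np.ndarray`` of left codes, or ``None``
    when no admissible split exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ok = ~np.isnan(x)
    x, y, w = x[ok], y[ok], w[ok]
    if x.size < 2:
        return None
    W, eh, vh = _weighted_label_moments(y, w)
    if vh <= _EPS:
        return None

    if kind == "n":
        order = np.argsort(x, kind="mergesort")
        xs, ys, ws = x[order], y[order], w[order]
        cw = np.cumsum(ws)
        cwy = np.cumsum(ws * ys)
        boundary = np.nonzero(np.diff(xs) > 0)[0]  # split after index b
        if boundary.size == 0:
            return None
        wl = cw[boundary]
        tl = cwy[boundary]
        admissible = (wl >= min_leaf) & (W - wl >= min_leaf)
        if not admissible.any():
            return None
        sigma2 = vh * wl * (W - wl) / (W - 1.0)
        stat = np.where(admissible, (tl - eh * wl) ** 2 / np.maximum(sigma2, _EPS), -np.inf)
        b = boundary[int(np.argmax(stat))]  # first max -> smallest cutpoint on ties
        return float((xs[b] + xs[b + 1]) / 2.0)

    # categorical
    codes = x.astype(np.int64)
    n_lev = codes.max() + 1
    s = np.bincount(codes, weights=w, minlength=n_lev)
    t = np.bincount(codes, weights=w * y, minlength=n_lev)
    present = np.nonzero(s > 0)[0]
    k = len(present)
    if k < 2:
        return None
    sp, tp = s[present], t[present]

    if k <= exhaustive_cat_max:
        # enumerate partitions with present[0] fixed to the right side
        n_sub = (1 << (k - 1)) - 1
        masks = np.arange(1, n_sub + 1, dtype=np.uint32)
        bits = ((masks[:, None] >> np.arange(k - 1)) & 1).astype(float)
        wl = bits @ sp[1:]
        tl = bits @ tp[1:]
    else:
        rate = tp / sp
        order = np.lexsort((present, rate))  # class rate, code as tie-break
        cw = np.cumsum(sp[order])[:-1]
        ct = np.cumsum(tp[order])[:-1]
        wl, tl = cw, ct
        bits = None
    admissible = (wl >= min_leaf) & (W - wl >= min_leaf)
    if not admissible.any():
        return None
    sigma2 = vh * wl * (W - wl) / (W - 1.0)
    stat = np.where(admissible, (tl - eh * wl) ** 2 / np.maximum(sigma2, _EPS), -np.inf)
    b = int(np.argmax(stat))
    if bits is None:
        rate = tp / sp
        order = np.lexsort((present, rate))
        left = present[order[: b + 1]]
    else:
        sel = bits[b].astype(bool)
        left = present[1:][sel]
    return np.sort(left.astype(np.int64))


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    """A node of a conditional inference tree.

    Internal nodes carry the split (feature index, numeric ``cut`` or
    categorical ``left_codes``), the training proportion of weight sent
    left (``p_left``, used for fractional missing routing during growth
    and, thresholded at 0.5 with ties to the left, for deterministic
    missing routing at prediction), and two children.  Leaves carry the
    weighted class counts and the at-risk proportion.
    """

    # leaf payload
    counts: tuple[float, float] | None = None  # (not_at_risk, at_risk) weights
    proportion: float | None = None
    n_node: float = 0.0
    # split payload
    feature: int | None = None
    kind: str | None = None
    cut: float | None = None
    left_codes: np.ndarray | None = None
    p_left: float | None = None
    p_adj: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def missing_left(self) -> bool:
        return bool(self.p_left is not None and self.p_left >= 0.5)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "counts": [float(c) for c in self.counts],
                "proportion": float(self.proportion),
                "n": float(self.n_node),
            }
        return {
            "leaf": False,
            "feature": int(self.feature),
            "kind": self.kind,
            "cut": None if self.cut is None else float(self.cut),
            "left_codes": None if self.left_codes is None else [int(c) for c in self.left_codes],
            "p_left": float(self.p_left),
            "p_adj": float(self.p_adj),
            "n": float(self.n_node),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(counts=tuple(d["counts"]), proportion=d["proportion"], n_node=d["n"])
        return cls(
            feature=d["feature"],
            kind=d["kind"],
            cut=d["cut"],
            left_codes=None if d["left_codes"] is None else np.array(d["left_codes"], dtype=np.int64),
            p_left=d["p_left"],
            p_adj=d["p_adj"],
            n_node=d["n"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def route_case(node: TreeNode, value: float, training: bool = False):
    """Routing of a single feature value at an internal node.

    Non-missing values go deterministically left (``value <= cut`` /
    code in the left set) or right.  Missing values are sent to *both*
    children with weights proportional to the node's observed split
    proportions during training, and to the heavier child (ties to the
    left) at prediction.  Returns ``{"left": wl, "right": wr}``.
    """
    if node.is_leaf:
        raise ValueError("cannot route at a leaf")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if training:
            return {"left": node.p_left, "right": 1.0 - node.p_left}
        return {"left": 1.0, "right": 0.0} if node.missing_left else {"left": 0.0, "right": 1.0}
    if node.kind == "n":
        go_left = value <= node.cut
    else:
        go_left = int(value) in set(int(c) for c in node.left_codes)
    return {"left": 1.0, "right": 0.0} if go_left else {"left": 0.0, "right": 1.0}


class ConditionalInferenceTree:
    """A single conditional inference tree (grown on a subsample)."""

    def __init__(self, root: TreeNode, config: ForestConfig, n_features: int):
        self.root = root
        self.config = config
        self.n_features = n_features

    # -- growth -----------------------------------------------------------

    @classmethod
    def grow(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        kinds: list[str],
        config: ForestConfig,
        rng: np.random.Generator,
    ) -> "ConditionalInferenceTree":
        n, p = X.shape
        w0 = np.ones(n, dtype=float)
        root = cls._grow_node(X, y, kinds, np.arange(n), w0, config, rng, depth=0)
        return cls(root, config, p)

    @staticmethod
    def _leaf(y: np.ndarray, idx: np.ndarray, w: np.ndarray) -> TreeNode:
        w1 = float((w * y[idx]).sum())
        w_tot = float(w.sum())
        prop = w1 / w_tot if w_tot > 0 else 0.0
        return TreeNode(counts=(w_tot - w1, w1), proportion=prop, n_node=w_tot)

    @classmethod
    def _grow_node(cls, X, y, kinds, idx, w, config, rng, depth) -> TreeNode:
        W = float(w.sum())
        w1 = float((w * y[idx]).sum())
        if (
            W < config.min_split
            or w1 <= _EPS
            or W - w1 <= _EPS
            or (config.max_depth is not None and depth >= config.max_depth)
        ):
            return cls._leaf(y, idx, w)

        p = X.shape[1]
        m = min(config.mtry, p)
        candidates = rng.choice(p, size=m, replace=False)
        Xn = X[idx]
        sel = select_split_variable(Xn, y[idx], candidates, kinds, weights=w, alpha=config.alpha)
        if sel is None:
            return cls._leaf(y, idx, w)
        j, test = sel
        split = best_split_point(
            Xn[:, j], y[idx], weights=w, kind=kinds[j],
            min_leaf=config.min_leaf, exhaustive_cat_max=config.exhaustive_cat_max,
        )
        if split is None:
            return cls._leaf(y, idx, w)

        xj = Xn[:, j]
        miss = np.isnan(xj)
        if kinds[j] == "n":
            go_left = np.zeros(len(xj), dtype=bool)
            go_left[~miss] = xj[~miss] <= split
            cut, left_codes = float(split), None
        else:
            go_left = np.isin(xj, split) & ~miss
            cut, left_codes = None, np.asarray(split, dtype=np.int64)
        wl_obs = float(w[go_left].sum())
        wr_obs = float(w[~miss & ~go_left].sum())
        if wl_obs + wr_obs <= 0:
            return cls._leaf(y, idx, w)
        p_left = wl_obs / (wl_obs + wr_obs)

        li = np.concatenate([idx[go_left], idx[miss]])
        lw = np.concatenate([w[go_left], w[miss] * p_left])
        ri = np.concatenate([idx[~miss & ~go_left], idx[miss]])
        rw = np.concatenate([w[~miss & ~go_left], w[miss] * (1.0 - p_left)])
        keep_l = lw > _EPS
        keep_r = rw > _EPS
        li, lw, ri, rw = li[keep_l], lw[keep_l], ri[keep_r], rw[keep_r]
        if len(li) == 0 or len(ri) == 0:
            return cls._leaf(y, idx, w)

        node = TreeNode(
            feature=int(j), kind=kinds[j], cut=cut, left_codes=left_codes,
            p_left=p_left, p_adj=test.adj_p_value, n_node=W,
        )
        node.left = cls._grow_node(X, y, kinds, li, lw, config, rng, depth + 1)
        node.right = cls._grow_node(X, y, kinds, ri, rw, config, rng, depth + 1)
        return node

    # -- prediction -------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=float)
        if X.shape[0]:
            self._predict_into(self.root, X, np.arange(X.shape[0]), out)
        return out

    @classmethod
    def _predict_into(cls, node: TreeNode, X, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.proportion
            return
        xv = X[idx, node.feature]
        miss = np.isnan(xv)
        if node.kind == "n":
            gl = np.zeros(len(xv), dtype=bool)
            gl[~miss] = xv[~miss] <= node.cut
        else:
            gl = np.isin(xv, node.left_codes) & ~miss
        if node.missing_left:
            gl = gl | miss
        left_idx = idx[gl]
        right_idx = idx[~gl]
        if len(left_idx):
            cls._predict_into(node.left, X, left_idx, out)
        if len(right_idx):
            cls._predict_into(node.right, X, right_idx, out)

    def to_dict(self) -> dict:
        return {"n_features": self.n_features, "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict, config: ForestConfig) -> "ConditionalInferenceTree":
        return cls(TreeNode.from_dict(d["root"]), config, d["n_features"])


class ConditionalInferenceForest:
    """An ensemble of conditional inference trees on subsamples.

    Each tree is grown on ``round(subsample_fraction * n)`` cases drawn
    without replacement; the per-tree subsample index sets are retained
    for out-of-subsample evaluation (permutation importance).  Forest
    probabilities are the plain average of per-tree leaf at-risk
    proportions and are invariant to tree order.
    """

    def __init__(
        self,
        trees: list[ConditionalInferenceTree],
        subsamples: list[np.ndarray],
        config: ForestConfig,
        feature_names: list[str],
        kinds: list[str],
        seed: int | None = None,
    ):
        self.trees = trees
        self.subsamples = subsamples
        self.config = config
        self.feature_names = list(feature_names)
        self.kinds = list(kinds)
        self.seed = seed

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        feature_names: list[str],
        kinds: list[str],
        config: ForestConfig | None = None,
        seed: int = 0,
    ) -> "ConditionalInferenceForest":
        """Grow the forest on labeled cases only.

        ``y`` may contain NaN (unlabeled / Data Deficient species); such
        rows are excluded from training but remain scoreable.
        """
        config = config or ForestConfig()
        config.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        labeled = ~np.isnan(y)
        Xl, yl = X[labeled], y[labeled]
        if len(yl) < 1:
            raise ValueError("no labeled cases to train on")
        n = len(yl)
        m = max(1, int(round(config.subsample_fraction * n)))
        ss = np.random.SeedSequence(seed)
        trees: list[ConditionalInferenceTree] = []
        subsamples: list[np.ndarray] = []
        for child in ss.spawn(config.n_trees):
            rng = np.random.default_rng(child)
            sub = np.sort(rng.choice(n, size=m, replace=False))
            tree = ConditionalInferenceTree.grow(Xl[sub], yl[sub], kinds, config, rng)
            trees.append(tree)
            subsamples.append(sub)
        return cls(trees, subsamples, config, feature_names, kinds, seed=seed)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, X: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        """Mean over trees of leaf at-risk proportions, one value per row."""
        X = np.asarray(X, dtype=float)
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature columns do not match the training dictionary")
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
            )
        acc = np.zeros(X.shape[0], dtype=float)
        for tree in self.trees:
            acc += tree.predict_proba(X)
        return acc / self.n_trees

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "kinds": self.kinds,
            "seed": self.seed,
            "subsamples": [s.tolist() for s in self.subsamples],
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalInferenceForest":
        config = ForestConfig(**d["config"])
        trees = [ConditionalInferenceTree.from_dict(td, config) for td in d["trees"]]
        subsamples = [np.array(s, dtype=np.int64) for s in d["subsamples"]]
        return cls(trees, subsamples, config, d["feature_names"], d["kinds"], seed=d.get("seed"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "ConditionalInferenceForest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def structure_hash(self) -> str:
        """SHA-256 of the serialized forest; equal for identical fits."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
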