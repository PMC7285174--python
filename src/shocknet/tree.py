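"""CART regression tree with surrogate-split predictor importance.

Used to rank hyperparameters by their influence on model accuracy.  The
importance of a predictor accumulates the squared-error impurity improvement
of every node where it provides the primary split, plus a share of the
improvement at nodes where it acts as a *surrogate*: the best split on the
predictor that mimics the primary split's left/right assignment, credited in
proportion to its adjusted agreement

    lambda = (agreement - majority) / (1 - majority),

counted only when positive (the surrogate beats the majority-rule baseline).
Surrogates let collinear predictors (e.g. a parameter count derived from
filter counts and kernel sizes) receive importance even if never chosen for
a primary split.  Final scores are normalized so the maximum is 1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass
class _Node:
    value: float
    split_var: int | None = None
    split_thr: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[float, float]:
    """Best SSE-improvement split ``x <= thr``; returns (gain, thr)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(ys)
    csum = np.cumsum(ys)
    csq = np.cumsum(ys**2)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    # candidate split after position i (1-based count i+1 on the left)
    idx = np.arange(min_leaf - 1, n - min_leaf)
    if len(idx) == 0:
        return 0.0, 0.0
    valid = xs[idx] < xs[idx + 1]  # only between distinct values
    idx = idx[valid]
    if len(idx) == 0:
        return 0.0, 0.0
    nl = idx + 1.0
    nr = n - nl
    sl, ql = csum[idx], csq[idx]
    sse = (ql - sl**2 / nl) + ((csq[-1] - ql) - (csum[-1] - sl) ** 2 / nr)
    best = int(np.argmin(sse))
    gain = float(total_sse - sse[best])
    thr = float((xs[idx[best]] + xs[idx[best] + 1]) / 2.0)
    return max(gain, 0.0), thr


def _best_surrogate_agreement(x: np.ndarray, go_left: np.ndarray) -> float:
    """Max fraction of cases a split on ``x`` can agree with the primary."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gl = go_left[order].astype(np.float64)
    n = len(gl)
    cum_left = np.concatenate(([0.0], np.cumsum(gl)))
    total_left = cum_left[-1]
    pos = np.arange(0, n + 1)
    boundary_ok = np.ones(n + 1, dtype=bool)
    boundary_ok[1:n] = xs[:-1] < xs[1:]  # cannot split between equal values
    # rule "x <= thr -> left": agree = left items at/below cut + right items above
    agree_fwd = cum_left + ((n - pos) - (total_left - cum_left))
    # rule "x <= thr -> right"
    agree_rev = (pos - cum_left) + (total_left - cum_left)
    agree = np.maximum(agree_fwd, agree_rev)
    agree[~boundary_ok] = -1.0
    # exclude degenerate all-one-side cuts (no real split)
    agree[0] = agree[-1] = -1.0
    m = agree.max()
    return float(m / n) if m >= 0 else 0.0


class SurrogateRegressionTree:
    """Squared-error regression tree exposing surrogate-aware importances.

    Parameters mirror common CART controls: ``max_depth`` (default 5),
    ``min_samples_leaf`` (5) and ``min_samples_split`` (10).
    """

    def __init__(self, max_depth: int = 5, min_samples_leaf: int = 5,
                 min_samples_split: int = 10):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurrogateRegressionTree":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n, p = X.shape
        self._raw_importance = np.zeros(p)
        if np.ptp(y) == 0.0:
            warnings.warn("constant response: all importances are zero")
            self.root_ = _Node(value=float(y.mean()) if n else 0.0)
            self.importances_ = self._raw_importance
            return self
        self.root_ = self._grow(X, y, depth=0)
        mx = self._raw_importance.max()
        self.importances_ = self._raw_importance / mx if mx > 0 else self._raw_importance
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _Node:
        node = _Node(value=float(y.mean()))
        n, p = X.shape
        if depth >= self.max_depth or n < self.min_samples_split or np.ptp(y) == 0.0:
            return node
        gains = np.empty(p)
        thrs = np.empty(p)
        for j in range(p):
            gains[j], thrs[j] = _best_split(X[:, j], y, self.min_samples_leaf)
        j_star = int(np.argmax(gains))
        if gains[j_star] <= 0.0:
            return node
        node.split_var = j_star
        node.split_thr = float(thrs[j_star])
        self._raw_importance[j_star] += gains[j_star]

        go_left = X[:, j_star] <= node.split_thr
        frac_left = go_left.mean()
        majority = max(frac_left, 1.0 - frac_left)
        if majority < 1.0:
            for j in range(p):
                if j == j_star:
                    continue
                agree = _best_surrogate_agreement(X[:, j], go_left)
                lam = (agree - majority) / (1.0 - majority)
                if lam > 0.0:
                    self._raw_importance[j] += lam * gains[j_star]

        node.left = self._grow(X[go_left], y[go_left], depth + 1)
        node.right = self._grow(X[~go_left], y[~go_left], depth + 1)
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root_
            while node.split_var is not None:
                node = node.left if row[node.split_var] <= node.split_thr else node.right
            out[i] = node.value
        return out
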