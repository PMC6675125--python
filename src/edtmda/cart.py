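"""From-scratch CART regression tree.

Recursive binary splitting by exact squared-error minimisation: every feature
is scanned, candidate thresholds are the midpoints between consecutive
distinct sorted values, and the (feature, threshold) pair minimising the sum
of child squared errors is chosen. Ties break to the smallest feature index,
then the smallest threshold, so trees are deterministic. Routing sends
``x[j] <= s`` left. Leaves store the mean of the targets routed to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegressionTree", "best_split", "fit_tree", "predict_tree"]

_EPS = 1e-12


def best_split(X: np.ndarray, y: np.ndarray):
    """Exact best squared-error split of (X, y), or None.

    Returns ``(feature, threshold, loss)`` where ``loss`` is the total child
    SSE after the split, or ``None`` when no split strictly reduces the SSE
    (constant targets, or all feature columns constant).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one target per row")
    n, d = X.shape
    if n == 0:
        raise ValueError("cannot split an empty sample")
    if n < 2:
        return None

    order = np.argsort(X, axis=0, kind="stable")          # (n, d)
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]                                          # (n, d)

    s1 = np.cumsum(ys, axis=0)[:-1]                        # left sums, split after row i
    total = y.sum()
    n1 = np.arange(1, n, dtype=float)[:, None]
    n2 = n - n1
    # maximising s1^2/n1 + s2^2/n2 minimises the total child SSE
    gain = s1**2 / n1 + (total - s1) ** 2 / n2
    valid = Xs[:-1] < Xs[1:]
    gain = np.where(valid, gain, -np.inf)
    if not valid.any():
        return None

    # argmax scanning position-major then feature-major would break ties to
    # the smallest threshold but not the smallest feature; transpose so the
    # flat scan is feature-major.
    flat = np.argmax(gain.T)
    j, pos = divmod(flat, n - 1)
    best_gain = gain[pos, j]

    parent_sse = float(((y - y.mean()) ** 2).sum())
    child_sse = float(y @ y - best_gain)
    if parent_sse - child_sse <= _EPS * max(1.0, parent_sse):
        return None
    lo, hi = float(Xs[pos, j]), float(Xs[pos + 1, j])
    threshold = (lo + hi) / 2.0
    if threshold >= hi:  # midpoint rounded up to hi: fall back to lo so both
        threshold = lo   # children stay non-empty under the <= convention
    return int(j), threshold, max(child_sse, 0.0)


@dataclass
class _Node:
    value: float
    n_samples: int
    feature: int = -1           # -1 marks a leaf
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


@dataclass
class RegressionTree:
    """A fitted CART regression tree."""

    root: _Node
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_tree(self, X)

    @property
    def n_leaves(self) -> int:
        def count(node: _Node) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    @property
    def depth(self) -> int:
        def dep(node: _Node) -> int:
            return 0 if node.is_leaf else 1 + max(dep(node.left), dep(node.right))

        return dep(self.root)

    def to_dict(self) -> dict:
        def conv(node: _Node) -> dict:
            if node.is_leaf:
                return {"value": node.value, "n_samples": node.n_samples}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "n_samples": node.n_samples,
                "left": conv(node.left),
                "right": conv(node.right),
            }

        return {"n_features": self.n_features, "root": conv(self.root)}

    @classmethod
    def from_dict(cls, data: dict) -> "RegressionTree":
        def conv(d: dict) -> _Node:
            if "feature" not in d:
                return _Node(value=float(d["value"]), n_samples=int(d["n_samples"]))
            left = conv(d["left"])
            right = conv(d["right"])
            n = int(d["n_samples"])
            value = (left.value * left.n_samples + right.value * right.n_samples) / n
            return _Node(
                value=value,
                n_samples=n,
                feature=int(d["feature"]),
                threshold=float(d["threshold"]),
                left=left,
                right=right,
            )

        return cls(root=conv(data["root"]), n_features=int(data["n_features"]))


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_samples_split: int = 2,
    min_impurity_decrease: float = 0.0,
    max_depth: int | None = None,
) -> RegressionTree:
    """Grow a CART regression tree until no node can be partitioned.

    A node becomes a leaf when it has fewer than ``min_samples_split``
    samples, its targets are constant, the best split reduces the SSE by less
    than ``min_impurity_decrease``, or ``max_depth`` is reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X must be non-empty and 2-D with one target per row")

    def make_node(idx: np.ndarray) -> _Node:
        return _Node(value=float(y[idx].mean()), n_samples=int(idx.size))

    # explicit work stack: trees can grow deeper than the interpreter stack
    root = make_node(np.arange(X.shape[0]))
    stack: list[tuple[_Node, np.ndarray, int]] = [(root, np.arange(X.shape[0]), 0)]
    while stack:
        node, idx, depth = stack.pop()
        yi = y[idx]
        if idx.size < min_samples_split or (max_depth is not None and depth >= max_depth):
            continue
        if np.ptp(yi) == 0.0:
            continue
        found = best_split(X[idx], yi)
        if found is None:
            continue
        j, s, child_sse = found
        parent_sse = float(((yi - yi.mean()) ** 2).sum())
        if parent_sse - child_sse < min_impurity_decrease:
            continue
        mask = X[idx, j] <= s
        node.feature = j
        node.threshold = s
        node.left = make_node(idx[mask])
        node.right = make_node(idx[~mask])
        stack.append((node.left, idx[mask], depth + 1))
        stack.append((node.right, idx[~mask], depth + 1))

    return RegressionTree(root=root, n_features=X.shape[1])


def predict_tree(tree: RegressionTree, X: np.ndarray) -> np.ndarray:
    """Route every row of X to its leaf and return the leaf means."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != tree.n_features:
        raise ValueError(f"expected {tree.n_features} features, got {X.shape[1]}")
    out = np.empty(X.shape[0])
    stack: list[tuple[_Node, np.ndarray]] = [(tree.root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            out[idx] = node.value
            continue
        mask = X[idx, node.feature] <= node.threshold
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return out
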