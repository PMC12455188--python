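"""Re-training of the interaction classifiers.

Mirrors the original analysis workflow: a PCA on the standardized
explanatory variables (reporting only), removal of highly correlated
variables, a stratified 80/20 split, and a depth-limited classification
tree (CART, Gini impurity) with the depth tuned among 1..5.

The tree learner is written out in full rather than delegated, because
its conventions are pinned by tests and by the serialized model format:
candidate thresholds at midpoints between consecutive sorted unique
values, "value <= threshold goes left", ties broken toward the
first-listed feature and the smallest threshold, stopping on depth,
purity or a minimum leaf size.  scikit-learn's tree serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PCASummary",
    "pca_summary",
    "correlation_screen",
    "stratified_split",
    "TreeNode",
    "TrainedTree",
    "fit_tree",
    "predict",
    "tune_depth",
    "save_tree",
    "load_tree",
]


# ---------------------------------------------------------------------------
# Variable screening


@dataclass(frozen=True)
class PCASummary:
    """One principal component of the correlation matrix.

    ``loadings`` are correlations between the original (standardized)
    variables and the component, i.e. eigenvector * sqrt(eigenvalue).
    """

    component: int
    explained_variance_fraction: float
    loadings: dict[str, float]


def pca_summary(table: pd.DataFrame, features: Sequence[str]) -> list[PCASummary]:
    """PCA on standardized variables (correlation-matrix eigendecomposition)."""
    if len(table) < 2:
        raise ValueError("pca_summary requires at least 2 rows")
    X = table[list(features)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = [f for f, s in zip(features, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    total = eigval.sum()
    out = []
    for k in range(len(features)):
        load = eigvec[:, k] * np.sqrt(eigval[k])
        # sign convention: largest-magnitude loading positive
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        out.append(PCASummary(
            component=k + 1,
            explained_variance_fraction=float(eigval[k] / total),
            loadings={f: float(v) for f, v in zip(features, load)},
        ))
    return out


def correlation_screen(table: pd.DataFrame, keep_priority: Sequence[str],
                       r_threshold: float = 0.8):
    """Greedy collinearity filter in priority order.

    Walks ``keep_priority``; a feature is dropped when its |Pearson r|
    with any already-kept feature reaches ``r_threshold``.  Returns the
    kept list and a drop log of (dropped, kept_culprit, r).
    """
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for feat in keep_priority:
        x = table[feat].to_numpy(dtype=float)
        culprit = None
        for other in kept:
            r = float(np.corrcoef(x, table[other].to_numpy(dtype=float))[0, 1])
            if abs(r) >= r_threshold:
                culprit = (other, r)
                break
        if culprit is None:
            kept.append(feat)
        else:
            dropped.append((feat, culprit[0], culprit[1]))
    return kept, dropped


# ---------------------------------------------------------------------------
# Splitting


def stratified_split(table: pd.DataFrame, target: str,
                     train_fraction: float = 0.8, seed: int = 0):
    """Class-stratified train/test partition.

    Each class contributes round(train_fraction * n_class) rows to the
    training set.  Deterministic for a fixed seed; the split is
    disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls, grp in table.groupby(target, sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"class {cls!r} has {n} row(s); need >= 2 to stratify")
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # both sides non-empty per class
        perm = rng.permutation(n)
        idx = grp.index.to_numpy()
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return table.loc[train_idx], table.loc[test_idx]


# ---------------------------------------------------------------------------
# CART


@dataclass(frozen=True)
class TreeNode:
    """Internal node (feature/threshold with two children) or leaf."""

    counts: dict[str, int]
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass(frozen=True)
class TrainedTree:
    root: TreeNode
    features: tuple[str, ...]
    target: str
    max_depth: int
    min_leaf: int
    metadata: dict = field(default_factory=dict)

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
               min_leaf: int = 1):
    """Exhaustive search for the best Gini split of one node.

    Candidate thresholds are midpoints between consecutive sorted
    unique values of each feature.  Returns (feature_index, threshold,
    impurity_decrease) or None when no split is valid.  Ties go to the
    first feature and the smallest threshold.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best = None  # (decrease, j, threshold)
    eps = 1e-12
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        left = np.zeros(n_classes, dtype=np.int64)
        right = parent_counts.astype(np.int64).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            child = (n_left * _gini(left) + n_right * _gini(right)) / n
            decrease = parent_gini - child
            thr = (xs[i] + xs[i + 1]) / 2.0
            if decrease <= eps:
                continue
            if best is None or decrease > best[0] + eps:
                best = (decrease, j, thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


def fit_tree(train: pd.DataFrame, features: Sequence[str], target: str,
             max_depth: int = 3, min_leaf: int = 5, seed: int = 0) -> TrainedTree:
    """Greedy binary recursive partitioning with the Gini criterion.

    Stops on ``max_depth``, node purity, or when no split leaves both
    children with at least ``min_leaf`` rows.  Leaf labels are the
    majority class (ties toward the lexicographically first class).
    ``seed`` only enters the fitted metadata: the learner itself is
    deterministic.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    feats = list(features)
    X = train[feats].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature columns contain missing values")
    classes = sorted(train[target].astype(str).unique())
    class_index = {c: i for i, c in enumerate(classes)}
    y = train[target].astype(str).map(class_index).to_numpy()

    def counts_dict(yy: np.ndarray) -> dict[str, int]:
        bc = np.bincount(yy, minlength=len(classes))
        return {c: int(bc[class_index[c]]) for c in classes}

    def majority(yy: np.ndarray) -> str:
        bc = np.bincount(yy, minlength=len(classes))
        return classes[int(np.argmax(bc))]  # argmax -> first (lexicographic) tie

    def build(XX: np.ndarray, yy: np.ndarray, depth: int) -> TreeNode:
        cd = counts_dict(yy)
        if depth >= max_depth or len(np.unique(yy)) == 1:
            return TreeNode(counts=cd, label=majority(yy))
        split = best_split(XX, yy, len(classes), min_leaf=min_leaf)
        if split is None:
            return TreeNode(counts=cd, label=majority(yy))
        j, thr, _ = split
        mask = XX[:, j] <= thr
        return TreeNode(
            counts=cd,
            feature=feats[j],
            threshold=float(thr),
            left=build(XX[mask], yy[mask], depth + 1),
            right=build(XX[~mask], yy[~mask], depth + 1),
        )

    root = build(X, y, 0)
    return TrainedTree(
        root=root, features=tuple(feats), target=target,
        max_depth=max_depth, min_leaf=min_leaf,
        metadata={"seed": seed, "n_train": int(len(train)), "classes": classes},
    )


def predict(tree: TrainedTree, rows) -> list[str] | str:
    """Route rows down the tree; values equal to a threshold go left."""
    single = isinstance(rows, Mapping)
    iterable = [rows] if single else rows
    if isinstance(iterable, pd.DataFrame):
        iterable = iterable.to_dict("records")
    out = []
    for row in iterable:
        node = tree.root
        while not node.is_leaf:
            if node.feature not in row:
                raise KeyError(f"row lacks feature {node.feature!r}")
            node = node.left if row[node.feature] <= node.threshold else node.right
        out.append(node.label)
    return out[0] if single else out


def tune_depth(table: pd.DataFrame, features: Sequence[str], target: str,
               depths: Iterable[int] = range(1, 6), min_leaf: int = 5,
               train_fraction: float = 0.8, seed: int = 0):
    """Fit one tree per depth on a common split; pick the best test accuracy.

    Ties are resolved toward the smallest depth.  Returns
    (best_depth, {depth: test_accuracy}).
    """
    train, test = stratified_split(table, target, train_fraction, seed)
    truth = test[target].astype(str).tolist()
    report: dict[int, float] = {}
    for d in depths:
        tree = fit_tree(train, features, target, max_depth=d,
                        min_leaf=min_leaf, seed=seed)
        pred = predict(tree, test)
        report[d] = sum(p == t for p, t in zip(pred, truth)) / len(truth)
    best = max(sorted(report), key=lambda d: report[d])  # ties -> smallest depth
    return best, report


# ---------------------------------------------------------------------------
# Model files


def _node_to_obj(node: TreeNode):
    if node.is_leaf:
        return {"leaf": node.label, "counts": node.counts}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "counts": node.counts,
        "left": _node_to_obj(node.left),
        "right": _node_to_obj(node.right),
    }


def _obj_to_node(obj) -> TreeNode:
    if "leaf" in obj:
        return TreeNode(counts=dict(obj["counts"]), label=obj["leaf"])
    return TreeNode(
        counts=dict(obj["counts"]),
        feature=obj["feature"],
        threshold=float(obj["threshold"]),
        left=_obj_to_node(obj["left"]),
        right=_obj_to_node(obj["right"]),
    )


def save_tree(tree: TrainedTree, path) -> None:
    """Serialize a trained tree as a human-readable YAML model file."""
    doc = {
        "model": "sow-interact classification tree",
        "target": tree.target,
        "features": list(tree.features),
        "max_depth": tree.max_depth,
        "min_leaf": tree.min_leaf,
        "metadata": tree.metadata,
        "tree": _node_to_obj(tree.root),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_tree(path) -> TrainedTree:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return TrainedTree(
        root=_obj_to_node(doc["tree"]),
        features=tuple(doc["features"]),
        target=doc["target"],
        max_depth=int(doc["max_depth"]),
        min_leaf=int(doc["min_leaf"]),
        metadata=dict(doc.get("metadata", {})),
    )
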