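"""Retraining machinery: PCA, screening, splitting, CART, depth tuning."""

import numpy as np
import pandas as pd
import pytest

from sow_interact import cart


def _table(cols: dict, target=None) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    if target is not None:
        df["y"] = target
    return df


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_features_is_rank_one():
    rng = np.random.default_rng(0)
    a = rng.normal(size=200)
    comps = cart.pca_summary(_table({"a": a, "b": a.copy()}), ["a", "b"])
    assert comps[0].explained_variance_fraction == pytest.approx(1.0, abs=1e-9)
    assert comps[1].explained_variance_fraction == pytest.approx(0.0, abs=1e-9)


def test_pca_single_feature():
    rng = np.random.default_rng(1)
    comps = cart.pca_summary(_table({"a": rng.normal(size=50)}), ["a"])
    assert len(comps) == 1
    assert comps[0].explained_variance_fraction == pytest.approx(1.0)


def test_pca_independent_features_split_variance():
    rng = np.random.default_rng(2)
    df = _table({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
    comps = cart.pca_summary(df, ["a", "b"])
    for c in comps:
        assert 0.45 <= c.explained_variance_fraction <= 0.55


def test_pca_fractions_sum_to_one_and_loadings_bounded(default_features):
    feats = ["avg_d_nose1_nose2", "avg_d_nose2_tail1",
             "d_evolution_nose1_nose2", "speed_nose1_nose2",
             "d_travelled_sow1"]
    sub = default_features[default_features.period == "before"]
    comps = cart.pca_summary(sub, feats)
    total = sum(c.explained_variance_fraction for c in comps)
    assert total == pytest.approx(1.0, abs=1e-9)
    fracs = [c.explained_variance_fraction for c in comps]
    assert fracs == sorted(fracs, reverse=True)
    for c in comps:
        for v in c.loadings.values():
            assert abs(v) <= 1.0 + 1e-9


def test_pca_zero_variance_feature_rejected():
    df = _table({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="zero-variance"):
        cart.pca_summary(df, ["a", "b"])


def test_pca_loadings_match_sklearn():
    """Explained variance fractions agree with sklearn PCA on z-scores."""
    sklearn = pytest.importorskip("sklearn")
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(5)
    base = rng.normal(size=(300, 1))
    X = np.hstack([base + 0.5 * rng.normal(size=(300, 1)) for _ in range(4)])
    df = _table({f"f{i}": X[:, i] for i in range(4)})
    feats = list(df.columns)
    comps = cart.pca_summary(df, feats)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    ref = PCA().fit(Z)
    frac_ref = ref.explained_variance_ratio_
    for mine, theirs in zip(comps, frac_ref):
        assert mine.explained_variance_fraction == pytest.approx(theirs, abs=1e-6)


# ---------------------------------------------------------------------------
# Correlation screening


def test_screen_drops_perfect_collinearity():
    rng = np.random.default_rng(3)
    a = rng.normal(size=100)
    c = rng.normal(size=100)
    df = _table({"a": a, "b": a.copy(), "c": c})
    kept, dropped = cart.correlation_screen(df, ["a", "b", "c"], 0.8)
    assert kept == ["a", "c"]
    assert dropped[0][0] == "b" and dropped[0][1] == "a"


def test_screen_threshold_above_one_keeps_all():
    rng = np.random.default_rng(4)
    df = _table({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    kept, dropped = cart.correlation_screen(df, ["a", "b"], 1.1)
    assert kept == ["a", "b"] and dropped == []


def test_screen_greedy_chain():
    """a~b and b~c strongly, a~c moderately: the greedy pass keeps {a, c}."""
    rng = np.random.default_rng(6)
    n = 20_000
    cov = np.array([[1.0, 0.90, 0.80],
                    [0.90, 1.0, 0.90],
                    [0.80, 0.90, 1.0]])
    X = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    df = _table({"a": X[:, 0], "b": X[:, 1], "c": X[:, 2]})
    # sanity: empirical correlations on the intended sides of 0.85
    r = np.corrcoef(X, rowvar=False)
    assert r[0, 1] > 0.85 and r[1, 2] > 0.85 and r[0, 2] < 0.85
    kept, dropped = cart.correlation_screen(df, ["a", "b", "c"], 0.85)
    assert kept == ["a", "c"]
    assert [d[0] for d in dropped] == ["b"]


# ---------------------------------------------------------------------------
# Stratified split


def test_stratified_split_class_arithmetic():
    df = _table({"x": np.arange(240.0)}, target=["i"] * 120 + ["n"] * 120)
    train, test = cart.stratified_split(df, "y", 0.8, seed=7)
    assert train.y.value_counts().to_dict() == {"i": 96, "n": 96}
    assert test.y.value_counts().to_dict() == {"i": 24, "n": 24}
    assert set(train.index).isdisjoint(test.index)
    assert len(train) + len(test) == 240


def test_stratified_split_deterministic():
    df = _table({"x": np.arange(50.0)}, target=["a", "b"] * 25)
    t1, s1 = cart.stratified_split(df, "y", 0.8, seed=11)
    t2, s2 = cart.stratified_split(df, "y", 0.8, seed=11)
    assert list(t1.index) == list(t2.index)
    assert list(s1.index) == list(s2.index)


def test_stratified_split_rejects_degenerate_inputs():
    df = _table({"x": [1.0, 2.0, 3.0]}, target=["a", "a", "b"])
    with pytest.raises(ValueError):
        cart.stratified_split(df, "y", 1.0, seed=0)
    with pytest.raises(ValueError):
        cart.stratified_split(df, "y", 0.8, seed=0)  # class b has 1 row


# ---------------------------------------------------------------------------
# CART fitting


def test_depth_one_separable():
    df = _table({"x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]},
                target=["A", "A", "A", "B", "B", "B"])
    tree = cart.fit_tree(df, ["x"], "y", max_depth=3, min_leaf=1)
    assert tree.root.feature == "x"
    assert tree.root.threshold == pytest.approx(0.5)
    assert tree.depth() == 1
    assert cart.predict(tree, df) == list(df.y)


def test_pure_node_is_single_leaf():
    df = _table({"x": [0.0, 1.0, 2.0]}, target=["A", "A", "A"])
    tree = cart.fit_tree(df, ["x"], "y", min_leaf=1)
    assert tree.root.is_leaf and tree.root.label == "A"


def test_constant_features_give_single_leaf():
    df = _table({"x": [1.0] * 6}, target=["A", "B"] * 3)
    tree = cart.fit_tree(df, ["x"], "y", min_leaf=1)
    assert tree.root.is_leaf


def test_xor_not_separable_at_depth_one():
    df = _table({"x1": [0.0, 0.0, 1.0, 1.0] * 5, "x2": [0.0, 1.0, 0.0, 1.0] * 5},
                target=["A", "B", "B", "A"] * 5)
    tree = cart.fit_tree(df, ["x1", "x2"], "y", max_depth=1, min_leaf=1)
    pred = cart.predict(tree, df)
    acc = np.mean([p == t for p, t in zip(pred, df.y)])
    assert acc <= 0.75
    # on perfectly balanced XOR no single split reduces Gini impurity at
    # all, so greedy CART stops at the root regardless of depth
    deep = cart.fit_tree(df, ["x1", "x2"], "y", max_depth=3, min_leaf=1)
    assert deep.root.is_leaf


def test_value_at_threshold_routes_left():
    df = _table({"x": [0.0, 0.0, 1.0, 1.0]}, target=["A", "A", "B", "B"])
    tree = cart.fit_tree(df, ["x"], "y", min_leaf=1)
    assert cart.predict(tree, {"x": tree.root.threshold}) == "A"
    assert cart.predict(tree, {"x": tree.root.threshold + 1e-9}) == "B"


def test_child_counts_sum_to_parent(default_features):
    sub = default_features[default_features.period == "before"]
    feats = ["d_evolution_nose1_nose2", "avg_d_nose1_nose2", "prop_any_standing"]
    tree = cart.fit_tree(sub, feats, "situation", max_depth=3)

    def walk(node):
        if node.is_leaf:
            return
        for cls in node.counts:
            assert node.counts[cls] == node.left.counts[cls] + node.right.counts[cls]
        walk(node.left)
        walk(node.right)

    walk(tree.root)


def test_training_predictions_match_leaf_majorities():
    rng = np.random.default_rng(8)
    df = _table({"x": rng.normal(size=60), "z": rng.normal(size=60)},
                target=list(rng.choice(["A", "B"], size=60)))
    tree = cart.fit_tree(df, ["x", "z"], "y", max_depth=3, min_leaf=5)
    # every training row lands in a leaf whose stored majority equals the
    # prediction, and routed label counts recompute the stored leaf counts
    from collections import Counter

    leaves: dict[int, tuple[object, Counter]] = {}
    for row, label in zip(df.to_dict("records"), df.y):
        node = tree.root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        leaves.setdefault(id(node), (node, Counter()))[1][label] += 1
        assert cart.predict(tree, row) == node.label
    for node, counter in leaves.values():
        stored = {c: n for c, n in node.counts.items() if n > 0}
        assert stored == dict(counter)


def test_root_split_matches_sklearn():
    """Root impurity decrease agrees with scikit-learn's CART."""
    sklearn = pytest.importorskip("sklearn")
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(9)
    for trial in range(20):
        n = int(rng.integers(10, 40))
        X = rng.normal(size=(n, 2))
        y = rng.choice(["A", "B"], size=n)
        if len(set(y)) < 2:
            continue
        df = _table({"f0": X[:, 0], "f1": X[:, 1]}, target=list(y))
        split = cart.best_split(X, (y == "B").astype(int), 2, min_leaf=1)
        ref = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        if split is None:
            continue
        j, thr, dec = split
        ref_j = ref.tree_.feature[0]
        n_node = ref.tree_.n_node_samples
        imp = ref.tree_.impurity
        ref_dec = imp[0] - (n_node[1] * imp[1] + n_node[2] * imp[2]) / n_node[0]
        assert dec == pytest.approx(ref_dec, abs=1e-9)


def test_save_load_round_trip(tmp_path, default_features):
    sub = default_features[default_features.period == "before"]
    feats = ["d_evolution_nose1_nose2", "avg_d_nose1_nose2", "prop_any_standing"]
    tree = cart.fit_tree(sub, feats, "situation", max_depth=3)
    path = tmp_path / "model.yaml"
    cart.save_tree(tree, path)
    back = cart.load_tree(path)
    rows = sub.to_dict("records")
    assert cart.predict(back, rows) == cart.predict(tree, rows)


# ---------------------------------------------------------------------------
# Depth tuning


def test_tune_depth_prefers_smallest_on_ties():
    rng = np.random.default_rng(10)
    x = np.concatenate([rng.uniform(-1, -0.1, 60), rng.uniform(0.1, 1, 60)])
    df = _table({"x": x}, target=["A"] * 60 + ["B"] * 60)
    best, report = cart.tune_depth(df, ["x"], "y", seed=0)
    assert best == 1
    assert len(report) == 5
    assert report[1] == 1.0


def test_tune_depth_on_noise_hovers_at_chance():
    rng = np.random.default_rng(12)
    df = _table({"x": rng.normal(size=400), "z": rng.normal(size=400)},
                target=list(rng.choice(["A", "B"], size=400)))
    best, report = cart.tune_depth(df, ["x", "z"], "y", seed=0)
    for acc in report.values():
        assert 0.3 <= acc <= 0.7
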