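import numpy as np
import pandas as pd
import pytest

from gliosurv.cohort import GeneratorConfig, generate_cohort
from gliosurv.geometry import QUANTITATIVE_VARIABLES
from gliosurv.trees import (
    TreeControl,
    evaluate_tree,
    grow_tree,
    prune_tree,
    run_tree_battery,
    split_cohort,
)


def _frame(n, rng, rule=None):
    df = pd.DataFrame({
        "x": rng.uniform(0, 10, n),
        "y": rng.uniform(0, 10, n),
    })
    if rule is None:
        df["label"] = rng.choice(["a", "b"], n)
    else:
        df["label"] = np.where(rule(df), "a", "b")
    return df


def test_split_cohort_sizes_and_determinism():
    rng = np.random.default_rng(0)
    df = _frame(100, rng)
    tr1, te1 = split_cohort(df, "label", 0.7, seed=5)
    tr2, te2 = split_cohort(df, "label", 0.7, seed=5)
    assert len(tr1) == 70 and len(te1) == 30
    assert list(tr1.index) == list(tr2.index)
    # stratification: per-class proportions differ by at most one subject
    for cls in ("a", "b"):
        expected = 0.7 * (df["label"] == cls).sum()
        assert abs((tr1["label"] == cls).sum() - expected) <= 1


def test_split_cohort_rejects_bad_fraction():
    df = _frame(20, np.random.default_rng(1))
    with pytest.raises(ValueError):
        split_cohort(df, "label", 1.5)


def test_perfectly_separable_gives_depth_one_tree():
    rng = np.random.default_rng(2)
    df = _frame(200, rng, rule=lambda d: d["x"] > 5.0)
    tree = grow_tree(df, "label", ["x", "y"])
    assert tree.depth == 1
    assert tree.root.variable == "x"
    gap = np.sort(df["x"].to_numpy())
    below, above = gap[gap <= 5].max(), gap[gap > 5].min()
    assert below < tree.root.threshold < above
    assert (tree.predict(df) == df["label"]).all()


def test_pure_class_gives_single_leaf():
    rng = np.random.default_rng(3)
    df = _frame(50, rng)
    df["label"] = "a"
    tree = grow_tree(df, "label", ["x", "y"])
    assert tree.root.is_leaf and tree.root.predicted == "a"


def test_gini_split_matches_exhaustive_search():
    """The root split agrees with a brute-force scan of every midpoint
    threshold on every variable (<= 50-point sample)."""
    rng = np.random.default_rng(4)
    df = _frame(50, rng, rule=lambda d: (d["x"] + rng.normal(0, 2.0, len(d))) > 5)
    tree = grow_tree(df, "label", ["x", "y"], TreeControl(minsplit=2, minbucket=1))

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.mean(labels == "a")
        return 2 * p * (1 - p)

    y = df["label"].to_numpy()
    best = (np.inf, None, None)
    for var in ("x", "y"):
        v = df[var].to_numpy()
        for thr in (np.sort(np.unique(v))[1:] + np.sort(np.unique(v))[:-1]) / 2:
            left = v <= thr
            w = left.mean() * gini(y[left]) + (1 - left.mean()) * gini(y[~left])
            if w < best[0] - 1e-12:
                best = (w, var, thr)
    assert tree.root.variable == best[1]
    # sklearn stores thresholds in float32, hence the loose tolerance
    assert tree.root.threshold == pytest.approx(best[2], abs=1e-5)


def test_noise_tree_prunes_toward_root():
    """Trees grown on pure label noise are pruned to (near-)root in most
    replicates by cross-validated cost-complexity pruning."""
    near_root = 0
    n_rep = 30
    grown_leaves, pruned_leaves = [], []
    for seed in range(n_rep):
        rng = np.random.default_rng(100 + seed)
        df = _frame(200, rng)  # labels independent of x, y
        grown = grow_tree(df, "label", ["x", "y"])
        pruned = prune_tree(grown, df, "label", seed=seed)
        near_root += pruned.n_leaves <= 3
        grown_leaves.append(grown.n_leaves)
        pruned_leaves.append(pruned.n_leaves)
    assert near_root / n_rep >= 0.7
    assert np.mean(pruned_leaves) < 0.25 * np.mean(grown_leaves)


def test_planted_rule_survives_pruning():
    rng = np.random.default_rng(6)
    df = _frame(300, rng, rule=lambda d: (d["x"] + rng.normal(0, 1.0, len(d))) > 5)
    grown = grow_tree(df, "label", ["x", "y"])
    pruned = prune_tree(grown, df, "label", seed=0)
    assert not pruned.root.is_leaf
    assert pruned.root.variable == "x"
    assert pruned.root.threshold == pytest.approx(5.0, abs=1.0)


def test_pruning_rejects_single_fold():
    rng = np.random.default_rng(7)
    df = _frame(100, rng)
    tree = grow_tree(df, "label", ["x", "y"])
    with pytest.raises(ValueError):
        prune_tree(tree, df, "label", TreeControl(cv_folds=1))


def test_training_accuracy_monotone_under_pruning():
    rng = np.random.default_rng(8)
    df = _frame(300, rng, rule=lambda d: (d["x"] + rng.normal(0, 3.0, len(d))) > 5)
    grown = grow_tree(df, "label", ["x", "y"], TreeControl(minsplit=5, minbucket=2))
    path = grown.estimator.cost_complexity_pruning_path(
        df[["x", "y"]].to_numpy(), df["label"].to_numpy()
    )
    accs = []
    for alpha in np.unique(np.clip(path.ccp_alphas, 0, None)):
        t = grow_tree(df, "label", ["x", "y"], TreeControl(minsplit=5, minbucket=2),
                      ccp_alpha=float(alpha))
        accs.append((t.predict(df) == df["label"]).mean())
    assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(accs, accs[1:]))


def test_evaluate_tree_arithmetic():
    rng = np.random.default_rng(9)
    train = _frame(100, rng, rule=lambda d: d["x"] > 5)
    test = _frame(40, rng, rule=lambda d: d["x"] > 5)
    tree = grow_tree(train, "label", ["x", "y"])
    ev = evaluate_tree(tree, train, test, "label", positive_class="a")
    assert ev.accuracy_train == 1.0 and ev.sensitivity_train == 1.0
    # full-cohort accuracy is the count-weighted combination
    expected_full = (100 * ev.accuracy_train + 40 * ev.accuracy_test) / 140
    assert ev.accuracy_full == pytest.approx(expected_full)


def test_majority_stump_metrics():
    df = pd.DataFrame({
        "x": np.arange(10, dtype=float),
        "label": ["pos"] * 1 + ["neg"] * 9,
    })
    tree = grow_tree(df, "label", ["x"])  # minsplit prevents splitting
    ev = evaluate_tree(tree, df, df.tail(2), "label", positive_class="pos")
    assert tree.root.is_leaf
    assert ev.accuracy_train == pytest.approx(0.9)
    assert ev.sensitivity_train == 0.0


def test_sensitivity_undefined_without_positives():
    rng = np.random.default_rng(10)
    train = _frame(60, rng, rule=lambda d: d["x"] > 5)
    test = train[train["label"] == "b"]
    tree = grow_tree(train, "label", ["x", "y"])
    ev = evaluate_tree(tree, train, test, "label", positive_class="a")
    assert ev.sensitivity_test is None


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = GeneratorConfig(
        n=600, seed=42,
        planted_effects={"age_years": {"STS": 12.0, "EXS": -12.0},
                         "pihna_rho": {"EXS": -10.0}},
    )
    return generate_cohort(cfg)


def test_battery_produces_six_trees(planted_cohort):
    battery = run_tree_battery(planted_cohort, seed=1)
    assert len(battery) == 6
    assert set(k[0] for k in battery) == {"male", "female"}
    for entry in battery.values():
        assert entry["tree"].feature_names == list(QUANTITATIVE_VARIABLES)


def test_battery_exs_sts_trees_use_only_those_groups(planted_cohort):
    battery = run_tree_battery(planted_cohort, seed=1)
    for sex in ("male", "female"):
        sub = planted_cohort[planted_cohort["sex"] == sex]
        n_exs_sts = int(sub["survival_group"].isin(["EXS", "STS"]).sum())
        entry = battery[(sex, "EXS_vs_STS")]
        assert entry["n_train"] + entry["n_test"] == n_exs_sts


def test_battery_reproducible(planted_cohort):
    b1 = run_tree_battery(planted_cohort, seed=9)
    b2 = run_tree_battery(planted_cohort, seed=9)
    for key in b1:
        assert b1[key]["tree"].to_dict() == b2[key]["tree"].to_dict()
        assert b1[key]["evaluation"] == b2[key]["evaluation"]


def test_tree_rendering_shows_concentrations(planted_cohort):
    battery = run_tree_battery(planted_cohort, seed=1)
    text = battery[("male", "STS_vs_NonSTS")]["tree"].render()
    assert "%" in text and "n=" in text
    d = battery[("male", "STS_vs_NonSTS")]["tree"].to_dict()
    assert abs(sum(d["concentrations"].values()) - 1.0) < 1e-9


def test_tree_path_thresholds_consistent(planted_cohort):
    """Along any root-to-leaf path, thresholds on one variable define a
    non-empty interval."""
    battery = run_tree_battery(planted_cohort, seed=1)

    def walk(node, lo, hi):
        if node.is_leaf:
            return
        v, t = node.variable, node.threshold
        l = dict(lo); h = dict(hi)
        assert lo.get(v, -np.inf) < t < hi.get(v, np.inf)
        h2 = dict(hi); h2[v] = min(hi.get(v, np.inf), t)
        walk(node.left, lo, h2)
        l2 = dict(lo); l2[v] = max(lo.get(v, -np.inf), t)
        walk(node.right, l2, hi)

    for entry in battery.values():
        walk(entry["tree"].root, {}, {})
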