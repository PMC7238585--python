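"""CART survival-group classification trees.

Six trees in total: for each sex, one binary tree per survival-group
contrast (extreme vs non-extreme, extreme vs short-term, short-term vs
non-short-term), grown on the eight quantitative pre-treatment variables
with greedy Gini partitioning, then pruned by cost-complexity with
10-fold cross-validation and the one-standard-error rule.  The cohort is
split 70/30 into training and testing, stratified by outcome; accuracy
and sensitivity (extreme and short-term survivors are condition positive)
are reported for training, testing and the full cohort.

scikit-learn's CART implementation provides the partitioning and the
pruning path; this module wraps it in a survival-group-aware structure
exposing node thresholds and per-node class concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .geometry import QUANTITATIVE_VARIABLES

logger = logging.getLogger("gliosurv")


@dataclass
class TreeControl:
    """Growth and pruning controls (recursive-partitioning tradition defaults)."""

    minsplit: int = 20
    minbucket: int = 7
    max_depth: int = 30
    cv_folds: int = 10
    one_se: bool = True


@dataclass
class TreeNode:
    """One node: an internal Gini split or a leaf with class concentrations."""

    n: int
    concentrations: dict[str, float]
    predicted: str
    variable: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # variable <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class DecisionTree:
    """A fitted survival-group tree with its sklearn estimator and structure."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]
    root: TreeNode

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.feature_names].to_numpy())

    @property
    def n_leaves(self) -> int:
        return int(self.estimator.get_n_leaves())

    @property
    def depth(self) -> int:
        return int(self.estimator.get_depth())

    def to_dict(self) -> dict:
        """Machine-readable nested structure."""

        def rec(node: TreeNode) -> dict:
            d = {
                "n": node.n,
                "concentrations": node.concentrations,
                "predicted": node.predicted,
            }
            if not node.is_leaf:
                d.update(
                    variable=node.variable,
                    threshold=node.threshold,
                    left=rec(node.left),
                    right=rec(node.right),
                )
            return d

        return rec(self.root)

    def render(self) -> str:
        """Indented text rendering with per-node class concentrations."""
        lines: list[str] = []

        def rec(node: TreeNode, indent: int, label: str) -> None:
            conc = ", ".join(
                f"{k}: {100 * v:.0f}%" for k, v in node.concentrations.items()
            )
            head = f"{'  ' * indent}{label}n={node.n} [{conc}] -> {node.predicted}"
            lines.append(head)
            if not node.is_leaf:
                rec(node.left, indent + 1, f"{node.variable} <= {node.threshold:.4g}: ")
                rec(node.right, indent + 1, f"{node.variable} > {node.threshold:.4g}: ")

        rec(self.root, 0, "")
        return "\n".join(lines)


@dataclass
class TreeEvaluation:
    """Accuracy and sensitivity on the training, testing and full cohorts."""

    accuracy_train: float
    accuracy_test: float
    accuracy_full: float
    sensitivity_train: float | None
    sensitivity_test: float | None
    sensitivity_full: float | None


def split_cohort(
    records: pd.DataFrame, outcome: str, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split, deterministic given the seed."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    y = records[outcome]
    stratify = y
    if y.value_counts().min() < 2:
        logger.warning("a class has < 2 members; stratification degraded to random split")
        stratify = None
    train, test = train_test_split(
        records, train_size=train_frac, random_state=seed, stratify=stratify
    )
    return train, test


def _build_structure(est: DecisionTreeClassifier, feature_names, classes) -> TreeNode:
    t = est.tree_

    def rec(i: int) -> TreeNode:
        counts = t.value[i][0] * t.weighted_n_node_samples[i] / max(t.value[i][0].sum(), 1e-300)
        n = int(round(t.weighted_n_node_samples[i]))
        frac = t.value[i][0] / max(t.value[i][0].sum(), 1e-300)
        conc = {classes[k]: float(frac[k]) for k in range(len(classes))}
        predicted = classes[int(np.argmax(frac))]
        if t.children_left[i] == -1:
            return TreeNode(n=n, concentrations=conc, predicted=predicted)
        return TreeNode(
            n=n, concentrations=conc, predicted=predicted,
            variable=feature_names[t.feature[i]],
            threshold=float(t.threshold[i]),
            left=rec(t.children_left[i]),
            right=rec(t.children_right[i]),
        )

    return rec(0)


def grow_tree(
    train: pd.DataFrame,
    outcome: str,
    predictors=QUANTITATIVE_VARIABLES,
    control: TreeControl | None = None,
    ccp_alpha: float = 0.0,
) -> DecisionTree:
    """Greedy binary Gini partitioning with minsplit/minbucket/depth stops.

    Split thresholds fall at midpoints of adjacent observed values.  If no
    admissible split exists the tree is a single majority-class leaf.
    """
    control = control or TreeControl()
    predictors = list(predictors)
    if len(train) < 1:
        raise ValueError("empty training set")
    X = train[predictors].to_numpy()
    y = train[outcome].to_numpy()
    est = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=control.minsplit,
        min_samples_leaf=control.minbucket,
        max_depth=control.max_depth,
        random_state=0,
        ccp_alpha=ccp_alpha,
    )
    est.fit(X, y)
    classes = [str(c) for c in est.classes_]
    return DecisionTree(
        estimator=est, feature_names=predictors, classes=classes,
        root=_build_structure(est, predictors, classes),
    )


def prune_tree(
    tree: DecisionTree,
    train: pd.DataFrame,
    outcome: str,
    control: TreeControl | None = None,
    seed: int = 0,
) -> DecisionTree:
    """Cost-complexity pruning with cross-validated complexity choice.

    The full pruning path is computed on the training data; the complexity
    parameter is chosen by ``cv_folds``-fold stratified cross-validated
    misclassification, using the one-standard-error rule (the largest
    complexity whose CV error is within one SE of the minimum).
    Deterministic given the seed; pruning may return a root-only tree.
    """
    control = control or TreeControl()
    if control.cv_folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    X = train[tree.feature_names].to_numpy()
    y = train[outcome].to_numpy()
    path = tree.estimator.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) == 1:
        return tree
    n_folds = min(control.cv_folds, int(pd.Series(y).value_counts().min()))
    if n_folds < 2:
        logger.warning("too few subjects per class for CV; returning unpruned tree")
        return tree
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = np.zeros((len(alphas), n_folds))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for i, alpha in enumerate(alphas):
            est = DecisionTreeClassifier(
                criterion="gini",
                min_samples_split=control.minsplit,
                min_samples_leaf=control.minbucket,
                max_depth=control.max_depth,
                random_state=0,
                ccp_alpha=alpha,
            ).fit(X[tr], y[tr])
            errs[i, f] = np.mean(est.predict(X[va]) != y[va])
    mean_err = errs.mean(axis=1)
    se_err = errs.std(axis=1, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_err))
    if control.one_se:
        cutoff = mean_err[i_min] + se_err[i_min]
        candidates = np.nonzero(mean_err <= cutoff)[0]
        i_best = int(candidates[-1])  # largest alpha within one SE
    else:
        i_best = i_min
    return grow_tree(
        train, outcome, tree.feature_names, control, ccp_alpha=float(alphas[i_best])
    )


def _metrics(y_true, y_pred, positive: str) -> tuple[float, float | None]:
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == positive
    if pos.sum() == 0:
        return acc, None
    return acc, float(np.mean(y_pred[pos] == positive))


def evaluate_tree(
    tree: DecisionTree,
    train: pd.DataFrame,
    test: pd.DataFrame,
    outcome: str,
    positive_class: str,
) -> TreeEvaluation:
    """Accuracy and sensitivity on train, test and their union.

    Sensitivity is undefined (None) in a partition without condition
    positives.
    """
    yt, pt = train[outcome].to_numpy(), tree.predict(train)
    ye, pe = test[outcome].to_numpy(), tree.predict(test)
    acc_tr, sen_tr = _metrics(yt, pt, positive_class)
    acc_te, sen_te = _metrics(ye, pe, positive_class)
    acc_f, sen_f = _metrics(np.concatenate([yt, ye]), np.concatenate([pt, pe]), positive_class)
    return TreeEvaluation(acc_tr, acc_te, acc_f, sen_tr, sen_te, sen_f)


#: contrast -> (subset rule, outcome labels, condition-positive class)
TREE_CONTRASTS = {
    "EXS_vs_NonEXS": ("all", ("EXS", "NonEXS"), "EXS"),
    "EXS_vs_STS": ("exs_sts_only", ("EXS", "STS"), "EXS"),
    "STS_vs_NonSTS": ("all", ("STS", "NonSTS"), "STS"),
}


def _outcome_column(cohort: pd.DataFrame, contrast: str) -> pd.DataFrame:
    subset_rule, (pos, neg), _ = TREE_CONTRASTS[contrast]
    df = cohort.copy()
    if subset_rule == "exs_sts_only":
        df = df[df["survival_group"].isin(("EXS", "STS"))]
        df["tree_outcome"] = df["survival_group"]
    else:
        df["tree_outcome"] = np.where(df["survival_group"] == pos, pos, neg)
    return df


def run_tree_battery(
    cohort: pd.DataFrame,
    seed: int = 0,
    predictors=QUANTITATIVE_VARIABLES,
    control: TreeControl | None = None,
    train_frac: float = 0.7,
) -> dict[tuple[str, str], dict]:
    """Grow, prune and evaluate the six per-sex survival-group trees.

    Uses complete cases on the eight quantitative variables (the imaging
    sub-cohort).  The extreme-vs-short-term trees use only subjects in
    those two groups.  Returns a mapping (sex, contrast) -> dict with the
    pruned tree, its evaluation, and the split sizes.
    """
    control = control or TreeControl()
    predictors = list(predictors)
    out: dict[tuple[str, str], dict] = {}
    complete = cohort.dropna(subset=predictors)
    for sex in ("male", "female"):
        sub = complete[complete["sex"] == sex]
        for contrast, (_, (pos, neg), positive) in TREE_CONTRASTS.items():
            df = _outcome_column(sub, contrast)
            counts = df["tree_outcome"].value_counts()
            if len(counts) < 2 or counts.min() < 2:
                logger.warning("skipping %s / %s: a class is (nearly) empty", sex, contrast)
                continue
            train, test = split_cohort(df, "tree_outcome", train_frac, seed)
            grown = grow_tree(train, "tree_outcome", predictors, control)
            pruned = prune_tree(grown, train, "tree_outcome", control, seed)
            ev = evaluate_tree(pruned, train, test, "tree_outcome", positive)
            out[(sex, contrast)] = {
                "tree": pruned,
                "evaluation": ev,
                "n_train": len(train),
                "n_test": len(test),
                "positive_class": positive,
            }
    return out
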