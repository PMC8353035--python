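"""Recovery-trajectory classification by recursive partitioning.

A CART-style classification tree predicts the three recovery
trajectories (resolution within 14 days, beyond 14 days, lost to
follow-up) from initial-assessment features: the somatosensory scores
(TOJ, TOJc, DUR, and the within-subject TOJc - TOJ difference), alone
or combined with the SCAT-5 symptom composites (PST, SSS).

Growth is greedy binary splitting by Gini impurity reduction with
midpoint thresholds; pruning is weakest-link cost-complexity pruning
with the penalty expressed as a complexity parameter cp relative to the
root's cost (a subtree survives only if its impurity improvement per
split exceeds cp times the root impurity).  Model selection evaluates a
grid of ten cp values by leave-one-out cross-validation and keeps the
simplest tree (fewest partitions) among those with maximal accuracy.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BG_FEATURES",
    "COMBINED_FEATURES",
    "TreeNode",
    "TreeModel",
    "TreeReport",
    "grow_tree",
    "prune_tree",
    "loocv_tree",
    "derived_features",
    "default_cp_grid",
]

logger = logging.getLogger(__name__)

#: Feature sets: somatosensory only, and somatosensory plus symptom burden.
BG_FEATURES = ("toj", "tojc", "dur", "tojc_minus_toj")
COMBINED_FEATURES = BG_FEATURES + ("pst", "sss")


@dataclass
class TreeNode:
    """A binary tree node; leaves have ``feature is None``."""

    counts: np.ndarray  # per-class training counts at this node
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # feature < threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def majority(self) -> int:
        return int(np.argmax(self.counts))

    def gini(self) -> float:
        p = self.counts / self.counts.sum()
        return float(1.0 - np.sum(p**2))

    def describe(self, class_names, depth: int = 0) -> str:
        pad = "  " * depth
        counts = "/".join(str(int(c)) for c in self.counts)
        if self.is_leaf:
            return f"{pad}leaf -> {class_names[self.majority]} [{counts}]"
        return "\n".join(
            [
                f"{pad}{self.feature} < {self.threshold:.4g} [{counts}]",
                self.left.describe(class_names, depth + 1),
                self.right.describe(class_names, depth + 1),
            ]
        )

    def to_dict(self, class_names) -> dict:
        base = {"n": self.n, "counts": [int(c) for c in self.counts],
                "majority_class": str(class_names[self.majority])}
        if self.is_leaf:
            return base
        base.update(
            feature=self.feature,
            threshold=float(self.threshold),
            left=self.left.to_dict(class_names),
            right=self.right.to_dict(class_names),
        )
        return base


@dataclass
class TreeModel:
    """A fitted (possibly pruned) classification tree."""

    root: TreeNode
    feature_names: tuple[str, ...]
    class_names: tuple
    cp: float = 0.0
    min_split: int = 20
    min_leaf: int = 7

    @property
    def n_splits(self) -> int:
        def count(node):
            return 0 if node.is_leaf else 1 + count(node.left) + count(node.right)

        return count(self.root)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict class labels for a feature table."""
        out = []
        for _, row in features.iterrows():
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            out.append(self.class_names[node.majority])
        return np.asarray(out)

    def describe(self) -> str:
        return self.root.describe(self.class_names)


@dataclass
class TreeReport:
    """LOOCV evaluation of the cp-tuned tree."""

    feature_set: tuple[str, ...]
    per_class: pd.DataFrame  # class, sensitivity, specificity, balanced_accuracy
    overall_accuracy: float
    accuracy_ci: tuple[float, float]
    selected_cp: float
    cv_accuracy: pd.DataFrame  # cp, accuracy, n_splits of full-data refit
    tree: TreeModel
    fold_predictions: pd.DataFrame = field(repr=False, default=None)


def _best_split(x: np.ndarray, y_codes: np.ndarray, n_classes: int, min_leaf: int):
    """Best (threshold, gini_decrease) for one feature, or None."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y_codes[order]
    n = len(xs)
    # cumulative class counts below each cut position
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    # candidate cuts between distinct adjacent values
    cuts = np.nonzero(np.diff(xs) > 0)[0]  # split after index i
    best = None
    parent_gini = 1.0 - np.sum((total / n) ** 2)
    for i in cuts:
        n_l = i + 1
        n_r = n - n_l
        if n_l < min_leaf or n_r < min_leaf:
            continue
        left = cum[i]
        right = total - left
        g_l = 1.0 - np.sum((left / n_l) ** 2)
        g_r = 1.0 - np.sum((right / n_r) ** 2)
        decrease = parent_gini - (n_l * g_l + n_r * g_r) / n
        if best is None or decrease > best[1] + 1e-15:
            best = ((xs[i] + xs[i + 1]) / 2.0, decrease)
    return best


def grow_tree(
    features: pd.DataFrame,
    labels,
    min_split: int = 20,
    min_leaf: int = 7,
) -> TreeModel:
    """Grow a classification tree by greedy Gini splitting.

    Split candidates are midpoints between sorted distinct feature
    values; a node is split only if it has at least ``min_split``
    cases, both children would have at least ``min_leaf``, and the best
    split strictly reduces Gini impurity.
    """
    if len(features) == 0:
        raise ValueError("empty training data")
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    labels = np.asarray(labels)
    class_names = tuple(sorted(pd.unique(labels), key=str))
    codes = np.array([class_names.index(l) for l in labels])
    feature_names = tuple(features.columns)
    mat = features.to_numpy(dtype=float)

    def build(idx: np.ndarray) -> TreeNode:
        counts = np.bincount(codes[idx], minlength=len(class_names)).astype(float)
        node = TreeNode(counts=counts)
        if len(idx) < min_split or np.count_nonzero(counts) < 2:
            return node
        best = None
        for j, fname in enumerate(feature_names):
            cand = _best_split(mat[idx, j], codes[idx], len(class_names), min_leaf)
            if cand is not None and (best is None or cand[1] > best[2] + 1e-15):
                best = (fname, cand[0], cand[1], j)
        if best is None or best[2] <= 1e-15:
            return node
        fname, thr, _, j = best
        mask = mat[idx, j] < thr
        node.feature = fname
        node.threshold = float(thr)
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(np.arange(len(labels)))
    return TreeModel(
        root=root,
        feature_names=feature_names,
        class_names=class_names,
        min_split=min_split,
        min_leaf=min_leaf,
    )


def _weighted_risk(node: TreeNode, n_total: int) -> float:
    """Sum of leaf Gini impurities weighted by leaf fraction of the data."""
    if node.is_leaf:
        return node.gini() * node.n / n_total
    return _weighted_risk(node.left, n_total) + _weighted_risk(node.right, n_total)


def prune_tree(tree: TreeModel, cp: float) -> TreeModel:
    """Weakest-link cost-complexity pruning.

    Repeatedly collapses the internal node whose impurity improvement
    per split is smallest, while that value is at most ``cp`` times the
    root cost (the root's Gini impurity).  cp = 0 returns the tree
    unchanged; cp >= 1 collapses to the root.  The pruned subtrees are
    nested in cp, so the number of splits is non-increasing.
    """
    if cp < 0:
        raise ValueError("cp must be non-negative")
    pruned = copy.deepcopy(tree)
    pruned.cp = cp
    if cp == 0 or pruned.root.is_leaf:
        return pruned
    n_total = pruned.root.n
    root_cost = pruned.root.gini()

    def weakest(node: TreeNode):
        """(g, node) with minimal g = improvement per split over the subtree."""
        if node.is_leaf:
            return None
        own_risk = node.gini() * node.n / n_total
        sub_risk = _weighted_risk(node, n_total)
        n_leaves = _count_leaves(node)
        g = (own_risk - sub_risk) / (n_leaves - 1)
        best = (g, node)
        for child in (node.left, node.right):
            cand = weakest(child)
            if cand is not None and cand[0] < best[0]:
                best = cand
        return best

    while not pruned.root.is_leaf:
        g, node = weakest(pruned.root)
        if g > cp * root_cost:
            break
        node.feature = None
        node.threshold = None
        node.left = None
        node.right = None
    return pruned


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def default_cp_grid(n_values: int = 10, low: float = 0.001, high: float = 1.0) -> np.ndarray:
    """Log-spaced cp grid from ``low`` to the root's relative cost (1.0)."""
    return np.geomspace(low, high, n_values)


def derived_features(records, feature_set=BG_FEATURES) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table (including TOJc - TOJ per record) and trajectory labels."""
    from .cohort import records_to_frame

    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    for col in ("toj", "tojc"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df["tojc_minus_toj"] = df["tojc"] - df["toj"]
    missing = [f for f in feature_set if f not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return df[list(feature_set)].astype(float), df["trajectory"].to_numpy()


def loocv_tree(
    features: pd.DataFrame,
    labels,
    cp_grid=None,
    seed: int = 0,
    min_split: int = 20,
    min_leaf: int = 7,
) -> TreeReport:
    """Tune cp by LOOCV and evaluate the selected tree.

    For each cp on the grid (ten log-spaced values by default), every
    case is left out in turn, the tree grown and pruned on the rest, and
    the left-out case predicted; the cp with maximal LOOCV accuracy is
    selected, ties broken toward the tree with fewest partitions when
    refit on all data (then toward larger cp).  The final tree is refit
    on the full data at the selected cp.  Per-class one-vs-rest
    sensitivity/specificity/balanced accuracy and the overall accuracy
    with an exact Clopper-Pearson 95% CI are reported from the selected
    cp's LOOCV predictions.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes = tuple(sorted(pd.unique(labels), key=str))
    if n < len(classes):
        raise ValueError("need at least as many cases as classes")
    if cp_grid is None:
        cp_grid = default_cp_grid()
    cp_grid = np.asarray(list(cp_grid), dtype=float)
    if len(cp_grid) == 0:
        raise ValueError("cp grid is empty")

    # grow once per fold, prune per cp
    fold_trees = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(pd.unique(labels[mask])) < 2:
            fold_trees.append(None)  # degenerate fold: majority prediction
            logger.warning("fold %d lost all but one class; predicting majority", i)
        else:
            fold_trees.append(
                grow_tree(features.iloc[mask], labels[mask], min_split, min_leaf)
            )

    preds_per_cp = {}
    acc_rows = []
    for cp in cp_grid:
        preds = []
        for i in range(n):
            tree = fold_trees[i]
            if tree is None:
                vals, cnts = np.unique(labels[np.arange(n) != i], return_counts=True)
                preds.append(vals[np.argmax(cnts)])
                continue
            pruned = prune_tree(tree, cp)
            preds.append(pruned.predict(features.iloc[[i]])[0])
        preds = np.asarray(preds)
        preds_per_cp[cp] = preds
        full = prune_tree(grow_tree(features, labels, min_split, min_leaf), cp)
        acc_rows.append(
            {"cp": cp, "accuracy": float(np.mean(preds == labels)), "n_splits": full.n_splits}
        )
    cv = pd.DataFrame(acc_rows)

    best_acc = cv["accuracy"].max()
    tied = cv[cv["accuracy"] == best_acc]
    tied = tied[tied["n_splits"] == tied["n_splits"].min()]
    selected_cp = float(tied["cp"].max())

    final = prune_tree(grow_tree(features, labels, min_split, min_leaf), selected_cp)
    preds = preds_per_cp[selected_cp]
    correct = int(np.sum(preds == labels))
    ci = proportion_confint(correct, n, alpha=0.05, method="beta")

    rows = []
    for cls in classes:
        tp = int(np.sum((preds == cls) & (labels == cls)))
        fn = int(np.sum((preds != cls) & (labels == cls)))
        tn = int(np.sum((preds != cls) & (labels != cls)))
        fp = int(np.sum((preds == cls) & (labels != cls)))
        sens = tp / (tp + fn) if tp + fn else None
        spec = tn / (tn + fp) if tn + fp else None
        bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
        rows.append(
            {"class": cls, "sensitivity": sens, "specificity": spec, "balanced_accuracy": bal}
        )
    fold_df = pd.DataFrame(
        {"case": np.arange(n), "true_class": labels, "predicted_class": preds}
    )
    return TreeReport(
        feature_set=tuple(features.columns),
        per_class=pd.DataFrame(rows),
        overall_accuracy=correct / n,
        accuracy_ci=(float(ci[0]), float(ci[1])),
        selected_cp=selected_cp,
        cv_accuracy=cv,
        tree=final,
        fold_predictions=fold_df,
    )
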