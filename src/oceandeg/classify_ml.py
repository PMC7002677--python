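"""Depth-limited decision trees over polymer physical properties.

The classifier assigns polymers to the 3-tier degradation scale
{slow, medium, fast} from a handful of bulk features (Mn, enthalpy of
melting, LogP/SA, Tg).  Trees are deliberately shallow (depth 2–3, no
pruning) so the fitted thresholds stay physically interpretable — e.g. a
Tg split near ocean temperature separating slow from medium degraders.

Split search is exact and deterministic: candidate thresholds are midpoints
between consecutive sorted unique feature values, the split maximizing Gini
impurity decrease wins, and ties break toward the lowest feature index in
the declared feature order, then the lowest threshold.  Samples route left
when value < threshold and right when value >= threshold; leaf predictions
take the majority class with ties broken toward the slower class.

Cross-validation (stratified k-fold) and the RBF-SVM used only to shade 2-D
decision regions are delegated to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .degradation_metrics import Tier3

#: declared feature order used for split tie-breaking
DEFAULT_FEATURE_ORDER = ("Mn", "enthalpy", "logp_per_sa", "Tg")
DEFAULT_CV_SEED = 2020

N_CLASSES = 3


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 − Σ pᵢ² of a class-count vector (∈ [0, 2/3] for 3 classes)."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero class counts have undefined impurity")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """Binary tree node carrying class counts [slow, medium, fast] and impurity."""

    counts: np.ndarray
    impurity: float
    feature: str | None = None  # None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> Tier3:
        # ties break toward the slower class: argmax takes the first maximum
        return Tier3(int(np.argmax(self.counts)))


@dataclass
class DecisionTreeModel:
    root: TreeNode
    feature_names: tuple[str, ...]
    max_depth: int

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def rules(self) -> str:
        """Plain-text rule list, one line per node."""
        lines: list[str] = []

        def _walk(node, indent):
            pad = "  " * indent
            tag = f"value={node.counts.astype(int).tolist()} gini={node.impurity:.3f}"
            if node.is_leaf:
                lines.append(f"{pad}predict {node.prediction.name}  [{tag}]")
            else:
                lines.append(f"{pad}if {node.feature} < {node.threshold:g}:  [{tag}]")
                _walk(node.left, indent + 1)
                lines.append(f"{pad}else:  # {node.feature} >= {node.threshold:g}")
                _walk(node.right, indent + 1)

        _walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self) -> str:
        """Graphviz DOT export mirroring the value=[slow, medium, fast] node boxes."""
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = {"n": 0}

        def _walk(node):
            my_id = counter["n"]
            counter["n"] += 1
            label = f"value = {node.counts.astype(int).tolist()}\\ngini = {node.impurity:.3f}"
            if node.is_leaf:
                label = f"{node.prediction.name}\\n{label}"
            else:
                label = f"{node.feature} < {node.threshold:g}\\n{label}"
            lines.append(f'  n{my_id} [label="{label}"];')
            if not node.is_leaf:
                for child in (node.left, node.right):
                    child_id = counter["n"]
                    _walk(child)
                    lines.append(f"  n{my_id} -> n{child_id};")

        _walk(self.root)
        lines.append("}")
        return "\n".join(lines)


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES).astype(float)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    return (uniq[:-1] + uniq[1:]) / 2.0


def _best_split(X: np.ndarray, y: np.ndarray, feature_names) -> tuple[int, float] | None:
    """Exhaustive search for the (feature, midpoint) split with maximal Gini decrease.

    Ties break toward the lowest feature index, then the lowest threshold
    (enforced by scan order and strict improvement comparison).
    """
    n = len(y)
    parent = gini_impurity(_class_counts(y))
    best = None
    best_gain = 0.0
    for f_idx in range(X.shape[1]):
        values = X[:, f_idx]
        order = np.argsort(values, kind="stable")
        for thr in _candidate_thresholds(values):
            mask = values < thr
            n_left = int(mask.sum())
            if n_left == 0 or n_left == n:
                continue
            g_left = gini_impurity(_class_counts(y[mask]))
            g_right = gini_impurity(_class_counts(y[~mask]))
            gain = parent - (n_left * g_left + (n - n_left) * g_right) / n
            if gain > best_gain + 1e-12:
                best_gain = gain
                best = (f_idx, float(thr))
        del order
    return best


def fit_tree(X, y, feature_names=DEFAULT_FEATURE_ORDER, max_depth: int = 2) -> DecisionTreeModel:
    """Greedy Gini tree limited to ``max_depth`` levels of splits.

    ``X`` is (n_samples, n_features) in the order of ``feature_names``; ``y``
    holds Tier3 labels (or their integer codes).  Recursion stops at the
    depth cap, at pure nodes, or when no split reduces impurity; datasets
    whose features cannot separate mixed labels yield a single-leaf model
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([int(v) for v in y])
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if len(y) < 2:
        raise ValueError("need at least 2 records to fit a tree")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names must match the number of columns in X")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; use select_complete upstream")

    def _grow(Xs, ys, depth) -> TreeNode:
        counts = _class_counts(ys)
        node = TreeNode(counts=counts, impurity=gini_impurity(counts))
        if depth >= max_depth or node.impurity == 0.0:
            return node
        split = _best_split(Xs, ys, feature_names)
        if split is None:
            return node
        f_idx, thr = split
        mask = Xs[:, f_idx] < thr
        node.feature = feature_names[f_idx]
        node.threshold = thr
        node.left = _grow(Xs[mask], ys[mask], depth + 1)
        node.right = _grow(Xs[~mask], ys[~mask], depth + 1)
        return node

    root = _grow(X, y, 0)
    if root.is_leaf and root.impurity > 0:
        warnings.warn(
            "features cannot separate mixed labels; returning a single-leaf model",
            stacklevel=2,
        )
    return DecisionTreeModel(root=root, feature_names=tuple(feature_names), max_depth=max_depth)


def predict(model: DecisionTreeModel, record) -> Tier3:
    """Route one feature vector (aligned with ``model.feature_names``) to a leaf class."""
    x = np.asarray(record, dtype=float)
    if x.shape != (len(model.feature_names),):
        raise ValueError(f"record must have {len(model.feature_names)} features")
    if np.isnan(x).any():
        raise ValueError("record has missing feature values")
    node = model.root
    name_to_idx = {n: i for i, n in enumerate(model.feature_names)}
    while not node.is_leaf:
        node = node.left if x[name_to_idx[node.feature]] < node.threshold else node.right
    return node.prediction


def predict_many(model: DecisionTreeModel, X) -> np.ndarray:
    return np.array([int(predict(model, row)) for row in np.asarray(X, dtype=float)])


def training_accuracy(model: DecisionTreeModel, X, y) -> float:
    """Percent of records the tree classifies correctly."""
    y = np.asarray([int(v) for v in y])
    if len(y) == 0:
        raise ValueError("empty data")
    return float(100.0 * np.mean(predict_many(model, X) == y))


@dataclass
class CVResult:
    k: int
    seed: int
    fold_accuracies: list[float]  # %
    mean_accuracy: float = field(init=False)  # %

    def __post_init__(self):
        self.mean_accuracy = float(np.mean(self.fold_accuracies))


def stratified_cv(
    X, y, k: int = 10, seed: int = DEFAULT_CV_SEED,
    feature_names=DEFAULT_FEATURE_ORDER, max_depth: int = 2,
) -> CVResult:
    """Stratified k-fold cross-validation of the depth-limited tree.

    Folds preserve class proportions as closely as integer counts allow;
    accuracy is the mean over folds of the holdout accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([int(v) for v in y])
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available records")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(X, y):
        model = fit_tree(X[train_idx], y[train_idx], feature_names, max_depth)
        folds.append(training_accuracy(model, X[test_idx], y[test_idx]))
    return CVResult(k=k, seed=seed, fold_accuracies=folds)


def decision_regions(X, y, kernel_width: float = 0.2, regularization: float = 10.0):
    """RBF-SVM region classifier for 2-D feature maps (visual layer only).

    Standardizes the two features, then fits an SVC with the given RBF gamma
    and C.  The returned pipeline shades fast/medium/slow zones on a grid;
    it is not used for any reported accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([int(v) for v in y])
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("decision_regions needs exactly 2 feature columns")
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-class input")
    pipeline = make_pipeline(
        StandardScaler(), SVC(kernel="rbf", gamma=kernel_width, C=regularization)
    )
    pipeline.fit(X, y)
    return pipeline
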