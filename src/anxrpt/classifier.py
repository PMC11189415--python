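"""Random-forest anxiety-level classification with a balanced-bootstrap variant.

STAI-S scores are thresholded into 'higher' / 'lower' classes (score >=
threshold is 'higher'); the thresholds 35 / 45 / 55 roughly track the 50th,
75th and 90th percentile of typical state-anxiety scores, so class imbalance
grows with the threshold.

Two forest modes share one implementation built on scikit-learn decision
trees:

* ``rf``  - the ordinary bootstrap (n draws with replacement per tree);
* ``brf`` - a balanced bootstrap: each tree draws, with replacement, the
  minority-class count from *every* class, down-sampling the majority class
  per tree. Down-sampling happens only during training; out-of-bag (OOB)
  accuracy and all test metrics are computed on untouched, imbalanced data.

The forest exposes per-tree bootstrap class counts (so the balance contract
is assertable), R-style mean decrease in Gini importances, and the
terminal-node proximity matrix used for classical MDS embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

HIGHER, LOWER = "higher", "lower"

#: The four contextual variables that dominate the Gini importance ranking.
TOP_CONTEXTUAL: tuple[str, ...] = ("age", "loneliness", "income", "employment")


class ClassBalanceError(ValueError):
    """Raised when a split/labelling leaves a class empty or unlearnable."""


def label_anxiety(scores: pd.Series, threshold: float) -> tuple[pd.Series, dict[str, float]]:
    """Binary anxiety labels: score >= threshold -> 'higher', else 'lower'.

    Returns the labels and each class's percentage of the data. Raises if
    the threshold is outside the attainable 20..80 score range or either
    class is empty (an unlearnable split).
    """
    if not 20 <= threshold <= 80:
        raise ValueError(f"threshold {threshold} outside the STAI-S range 20..80")
    labels = pd.Series(np.where(scores >= threshold, HIGHER, LOWER),
                       index=scores.index, name="anxiety_class")
    pct = {c: 100.0 * float((labels == c).mean()) for c in (HIGHER, LOWER)}
    if pct[HIGHER] == 0.0 or pct[LOWER] == 0.0:
        raise ClassBalanceError(f"threshold {threshold} leaves one class empty")
    return labels, pct


@dataclass
class ClassifierRun:
    """Settings for one train/evaluate cycle (defaults follow the study design)."""

    threshold: float = 35.0
    mode: str = "brf"  # 'rf' or 'brf'
    seed: int = 0
    train_frac: float = 0.7
    n_trees: int = 1000
    vars_per_split: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("rf", "brf"):
            raise ValueError(f"mode must be 'rf' or 'brf', got {self.mode!r}")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


class RandomForest:
    """Bagged CART forest with plain or per-tree class-balanced bootstraps.

    Vote fractions (the share of trees predicting 'higher') provide the
    continuous score used for ROC curves. ``bootstrap_class_counts_`` holds
    the per-tree drawn class counts for auditing the balance contract.
    """

    def __init__(self, mode: str = "brf", n_trees: int = 1000,
                 vars_per_split: int = 5, seed: int = 0):
        self.mode = mode
        self.n_trees = n_trees
        self.vars_per_split = vars_per_split
        self.seed = seed

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ClassBalanceError("training data contains a single class")
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        class_idx = {c: np.flatnonzero(y == c) for c in self.classes_}
        minority = min(len(v) for v in class_idx.values())

        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_class_counts_: list[dict[str, int]] = []
        votes = np.zeros((n, self.classes_.size))
        oob_counts = np.zeros(n)

        for _ in range(self.n_trees):
            if self.mode == "brf":
                idx = np.concatenate([
                    rng.choice(class_idx[c], size=minority, replace=True)
                    for c in self.classes_])
            else:
                idx = rng.integers(0, n, size=n)
            yb = y[idx]
            self.bootstrap_class_counts_.append(
                {c: int((yb == c).sum()) for c in self.classes_})
            tree = DecisionTreeClassifier(
                max_features=min(self.vars_per_split, X.shape[1]),
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[idx], yb)
            self.trees_.append(tree)

            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if oob.any():
                pred = tree.predict(X[oob])
                for j, c in enumerate(self.classes_):
                    votes[oob, j] += (pred == c)
                oob_counts[oob] += 1

        seen = oob_counts > 0
        oob_pred = self.classes_[np.argmax(votes, axis=1)]
        self.oob_accuracy_ = 100.0 * float((oob_pred[seen] == y[seen]).mean())
        self._fit_X_shape = X.shape
        return self

    # -- prediction --------------------------------------------------------

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Per-class fraction of trees voting for each sample (rows sum to 1)."""
        X = np.asarray(X, dtype=float)
        counts = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.trees_:
            pred = tree.predict(X)
            for j, c in enumerate(self.classes_):
                counts[:, j] += (pred == c)
        return counts / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.vote_fractions(X), axis=1)]

    # -- importances and proximities --------------------------------------

    def gini_decreases(self) -> np.ndarray:
        """Mean decrease in Gini per feature (R randomForest convention).

        Per tree, each internal node contributes its impurity decrease
        weighted by the number of samples reaching it; contributions are
        summed per feature and averaged over trees.
        """
        n_features = self._fit_X_shape[1]
        total = np.zeros(n_features)
        for tree in self.trees_:
            t = tree.tree_
            internal = t.children_left >= 0
            node = np.flatnonzero(internal)
            left, right = t.children_left[node], t.children_right[node]
            w = t.weighted_n_node_samples
            decrease = (w[node] * t.impurity[node]
                        - w[left] * t.impurity[left]
                        - w[right] * t.impurity[right])
            np.add.at(total, t.feature[node], decrease)
        return total / len(self.trees_)

    def proximity(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node co-occurrence frequencies, normalized by tree count.

        P[i, j] is the fraction of trees in which samples i and j land in
        the same leaf; symmetric with unit diagonal. O(n^2) memory.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        P = np.zeros((n, n))
        for tree in self.trees_:
            leaves = tree.apply(X)
            P += leaves[:, None] == leaves[None, :]
        return P / len(self.trees_)


@dataclass
class MetricsReport:
    """Confusion-matrix rates (percent) and AUC for one evaluation."""

    oob_accuracy: float | None
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc_roc: float | None
    class_percentages: dict[str, float] = field(default_factory=dict)

    @property
    def balanced_accuracy(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return (self.sensitivity + self.specificity) / 2.0

    def to_dict(self) -> dict:
        return {"oob_accuracy": self.oob_accuracy, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "auc_roc": self.auc_roc, "balanced_accuracy": self.balanced_accuracy,
                "class_percentages": dict(self.class_percentages)}


def split_train_test(index: pd.Index, train_frac: float, seed: int
                     ) -> tuple[pd.Index, pd.Index]:
    """Simple (non-stratified) random split of participant ids."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(index))
    n_train = int(round(train_frac * len(index)))
    return index[perm[:n_train]], index[perm[n_train:]]


def train_rf(X_train: np.ndarray, y_train: Sequence[str], run: ClassifierRun
             ) -> RandomForest:
    """Fit a forest per ``run``; OOB accuracy lands on ``model.oob_accuracy_``."""
    model = RandomForest(mode=run.mode, n_trees=run.n_trees,
                         vars_per_split=run.vars_per_split, seed=run.seed)
    return model.fit(X_train, y_train)


def evaluate(model: RandomForest, X_test: np.ndarray, y_test: Sequence[str],
             class_percentages: dict[str, float] | None = None) -> MetricsReport:
    """Test-set metrics with 'higher' as the positive class.

    AUC uses the continuous vote fraction for 'higher'. A test set missing
    one class reports the corresponding rate (and AUC) as None.
    """
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    frac = model.vote_fractions(X_test)
    pred = model.classes_[np.argmax(frac, axis=1)]
    acc = 100.0 * float((pred == y_test).mean())

    pos, neg = y_test == HIGHER, y_test == LOWER
    sens = 100.0 * float((pred[pos] == HIGHER).mean()) if pos.any() else None
    spec = 100.0 * float((pred[neg] == LOWER).mean()) if neg.any() else None
    if pos.any() and neg.any():
        j = list(model.classes_).index(HIGHER)
        auc = float(roc_auc_score((y_test == HIGHER).astype(int), frac[:, j]))
    else:
        auc = None
    return MetricsReport(
        oob_accuracy=getattr(model, "oob_accuracy_", None), accuracy=acc,
        sensitivity=sens, specificity=spec, auc_roc=auc,
        class_percentages=class_percentages or {})


def classify_cohort(features: pd.DataFrame, scores: pd.Series, run: ClassifierRun
                    ) -> tuple[RandomForest, MetricsReport, pd.Index, pd.Index]:
    """Label, split, train and evaluate in one call.

    Returns the fitted model, the test metrics, and the train/test id sets.
    """
    labels, pct = label_anxiety(scores, run.threshold)
    train_ids, test_ids = split_train_test(features.index, run.train_frac, run.seed)
    if labels.loc[train_ids].nunique() < 2:
        raise ClassBalanceError("training split contains a single class")
    model = train_rf(features.loc[train_ids].to_numpy(), labels.loc[train_ids], run)
    report = evaluate(model, features.loc[test_ids].to_numpy(),
                      labels.loc[test_ids].to_numpy(), class_percentages=pct)
    return model, report, train_ids, test_ids


def permutation_null(features: pd.DataFrame, scores: pd.Series, run: ClassifierRun,
                     n_iter: int = 100) -> MetricsReport:
    """Chance-level metrics: shuffle labels, retrain, evaluate; average.

    Each iteration shuffles the 'higher'/'lower' labels over participants,
    repeats the full split/train/evaluate cycle with a fresh derived seed,
    and the metric means over iterations are returned.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels, pct = label_anxiety(scores, run.threshold)
    rng = np.random.default_rng(run.seed)
    acc, sens, spec, auc, oob = [], [], [], [], []
    for it in range(n_iter):
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        train_ids, test_ids = split_train_test(features.index, run.train_frac, sub_seed)
        if shuffled.loc[train_ids].nunique() < 2:
            continue
        model = RandomForest(run.mode, run.n_trees, run.vars_per_split, sub_seed)
        model.fit(features.loc[train_ids].to_numpy(), shuffled.loc[train_ids])
        rep = evaluate(model, features.loc[test_ids].to_numpy(),
                       shuffled.loc[test_ids].to_numpy())
        acc.append(rep.accuracy)
        oob.append(rep.oob_accuracy)
        if rep.sensitivity is not None:
            sens.append(rep.sensitivity)
        if rep.specificity is not None:
            spec.append(rep.specificity)
        if rep.auc_roc is not None:
            auc.append(rep.auc_roc)

    mean = lambda v: float(np.mean(v)) if v else None
    return MetricsReport(oob_accuracy=mean(oob), accuracy=mean(acc),
                         sensitivity=mean(sens), specificity=mean(spec),
                         auc_roc=mean(auc), class_percentages=pct)


@dataclass
class ImportanceReport:
    """Normalized Gini shares (summing to 1) with the study's feature groups."""

    shares: pd.Series  # per-feature normalized mean decrease in Gini
    group_sums: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return self.shares.sort_values(ascending=False).to_frame("relative_importance")


def gini_importance(model: RandomForest, feature_names: Sequence[str],
                    judgment_vars: Sequence[str] | None = None) -> ImportanceReport:
    """Relative importance: each Gini score over the sum of all Gini scores.

    Group sums cover the four leading contextual variables (age, loneliness,
    income, employment), the 15 judgment variables, and the remainder.
    """
    from .rpt_features import JUDGMENT_VARIABLES

    raw = model.gini_decreases()
    total = raw.sum()
    if total <= 0:
        raise ValueError("all Gini importances are zero")
    shares = pd.Series(raw / total, index=list(feature_names))
    judgment = list(judgment_vars) if judgment_vars is not None else list(JUDGMENT_VARIABLES)
    top4 = [f for f in TOP_CONTEXTUAL if f in shares.index]
    jv = [f for f in judgment if f in shares.index]
    rest = [f for f in shares.index if f not in set(top4) | set(jv)]
    groups = {"top4_contextual": float(shares[top4].sum()),
              "judgment": float(shares[jv].sum()),
              "other_contextual": float(shares[rest].sum())}
    return ImportanceReport(shares=shares, group_sums=groups)


def proximity_mds(model: RandomForest, X: np.ndarray, n_components: int = 2
                  ) -> np.ndarray:
    """Classical metric MDS of 1 - proximity into ``n_components`` dimensions."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for an MDS embedding")
    D = 1.0 - model.proximity(X)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_top)
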