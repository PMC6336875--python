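"""Depth-limited decision-tree permissibility models.

Binarized permissibility is predicted from residue-level protein properties
with CART trees (Gini impurity) capped at depth 4 to limit overfitting,
evaluated by stratified 10-fold cross-validation with out-of-fold
probabilities pooled into ROC / precision-recall / accuracy-vs-cutoff
curves. Feature-withholding refits quantify how much signal a property or a
whole category (static / conservation / dynamic) carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier


def _as_matrix(features):
    """Accept a FeatureTable, DataFrame or ndarray; return (X, names)."""
    table = features.values if hasattr(features, "categories") else features
    if hasattr(table, "columns"):
        return table.to_numpy(float), list(table.columns)
    X = np.asarray(table, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


@dataclass
class TreeModel:
    """A fitted CART tree plus its feature names."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    max_depth: int

    @property
    def fitted(self) -> bool:
        return hasattr(self.estimator, "tree_")

    @property
    def depth(self) -> int:
        return int(self.estimator.get_depth())

    @property
    def root_feature(self) -> str:
        """Name of the feature used at the root split."""
        idx = self.estimator.tree_.feature[0]
        if idx < 0:
            raise ValueError("tree has no split")
        return self.feature_names[idx]

    def predict_proba(self, features) -> np.ndarray:
        X, _ = _as_matrix(features)
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class PerformanceReport:
    fold_auc: list[float]
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    accuracy: np.ndarray
    top_features: list[tuple[str, float]]


def fit_tree(features, labels, max_depth: int = 4,
             min_leaf: int = 5) -> TreeModel:
    """Fit a Gini CART tree of bounded depth. Deterministic: refitting on
    identical input yields an identical tree (fixed random_state)."""
    X, names = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    est = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 min_samples_leaf=min_leaf, random_state=0)
    est.fit(X, y)
    return TreeModel(est, names, max_depth)


def _curves(y: np.ndarray, prob: np.ndarray):
    fpr, tpr, _ = roc_curve(y, prob)
    cutoffs = np.linspace(0.0, 1.0, 101)
    precision = np.empty_like(cutoffs)
    recall = np.empty_like(cutoffs)
    accuracy = np.empty_like(cutoffs)
    pos = y == 1
    for i, c in enumerate(cutoffs):
        pred = prob >= c
        tp = np.sum(pred & pos)
        precision[i] = tp / pred.sum() if pred.sum() else np.nan
        recall[i] = tp / pos.sum() if pos.sum() else np.nan
        accuracy[i] = np.mean(pred == pos)
    return fpr, tpr, cutoffs, precision, recall, accuracy


def cross_validate(features, labels, k: int = 10, seed: int = 0,
                   max_depth: int = 4, min_leaf: int = 5) -> PerformanceReport:
    """Stratified k-fold CV; out-of-fold leaf probabilities are pooled into
    one ROC (AUC by the trapezoid rule), precision / recall / accuracy
    vs cutoff curves, and mean per-feature importances."""
    X, names = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if k > len(y):
        raise ValueError("k exceeds the number of samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    fold_auc = []
    importances = np.zeros(X.shape[1])
    for train, test in skf.split(X, y):
        est = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                     min_samples_leaf=min_leaf,
                                     random_state=0)
        est.fit(X[train], y[train])
        prob = est.predict_proba(X[test])[:, 1]
        oof[test] = prob
        importances += est.feature_importances_
        if len(np.unique(y[test])) == 2:
            fpr, tpr, _ = roc_curve(y[test], prob)
            fold_auc.append(float(_auc(fpr, tpr)))
    fpr, tpr, cutoffs, precision, recall, accuracy = _curves(y, oof)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    top = sorted(zip(names, importances), key=lambda t: -t[1])
    return PerformanceReport(fold_auc, float(_auc(fpr, tpr)), fpr, tpr,
                             cutoffs, precision, recall, accuracy, top)


def withhold_features(features, labels, withhold,
                      categories: Mapping[str, str] | None = None,
                      k: int = 10, seed: int = 0, max_depth: int = 4,
                      min_leaf: int = 5,
                      ) -> tuple[PerformanceReport, PerformanceReport, float]:
    """Cross-validate with and without a feature set.

    ``withhold`` is a list of feature names or a category name ('static',
    'conservation', 'dynamic'); categories come from the FeatureTable or the
    ``categories`` mapping. Returns (full report, withheld report, delta AUC
    = full - withheld).
    """
    import pandas as pd

    table = features.values if hasattr(features, "categories") else features
    if not hasattr(table, "columns"):
        table = pd.DataFrame(np.asarray(table, dtype=float))
        table.columns = [f"f{i}" for i in range(table.shape[1])]
    cats = categories or getattr(features, "categories", {})
    if isinstance(withhold, str):
        names = [f for f, c in cats.items() if c == withhold]
        if not names:
            raise ValueError(f"no features in category {withhold!r}")
    else:
        names = list(withhold)
    unknown = set(names) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    kept = [c for c in table.columns if c not in set(names)]
    if not kept:
        raise ValueError("cannot withhold every feature")
    full = cross_validate(table, labels, k=k, seed=seed, max_depth=max_depth,
                          min_leaf=min_leaf)
    reduced = cross_validate(table[kept], labels, k=k, seed=seed,
                             max_depth=max_depth, min_leaf=min_leaf)
    return full, reduced, full.auc - reduced.auc


def top_features(model: TreeModel, n: int = 4) -> list[tuple[str, float]]:
    """Features ranked by total Gini impurity decrease, normalized to sum 1."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    imp = model.estimator.feature_importances_
    ranked = sorted(zip(model.feature_names, imp), key=lambda t: -t[1])
    return [(f, float(v)) for f, v in ranked[:n]]


def depth_score_table(features, labels, depths: Sequence[int] = (1, 2, 3, 4, 5, 6),
                      k: int = 10, seed: int = 0):
    """CV AUC as a function of tree depth (complexity/pruning view)."""
    import pandas as pd

    rows = [{"max_depth": d,
             "cv_auc": cross_validate(features, labels, k=k, seed=seed,
                                      max_depth=d).auc}
            for d in depths]
    return pd.DataFrame(rows)


def tree_to_dict(model: TreeModel) -> dict:
    """JSON-serializable nested representation of a fitted tree."""
    t = model.estimator.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            counts = t.value[i][0]
            total = counts.sum()
            return {"leaf": True,
                    "proba": (counts / total).tolist() if total else [0.5, 0.5]}
        return {"leaf": False,
                "feature": model.feature_names[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i])}

    return {"max_depth": model.max_depth, "tree": node(0)}
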