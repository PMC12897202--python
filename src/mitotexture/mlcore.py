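"""Feature standardization, recursive feature elimination, and the two
classifiers (decision tree; one-vs-rest SVM).

Stands on scikit-learn: ``StandardScaler``, ``RFE``, ``DecisionTreeClassifier``
and ``OneVsRestClassifier(SVC)``. Standardization is applied for the SVM and
for RFE (margin methods are scale-sensitive) and never for the decision tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable


def _as_dataframe(table) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        return table.to_dataframe()
    return table


def table_xy(table, feature_names: list[str] | None = None):
    """(X, y, feature_names) arrays from a feature table, dropping rows with
    missing values (row-completeness filter)."""
    df = _as_dataframe(table)
    names = feature_names or [c for c in df.columns if c not in ("roi_id", "class_label")]
    sub = df[names + ["class_label"]].dropna()
    return sub[names].to_numpy(dtype=np.float64), sub["class_label"].to_numpy(), names


@dataclass
class SelectionResult:
    """RFE output: per-feature rank (1 = retained) and the retained set."""

    ranking: pd.DataFrame          # columns: feature, rank, retained
    n_keep: int
    accuracy_curve: pd.DataFrame | None = None   # columns: n_features, cv_accuracy

    @property
    def retained(self) -> list[str]:
        kept = self.ranking.loc[self.ranking["retained"], "feature"].tolist()
        return kept

    def to_csv(self, path) -> None:
        self.ranking.to_csv(path, index=False)


def _ranking_estimator(kind: str, seed: int):
    if kind == "svm_linear":
        # one-vs-rest linear SVM; RFE ranks by absolute coefficient magnitude
        return LinearSVC(C=1.0, dual="auto", max_iter=5000, random_state=seed)
    if kind == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown ranking estimator {kind!r}")


def rfe_cv(table, n_keep: int = 20, estimator: str = "svm_linear",
           cv_folds: int = 5, seed: int = 0,
           accuracy_curve: bool = True) -> SelectionResult:
    """Recursive feature elimination retaining the ``n_keep`` top features.

    Features are z-scored, the ranking model refit after each single-feature
    removal; constant (zero-variance) features are dropped with a warning
    before ranking. When ``accuracy_curve`` is set, stratified CV accuracy is
    reported as a function of retained-set size.
    """
    X, y, names = table_xy(table)
    if n_keep > len(names):
        raise ValueError(f"n_keep={n_keep} exceeds feature count {len(names)}")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")

    keep_mask = X.std(axis=0) > 0
    if not keep_mask.all():
        dropped = [n for n, k in zip(names, keep_mask) if not k]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}")
    active = [n for n, k in zip(names, keep_mask) if k]
    Xa = X[:, keep_mask]

    if n_keep == len(active) and keep_mask.all():
        ranking = pd.DataFrame({"feature": names, "rank": 1, "retained": True})
        return SelectionResult(ranking, n_keep)

    Xs = StandardScaler().fit_transform(Xa)
    rfe = RFE(_ranking_estimator(estimator, seed), n_features_to_select=n_keep, step=1)
    rfe.fit(Xs, y)

    rank_map = {n: int(r) for n, r in zip(active, rfe.ranking_)}
    worst = max(rank_map.values(), default=1)
    rows = [{"feature": n,
             "rank": rank_map.get(n, worst + 1),
             "retained": rank_map.get(n, worst + 1) == 1} for n in names]
    ranking = pd.DataFrame(rows).sort_values(["rank", "feature"]).reset_index(drop=True)

    curve = None
    if accuracy_curve:
        order = ranking["feature"].tolist()      # best first
        sizes = sorted({s for s in (5, 10, 20, 40, len(active)) if s <= len(active)})
        cv = StratifiedKFold(n_splits=min(cv_folds, int(np.min(np.bincount(
            pd.factorize(y)[0])))), shuffle=True, random_state=seed)
        recs = []
        for s in sizes:
            cols = [names.index(f) for f in order[:s]]
            pipe = Pipeline([("scale", StandardScaler()),
                             ("clf", _ranking_estimator(estimator, seed))])
            acc = cross_val_score(pipe, X[:, cols], y, cv=cv).mean()
            recs.append({"n_features": s, "cv_accuracy": float(acc)})
        curve = pd.DataFrame(recs)

    return SelectionResult(ranking, n_keep, curve)


@dataclass
class TrainedModel:
    """A fitted classifier plus its scaler and retained feature list."""

    kind: str                       # "tree" | "ovr_svm"
    estimator: object               # fitted sklearn estimator/pipeline
    classes: np.ndarray
    features: list[str]
    decision_threshold: float = 0.5

    def _matrix(self, table) -> np.ndarray:
        df = _as_dataframe(table)
        missing = [f for f in self.features if f not in df.columns]
        if missing:
            raise ValueError(f"feature mismatch; missing {missing[:3]}")
        return df[self.features].to_numpy(dtype=np.float64)

    def predict(self, table) -> np.ndarray:
        scores = self.predict_scores(table)
        if self.kind == "tree" and len(self.classes) == 2:
            pos = scores[:, 1] > self.decision_threshold
            return np.where(pos, self.classes[1], self.classes[0])
        return self.classes[np.argmax(scores, axis=1)]

    def predict_scores(self, table) -> np.ndarray:
        """Per-class score matrix: class probabilities for the tree,
        decision-function values for the SVM."""
        X = self._matrix(table)
        if self.kind == "tree":
            return self.estimator.predict_proba(X)
        scores = self.estimator.decision_function(X)
        if scores.ndim == 1:    # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores


def _selected_features(selection, table) -> list[str] | None:
    if selection is None:
        return None     # table_xy falls back to all feature columns
    if isinstance(selection, SelectionResult):
        return selection.retained
    return list(selection)


def fit_decision_tree(table, selection=None, seed: int = 0,
                      **hyperparams) -> TrainedModel:
    """Fit an axis-aligned threshold tree (Gini impurity by default)."""
    X, y, feats = table_xy(table, _selected_features(selection, table))
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    clf = DecisionTreeClassifier(random_state=seed, **hyperparams).fit(X, y)
    return TrainedModel("tree", clf, clf.classes_, feats)


def fit_ovr_svm(table, selection=None, kernel: str = "rbf", C: float = 1.0,
                gamma="scale", seed: int = 0) -> TrainedModel:
    """Fit a one-vs-rest SVM on z-scored features.

    One binary margin classifier per class; prediction is the argmax of the
    decision values with ties broken by the fixed (sorted) class order.
    """
    X, y, feats = table_xy(table, _selected_features(selection, table))
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", OneVsRestClassifier(SVC(kernel=kernel, C=C, gamma=gamma,
                                        random_state=seed))),
    ]).fit(X, y)
    return TrainedModel("ovr_svm", pipe, pipe.named_steps["svm"].classes_, feats)


def predict_scores(model: TrainedModel, table) -> np.ndarray:
    """Module-level alias for :meth:`TrainedModel.predict_scores`."""
    return model.predict_scores(table)
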