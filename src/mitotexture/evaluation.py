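"""Repeated stratified cross-validation, classification reports, and
bootstrap ROC/AUC with percentile confidence intervals."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import mlcore
from .mlcore import TrainedModel, table_xy

logger = logging.getLogger(__name__)


@dataclass
class CVSpec:
    """Cross-validation layout. The defaults match a 10-fold stratified
    scheme; the one-vs-rest SVM is conventionally run 2-fold x 3 repeats."""

    n_folds: int = 10
    n_repeats: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ModelSpec:
    """Which classifier to refit in each training fold.

    When ``n_keep`` is set, feature selection (RFE) is re-run inside every
    training fold so no information leaks from the test fold.
    """

    kind: str = "ovr_svm"          # "ovr_svm" | "tree"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: object = "scale"
    tree_params: dict = field(default_factory=dict)
    n_keep: int | None = None

    def fit(self, table, selection=None, seed: int = 0) -> TrainedModel:
        if self.kind == "ovr_svm":
            return mlcore.fit_ovr_svm(table, selection, kernel=self.kernel,
                                      C=self.C, gamma=self.gamma, seed=seed)
        if self.kind == "tree":
            return mlcore.fit_decision_tree(table, selection, seed=seed,
                                            **self.tree_params)
        raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class EvalReport:
    """Cross-validated performance summary."""

    classes: list[str]
    accuracy_mean: float
    accuracy_sd: float
    fold_accuracies: list[float]
    confusion: np.ndarray                    # pooled counts over folds/repeats
    per_class: dict                          # precision/recall/f1 per class
    auc: dict | None = None                  # per-class AUC + CI, macro AUC

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "fold_accuracies": self.fold_accuracies,
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": self.per_class,
            "auc": self.auc,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy_mean:.3f} +/- {self.accuracy_sd:.3f}",
                 "confusion matrix (rows = true):"]
        header = "            " + "  ".join(f"{c:>8}" for c in self.classes)
        lines.append(header)
        for c, row in zip(self.classes, np.asarray(self.confusion)):
            lines.append(f"{c:>12}" + "  ".join(f"{int(v):8d}" for v in row))
        for c in self.classes:
            m = self.per_class[c]
            lines.append(f"{c:>12}  precision {m['precision']:.3f}  "
                         f"recall {m['recall']:.3f}  f1 {m['f1']:.3f}")
        if self.auc:
            for c, a in self.auc["per_class"].items():
                lines.append(f"{c:>12}  AUC {a['auc']:.3f} "
                             f"[{a['ci_low']:.3f}, {a['ci_high']:.3f}]")
            lines.append(f"macro AUC: {self.auc['macro_auc']:.3f}")
        return "\n".join(lines)


def classification_report(confusion: np.ndarray, classes=None) -> dict:
    """Per-class precision/recall/F1 and overall accuracy from a square
    confusion matrix (rows = true class). Zero divisions yield 0 and are
    flagged in the per-class ``undefined`` list."""
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = cm.shape[0]
    classes = list(classes) if classes is not None else list(range(n))
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    out = {}
    for k, c in enumerate(classes):
        undefined = []
        prec = tp[k] / (tp[k] + fp[k]) if tp[k] + fp[k] > 0 else 0.0
        if tp[k] + fp[k] == 0:
            undefined.append("precision")
        rec = tp[k] / (tp[k] + fn[k]) if tp[k] + fn[k] > 0 else 0.0
        if tp[k] + fn[k] == 0:
            undefined.append("recall")
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        out[c] = {"precision": float(prec), "recall": float(rec), "f1": float(f1),
                  "support": int(cm[k].sum()), "undefined": undefined}
    accuracy = float(tp.sum() / cm.sum()) if cm.sum() > 0 else 0.0
    return {"per_class": out, "accuracy": accuracy}


def stratified_repeated_cv(model_spec: ModelSpec, table, cv: CVSpec,
                           collect_scores: bool = False):
    """Repeated stratified k-fold CV with scaler/selector/model refit per
    training fold.

    Returns an :class:`EvalReport`; with ``collect_scores`` also returns the
    pooled out-of-fold ``(scores, labels)`` for ROC analysis.
    """
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else table
    y = df["class_label"].to_numpy()
    classes = sorted(np.unique(y))
    counts = pd.Series(y).value_counts()
    if counts.min() < cv.n_folds:
        raise ValueError(f"class {counts.idxmin()!r} has {counts.min()} samples, "
                         f"fewer than n_folds={cv.n_folds}")
    idx = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_accs: list[float] = []
    all_scores, all_labels = [], []

    for rep in range(cv.n_repeats):
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True,
                                   random_state=cv.seed + rep)
        for train_idx, test_idx in splitter.split(df, y):
            train_df = df.iloc[train_idx]
            test_df = df.iloc[test_idx]
            selection = None
            if model_spec.n_keep is not None:
                selection = mlcore.rfe_cv(train_df, n_keep=model_spec.n_keep,
                                          seed=cv.seed, accuracy_curve=False)
            model = model_spec.fit(train_df, selection, seed=cv.seed)
            pred = model.predict(test_df)
            truth = test_df["class_label"].to_numpy()
            fold_accs.append(float(np.mean(pred == truth)))
            for t, p in zip(truth, pred):
                cm[idx[t], idx[p]] += 1
            if collect_scores:
                sc = model.predict_scores(test_df)
                # align score columns to the global sorted class order
                col = [list(model.classes).index(c) for c in classes]
                all_scores.append(sc[:, col])
                all_labels.append(truth)

    report_stats = classification_report(cm, classes)
    report = EvalReport(
        classes=classes,
        accuracy_mean=float(np.mean(fold_accs)),
        accuracy_sd=float(np.std(fold_accs)),
        fold_accuracies=fold_accs,
        confusion=cm,
        per_class=report_stats["per_class"],
    )
    if collect_scores:
        return report, (np.vstack(all_scores), np.concatenate(all_labels))
    return report


def bootstrap_roc(scores: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
                  ci: float = 0.95, seed: int = 0) -> dict:
    """One-vs-rest ROC curves with AUC and percentile bootstrap CIs.

    ``scores`` is (n_samples, n_classes) in sorted class order (or 1D for a
    binary positive-class score). Bootstrap resamples are stratified by class
    so every resample contains both positives and negatives; the macro AUC is
    the unweighted mean of per-class AUCs.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    classes = sorted(np.unique(labels))
    if scores.ndim == 1:
        if len(classes) != 2:
            raise ValueError("1D scores require exactly two classes")
        scores = np.column_stack([-scores, scores])
    if scores.shape[1] != len(classes):
        raise ValueError("score columns must match the number of classes")

    alpha = (1.0 - ci) / 2.0
    per_class = {}
    for k, c in enumerate(classes):
        pos = (labels == c).astype(int)
        sc = scores[:, k]
        fpr, tpr, _ = roc_curve(pos, sc)
        point_auc = float(_auc(fpr, tpr))
        pos_idx = np.flatnonzero(pos == 1)
        neg_idx = np.flatnonzero(pos == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate([rng.choice(pos_idx, size=pos_idx.size, replace=True),
                                 rng.choice(neg_idx, size=neg_idx.size, replace=True)])
            f, t, _ = roc_curve(pos[bi], sc[bi])
            boots[b] = _auc(f, t)
        per_class[str(c)] = {
            "auc": point_auc,
            "ci_low": float(np.quantile(boots, alpha)),
            "ci_high": float(np.quantile(boots, 1.0 - alpha)),
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
        }
    macro = float(np.mean([v["auc"] for v in per_class.values()]))
    return {"per_class": per_class, "macro_auc": macro,
            "n_boot": n_boot, "ci": ci}
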