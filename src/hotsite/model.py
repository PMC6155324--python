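"""Gradient-boosted classification and evaluation.

The boosted-tree learner is scikit-learn's ``GradientBoostingClassifier``
(the boosting objective itself is consumed from the library, not
re-derived).  The published operating point — 2000 boosted trees,
max_depth 5, minimum split gain 0.005 — is the default; the split-gain
threshold maps to ``min_impurity_decrease``.  The backing library and
its version are recorded in every report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "DEFAULT_PARAMS",
    "confusion_metrics",
    "counts_from_predictions",
    "make_classifier",
    "train_model",
    "cross_validate",
    "roc_pr_curves",
    "grid_search",
]

#: Published operating point; everything else is the library default.
DEFAULT_PARAMS: dict = {
    "n_estimators": 2000,
    "max_depth": 5,
    "min_impurity_decrease": 0.005,
}

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _ratio(num: float, den: float) -> float:
    """NaN sentinel for undefined metrics (zero denominator)."""
    return num / den if den else float("nan")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """SPE, PRE, SEN, ACC, F1 and MCC from raw confusion counts.

    Exact integer arithmetic up to the final division; undefined metrics
    are NaN, never zero-substituted.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    spe = _ratio(tn, tn + fp)
    pre = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    acc = _ratio(tp + tn, counts.total)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _ratio(tp * tn - fp * fn, math.sqrt(denom2)) if denom2 else float("nan")
    return {"SPE": spe, "PRE": pre, "SEN": sen, "ACC": acc,
            "F1": f1, "MCC": mcc}


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            ) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def make_classifier(params: dict | None = None,
                    seed: int = 0) -> GradientBoostingClassifier:
    merged = dict(DEFAULT_PARAMS)
    merged.update(params or {})
    return GradientBoostingClassifier(random_state=seed, **merged)


def train_model(X, y, params: dict | None = None,
                seed: int = 0) -> GradientBoostingClassifier:
    """Fit the boosted-tree classifier; errors on a single-class set."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(params, seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def roc_pr_curves(scores, labels) -> dict:
    """ROC (trapezoidal AUC) and precision-recall (step AUC) curves."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to draw curves")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr": {"precision": prec.tolist(), "recall": rec.tolist()},
        "pr_auc": float(average_precision_score(labels, scores)),
    }


@dataclass
class EvalReport:
    counts: ConfusionCounts
    metrics: dict[str, float]
    roc_auc: float
    pr_auc: float
    per_repeat: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int | None = None
    threshold: float = DEFAULT_THRESHOLD
    library: str = f"scikit-learn {sklearn.__version__}"

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["counts"] = asdict(self.counts)
        text = json.dumps(payload, indent=2, sort_keys=True,
                          allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def cross_validate(X, y, folds: int = 10, repeats: int = 1, seed: int = 0,
                   params: dict | None = None,
                   threshold: float = DEFAULT_THRESHOLD) -> EvalReport:
    """Repeated stratified k-fold CV; pooled out-of-fold predictions.

    Headline counts pool every repeat's out-of-fold calls, so the
    report's metrics are exactly recomputable from its own counts; AUCs
    are per-repeat pooled scores averaged over repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < folds:
        raise ValueError(f"n_samples={len(y)} < folds={folds}")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")
    per_repeat = []
    tp = tn = fp = fn = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + rep)
        oof = np.zeros(len(y))
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("a training fold contains a single class")
            clf = make_classifier(params, seed + rep)
            clf.fit(X[train_idx], y[train_idx])
            oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        pred = (oof >= threshold).astype(int)
        counts = counts_from_predictions(y, pred)
        rep_metrics = confusion_metrics(counts)
        rep_metrics["AUC"] = float(roc_auc_score(y, oof))
        rep_metrics["PR_AUC"] = float(average_precision_score(y, oof))
        per_repeat.append({"repeat": rep, "counts": asdict(counts),
                           **rep_metrics})
        tp += counts.TP
        tn += counts.TN
        fp += counts.FP
        fn += counts.FN
    pooled = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return EvalReport(
        counts=pooled,
        metrics=confusion_metrics(pooled),
        roc_auc=float(np.mean([r["AUC"] for r in per_repeat])),
        pr_auc=float(np.mean([r["PR_AUC"] for r in per_repeat])),
        per_repeat=per_repeat,
        params=dict(DEFAULT_PARAMS, **(params or {})),
        seed=seed,
        threshold=threshold,
    )


def grid_search(X, y, grid: dict[str, list] | None = None, folds: int = 10,
                seed: int = 0) -> tuple[dict, float]:
    """Optional grid search over {n_estimators, max_depth,
    min_impurity_decrease}; returns (best params, best CV accuracy)."""
    grid = grid or {
        "n_estimators": [500, 1000, 2000],
        "max_depth": [3, 5, 7],
        "min_impurity_decrease": [0.0, 0.005, 0.05],
    }
    from itertools import product
    best, best_acc = None, -1.0
    keys = sorted(grid)
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        report = cross_validate(X, y, folds=folds, seed=seed, params=params)
        acc = report.metrics["ACC"]
        if acc > best_acc:
            best, best_acc = params, acc
    return best, best_acc
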