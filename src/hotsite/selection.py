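"""Two-step feature selection.

Step 1: mRMR (mutual-information difference form, MID) ranks all
features; the top-50 seed the wrapper and the top-500 form the candidate
pool.  Step 2: a greedy initial triple from the top-50, then sequential
forward selection adding the candidate with the highest composite
criterion Rc = mean over repeated stratified 10-fold CV of
(ACC + SEN + SPE + AUC), stopping when no candidate strictly increases
Rc.  F-score and permutation-importance (PIMP) diagnostics accompany the
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import (confusion_metrics, counts_from_predictions,
                    make_classifier)

__all__ = [
    "SelectionResult",
    "mutual_information",
    "discretize",
    "mrmr_rank",
    "rc_score",
    "select_initial_triple",
    "sequential_forward_selection",
    "run_two_step",
    "f_score",
    "permutation_importance",
]

#: Classic mRMR discretization: 3 bins split at mean +/- std.
DEFAULT_N_BINS = 3


def discretize(x: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Integer codes for a 1-D feature.

    Already-discrete inputs (<= n_bins distinct values) are label-coded;
    continuous ones use mean +/- std boundaries for 3 bins, equal-width
    edges otherwise.  A constant column codes to a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    if n_bins == 3:
        mu, sd = x.mean(), x.std()
        edges = np.array([mu - sd, mu + sd])
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    return np.digitize(x, edges)


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a 2-D contingency table of counts."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())


def mutual_information(x, y, n_bins: int = DEFAULT_N_BINS) -> float:
    """Plug-in histogram estimate of I(x; y) in bits.

    ``x`` is discretized (see :func:`discretize`); ``y`` is treated as
    already discrete (binary label or discretized feature).  A constant
    ``x`` gives 0 by construction.
    """
    xd = discretize(np.asarray(x), n_bins)
    yd = np.asarray(y).astype(int)
    yd = np.searchsorted(np.unique(yd), yd)
    joint = np.zeros((xd.max() + 1, yd.max() + 1))
    np.add.at(joint, (xd, yd), 1.0)
    return _mi_from_joint(joint)


def _pairwise_mi_one_vs_many(xd_many: np.ndarray, xd_one: np.ndarray) -> np.ndarray:
    """MI of each row of ``xd_many`` (codes) against ``xd_one`` (codes)."""
    k1 = int(xd_many.max()) + 1 if xd_many.size else 1
    k2 = int(xd_one.max()) + 1
    n_feat, n = xd_many.shape
    flat = (np.arange(n_feat)[:, None] * (k1 * k2)
            + xd_many * k2 + xd_one[None, :]).ravel()
    counts = np.bincount(flat, minlength=n_feat * k1 * k2)
    joints = counts.reshape(n_feat, k1, k2)
    return np.array([_mi_from_joint(j) for j in joints])


def mrmr_rank(table: pd.DataFrame, labels, k: int,
              n_bins: int = DEFAULT_N_BINS) -> list[str]:
    """Greedy mRMR ranking (difference form): at each step pick the
    feature maximizing MI(f; y) − mean over selected of MI(f; s).

    The first pick is simply the most label-relevant feature.  Ties
    break by column order for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    names = list(table.columns)
    k = min(k, len(names))
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    xd = np.column_stack([discretize(X[:, j], n_bins)
                          for j in range(X.shape[1])]).T  # (n_feat, n)
    relevance = _pairwise_mi_one_vs_many(xd, np.searchsorted(np.unique(y), y))
    selected: list[int] = []
    redundancy_sum = np.zeros(len(names))
    remaining = np.ones(len(names), dtype=bool)
    for _ in range(k):
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))  # argmax takes the first max: tie -> column order
        selected.append(pick)
        remaining[pick] = False
        if remaining.any():
            redundancy_sum += _pairwise_mi_one_vs_many(xd, xd[pick])
    return [names[i] for i in selected]


def rc_score(feature_subset: list[str], table: pd.DataFrame, labels,
             n_repeats: int = 5, seed: int = 0, folds: int = 10,
             model_params: dict | None = None) -> float:
    """Composite criterion Rc in [0, 4]: mean over ``n_repeats`` runs of
    stratified ``folds``-fold CV of (ACC + SEN + SPE + AUC), each run
    scored on its pooled out-of-fold predictions."""
    if not feature_subset:
        raise ValueError("feature subset must be nonempty")
    X = table[list(feature_subset)].to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    totals = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + rep)
        oof = np.zeros(len(y))
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a fold's training part has a single class")
            clf = make_classifier(model_params, seed + rep)
            clf.fit(X[tr], y[tr])
            oof[te] = clf.predict_proba(X[te])[:, 1]
        m = confusion_metrics(counts_from_predictions(y, oof >= 0.5))
        auc = roc_auc_score(y, oof)
        totals.append(m["ACC"] + m["SEN"] + m["SPE"] + auc)
    return float(np.mean(totals))


@dataclass
class SelectionResult:
    mrmr_ranking: list[str]
    top50: list[str]
    top500: list[str]
    initial_triple: list[str]
    sfs_trajectory: list[tuple] = field(default_factory=list)
    final_subset: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            payload = json.load(fh)
        trajectory = []
        for feat, rc in payload["sfs_trajectory"]:
            trajectory.append((tuple(feat) if isinstance(feat, list)
                               else feat, rc))
        payload["sfs_trajectory"] = trajectory
        return cls(**payload)


def select_initial_triple(top50: list[str], table: pd.DataFrame, labels,
                          exhaustive: bool = False,
                          **rc_kwargs) -> tuple[list[str], float]:
    """Greedy forward pick of three seed features from the top-50 by Rc
    (best single, best pair extension, best triple extension).

    ``exhaustive=True`` scores every C(n,3) triple instead (slow;
    default is the tractable greedy search)."""
    if len(top50) < 3:
        raise ValueError("need at least 3 candidate features")
    if exhaustive:
        from itertools import combinations
        best, best_rc = None, -np.inf
        for triple in combinations(top50, 3):
            rc = rc_score(list(triple), table, labels, **rc_kwargs)
            if rc > best_rc:
                best, best_rc = list(triple), rc
        return best, best_rc
    current: list[str] = []
    rc = -np.inf
    for _ in range(3):
        best, best_rc = None, -np.inf
        for cand in top50:
            if cand in current:
                continue
            r = rc_score(current + [cand], table, labels, **rc_kwargs)
            if r > best_rc:
                best, best_rc = cand, r
        current.append(best)
        rc = best_rc
    return current, rc


def sequential_forward_selection(initial: list[str], pool: list[str],
                                 table: pd.DataFrame, labels,
                                 initial_rc: float | None = None,
                                 **rc_kwargs) -> tuple[list[str], list[tuple]]:
    """Add the argmax-Rc pool feature while it strictly increases Rc.

    Returns (final subset, trajectory) where the trajectory starts with
    the initial combination and then one (feature, Rc) entry per
    accepted addition; Rc values are non-decreasing by construction.
    Ties break by pool order (mRMR rank) for determinism.
    """
    current = list(initial)
    rc = (rc_score(current, table, labels, **rc_kwargs)
          if initial_rc is None else initial_rc)
    trajectory: list[tuple] = [(tuple(initial), rc)]
    candidates = [f for f in pool if f not in current]
    while candidates:
        best, best_rc = None, -np.inf
        for cand in candidates:
            r = rc_score(current + [cand], table, labels, **rc_kwargs)
            if r > best_rc:
                best, best_rc = cand, r
        if best_rc <= rc:
            break
        current.append(best)
        candidates.remove(best)
        rc = best_rc
        trajectory.append((best, rc))
    return current, trajectory


def run_two_step(table: pd.DataFrame, labels, top_m: int = 50,
                 pool: int = 500, **rc_kwargs) -> SelectionResult:
    """Full pipeline: mRMR ranking -> top-m seeds and top-``pool``
    candidates -> greedy triple -> sequential forward selection."""
    ranking = mrmr_rank(table, labels, max(top_m, pool))
    top50 = ranking[:top_m]
    top500 = ranking[:pool]
    triple, rc0 = select_initial_triple(top50, table, labels, **rc_kwargs)
    final, trajectory = sequential_forward_selection(
        triple, top500, table, labels, initial_rc=rc0, **rc_kwargs)
    return SelectionResult(mrmr_ranking=ranking, top50=top50, top500=top500,
                           initial_triple=triple, sfs_trajectory=trajectory,
                           final_subset=final)


def f_score(feature, labels) -> float:
    """Two-class F-score: between-class separation of the feature means
    over the summed within-class variances,

        F = ((m+ - m)^2 + (m- - m)^2) / (s+^2 + s-^2)

    with s^2 the unbiased within-class variances."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("F-score needs exactly two classes")
    xp, xn = x[y == classes.max()], x[y == classes.min()]
    m, mp, mn = x.mean(), xp.mean(), xn.mean()
    denom = xp.var(ddof=1) + xn.var(ddof=1)
    num = (mp - m) ** 2 + (mn - m) ** 2
    if denom == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / denom)


def permutation_importance(model, table: pd.DataFrame, labels,
                           n_perm: int = 50, seed: int = 0) -> pd.Series:
    """PIMP significance p-values per feature.

    Null importances come from refitting clones of ``model`` on
    label-permuted data; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    X = table.to_numpy(dtype=float)
    observed = np.asarray(model.feature_importances_)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(observed))
    for _ in range(n_perm):
        perm = rng.permutation(y)
        null_model = clone(model)
        null_model.fit(X, perm)
        exceed += null_model.feature_importances_ >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return pd.Series(pvals, index=table.columns, name="pimp_pvalue")
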