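"""Cross-validated evaluation and confusion-matrix metrics.

The positive condition is >5-year survival (label 1), the negative
condition <5-year survival (label 0).  Reported measures:

    ACC = (TP + TN) / (P + N)      accuracy
    SEN = TP / P                   sensitivity (true positive rate)
    SPE = TN / N                   specificity (true negative rate)
    PRE = TP / (TP + FP)           precision (positive predictive value)
    F1  = 2 * PRE * SEN / (PRE + SEN)

``run_cv_experiment`` performs stratified k-fold cross-validation with a
fresh model per fold, pools the out-of-fold predictions into a single
confusion matrix for the headline metrics, and retains per-fold reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "kfold_split",
    "confusion_counts",
    "compute_metrics",
    "run_cv_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with >5-year survival as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class MetricsReport:
    """Pooled metrics plus optional per-fold breakdown."""

    counts: ConfusionCounts
    ACC: float
    SEN: float
    SPE: float
    PRE: float
    F1: float
    per_fold: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "counts": {"TP": self.counts.TP, "TN": self.counts.TN,
                       "FP": self.counts.FP, "FN": self.counts.FN,
                       "P": self.counts.P, "N": self.counts.N},
            "ACC": self.ACC, "SEN": self.SEN, "SPE": self.SPE,
            "PRE": self.PRE, "F1": self.F1,
        }
        if self.per_fold:
            d["per_fold"] = [
                {"fold": i, "ACC": r.ACC, "SEN": r.SEN, "SPE": r.SPE,
                 "PRE": r.PRE, "F1": r.F1}
                for i, r in enumerate(self.per_fold)
            ]
            accs = [r.ACC for r in self.per_fold]
            d["fold_ACC_mean"] = float(np.nanmean(accs))
            d["fold_ACC_sd"] = float(np.nanstd(accs, ddof=1)) if len(accs) > 1 else 0.0
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        c = self.counts
        lines = [
            f"confusion: TP={c.TP} TN={c.TN} FP={c.FP} FN={c.FN} (P={c.P}, N={c.N})",
            f"ACC={self.ACC:.4f}  SEN={self.SEN:.4f}  SPE={self.SPE:.4f}  "
            f"PRE={self.PRE:.4f}  F1={self.F1:.4f}",
        ]
        return "\n".join(lines)


def kfold_split(labels, k: int = 10, stratified: bool = True, seed: int = 0):
    """Disjoint test folds covering all indices exactly once.

    Stratified folds (the default) keep the class ratio per fold within
    one sample of the global ratio.  Returns a list of k index arrays.
    """
    y = np.asarray(labels).astype(int).ravel()
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        counts = np.bincount(y)
        if k > counts[counts > 0].min():
            raise ValueError(
                f"stratified k={k} exceeds the minority class count "
                f"({counts[counts > 0].min()})"
            )
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((n, 1)), y)]


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with label 1 (>5-year survival) as positive."""
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if yt.size != yp.size:
        raise ValueError(f"length mismatch: {yt.size} vs {yp.size}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts, per_fold: list | None = None,
                    predictions: pd.DataFrame | None = None) -> MetricsReport:
    """ACC/SEN/SPE/PRE/F1 from confusion counts; NaN on empty denominators."""
    acc = _safe_div(counts.TP + counts.TN, counts.total, "ACC")
    sen = _safe_div(counts.TP, counts.P, "SEN")
    spe = _safe_div(counts.TN, counts.N, "SPE")
    pre = _safe_div(counts.TP, counts.TP + counts.FP, "PRE")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        if not (np.isnan(pre) or np.isnan(sen)):
            warnings.warn("F1 undefined (PRE + SEN = 0); reporting NaN",
                          RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return MetricsReport(counts=counts, ACC=acc, SEN=sen, SPE=spe, PRE=pre,
                         F1=f1, per_fold=per_fold or [], predictions=predictions)


def run_cv_experiment(X, y, model_factory, k: int = 10, stratified: bool = True,
                      seed: int = 0, ids=None) -> MetricsReport:
    """Stratified k-fold cross-validation of a classifier.

    Parameters
    ----------
    X : sequence of examples (FRPs for the LSTM, feature vectors for the SVM)
    y : binary labels, 1 = >5-year survival
    model_factory : callable -> object with ``fit(X, y)`` and ``predict(X)``
        Called once per fold so every fold trains a fresh model.
    ids : optional per-example identifiers for the prediction table.

    Returns the report built from the pooled out-of-fold confusion counts;
    ``per_fold`` holds one report per fold and ``predictions`` the
    per-example out-of-fold prediction table.
    """
    y = np.asarray(y).astype(int).ravel()
    n = y.size
    if ids is None:
        ids = [str(i) for i in range(n)]
    folds = kfold_split(y, k=k, stratified=stratified, seed=seed)

    y_pred = np.full(n, -1, dtype=int)
    fold_of = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    per_fold = []
    index = np.arange(n)
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(index, test_idx)
        model = model_factory()
        model.fit(_take(X, train_idx), y[train_idx])
        pred = np.asarray(model.predict(_take(X, test_idx))).astype(int).ravel()
        y_pred[test_idx] = pred
        fold_of[test_idx] = fi
        if hasattr(model, "predict_scores"):
            scores[test_idx] = model.predict_scores(_take(X, test_idx))[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_fold.append(compute_metrics(confusion_counts(y[test_idx], pred)))

    assert (y_pred >= 0).all(), "some samples were never assigned to a test fold"
    table = pd.DataFrame({
        "image_id": ids, "fold": fold_of, "true": y, "predicted": y_pred,
        "score": scores,
    })
    return compute_metrics(confusion_counts(y, y_pred), per_fold=per_fold,
                           predictions=table)


def _take(X, idx):
    if isinstance(X, np.ndarray):
        return X[idx]
    return [X[i] for i in idx]
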