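"""Classification metrics and the repeated random-split protocol.

Binary metrics are the usual accuracy / sensitivity / specificity from
TP, FP, TN, FN counts.  Ternary metrics are per-class precision (over the
predicted-as-class column), recall (over the true-class row), their harmonic
mean F1, and trace-over-total accuracy.  Evaluation uses repeated random
splits: per repeat, a fixed fraction of the minority class is sampled, an
equal count from every other class joins it to form a balanced training
set, a validation fraction is carved from the training pool, and everything
unselected is the test set.  Means (and dispersion) over repeats are
reported; default 25 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "SplitPlan",
    "confusion_from_labels",
    "binary_metrics",
    "ternary_metrics",
    "make_splits",
    "aggregate",
]


@dataclass
class ConfusionCounts:
    """Either binary TP/FP/TN/FN or a square count matrix (rows = true)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix)
            if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
                raise ValueError("count matrix must be square")
            if np.any(self.matrix < 0):
                raise ValueError("counts must be nonnegative")
        else:
            for c in (self.tp, self.fp, self.tn, self.fn):
                if c < 0:
                    raise ValueError("counts must be nonnegative")


def confusion_from_labels(y_true, y_pred, n_classes: int | None = None) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    if n_classes == 2:
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    mat = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[t, p] += 1
    return ConfusionCounts(matrix=mat)


def binary_metrics(counts: ConfusionCounts) -> tuple:
    """(accuracy, sensitivity, specificity)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    if total == 0:
        raise ZeroDivisionError("accuracy undefined: no samples")
    if tp + fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    if tn + fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative samples")
    return ((tp + tn) / total, tp / (tp + fn), tn / (tn + fp))


def ternary_metrics(counts: ConfusionCounts) -> dict:
    """Per-class precision/recall/F1 plus trace-over-total accuracy."""
    if counts.matrix is None:
        raise ValueError("ternary metrics need a count matrix")
    mat = counts.matrix.astype(float)
    n = mat.shape[0]
    out = {"per_class": []}
    for c in range(n):
        col = mat[:, c].sum()   # predicted as class c (T_c + cross-class terms)
        row = mat[c, :].sum()   # true class c
        if col == 0:
            raise ZeroDivisionError(f"precision undefined for class {c}: nothing predicted")
        if row == 0:
            raise ZeroDivisionError(f"recall undefined for class {c}: no true samples")
        prec = mat[c, c] / col
        rec = mat[c, c] / row
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        out["per_class"].append({"precision": prec, "recall": rec, "f1": f1})
    out["accuracy"] = float(np.trace(mat) / mat.sum())
    return out


@dataclass
class SplitPlan:
    """Repeated balanced random-split protocol.

    Defaults match the fMRI protocol: 70% of the minority class (plus an
    equal majority count) trains, 10% of the training pool validates, the
    rest tests; 25 repeats.  The MRI protocol uses minority_fraction 0.90.
    """

    n_repeats: int = 25
    minority_fraction: float = 0.70
    validation_fraction: float = 0.10

    def __post_init__(self):
        if not (0 < self.minority_fraction <= 1):
            raise ValueError("minority_fraction must be in (0, 1]")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")


def make_splits(labels, plan: SplitPlan, seed: int = 0) -> list:
    """Per repeat: (train, val, test) index arrays; disjoint, seed-determined."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 subjects")
    n_take = int(np.floor(plan.minority_fraction * counts.min()))
    if n_take < 1:
        raise ValueError("minority fraction selects no subjects")

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(plan.n_repeats):
        train_pool = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            train_pool.append(rng.choice(idx, size=n_take, replace=False))
        train_pool = np.concatenate(train_pool)
        rng.shuffle(train_pool)
        n_val = int(np.floor(plan.validation_fraction * len(train_pool)))
        val = np.sort(train_pool[:n_val])
        train = np.sort(train_pool[n_val:])
        test = np.sort(np.setdiff1d(np.arange(len(labels)), train_pool))
        if len(test) == 0:
            raise ValueError("plan leaves an empty test set")
        splits.append((train, val, test))
    return splits


def aggregate(run_metrics, scores=None, labels=None) -> dict:
    """Mean and sd of each metric over repeats; optional per-run trapezoidal AUC.

    ``run_metrics``: list of dicts (or list of floats for a single metric).
    ``scores``/``labels``: optional per-run positive-class scores and true
    labels from which AUC is computed per run and averaged.
    """
    if len(run_metrics) == 0:
        raise ValueError("no repeats to aggregate")
    if not isinstance(run_metrics[0], dict):
        run_metrics = [{"metric": float(v)} for v in run_metrics]
    keys = run_metrics[0].keys()
    out = {}
    for key in keys:
        vals = np.array([m[key] for m in run_metrics], dtype=float)
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    if scores is not None and labels is not None:
        aucs = [roc_auc_score(y, s) for y, s in zip(labels, scores)]
        out["auc"] = {"mean": float(np.mean(aucs)), "sd": float(np.std(aucs))}
    return out
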