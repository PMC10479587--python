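"""Multiclass metric conventions for the three-disease problem.

The confusion matrix is oriented rows = predicted ("output class"),
columns = true ("target class"), in the fixed class order (MCD, MN, TBMN).
Accuracy is the fraction correct; precision/recall are macro-averaged
(unweighted over classes); the F1 score is the harmonic mean of the macro
precision and macro recall, each first rounded to two decimals — the
rounding chain under which the reported reference values reproduce exactly.
All values are percentages.
"""

from __future__ import annotations

import numpy as np

from .classify import BFE_CLASSES


def confusion(y_true, y_pred, classes=BFE_CLASSES) -> np.ndarray:
    """3x3 counts, entry (i, j) = predicted class i with true class j."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label: {t!r} / {p!r}")
        m[index[p], index[t]] += 1
    return m


def accuracy(m: np.ndarray) -> float:
    """100 * trace / total."""
    m = np.asarray(m)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(m) / total


def per_class_recall(m: np.ndarray) -> np.ndarray:
    """Per-class recall %, i.e. the column-wise diagonal fractions."""
    m = np.asarray(m, dtype=np.float64)
    col = m.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(col > 0, np.diag(m) / col, 0.0)
    return 100.0 * r


def per_class_precision(m: np.ndarray) -> np.ndarray:
    """Per-class precision %, i.e. the row-wise diagonal fractions."""
    m = np.asarray(m, dtype=np.float64)
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row > 0, np.diag(m) / row, 0.0)
    return 100.0 * p


def macro_precision_recall(m: np.ndarray) -> tuple[float, float]:
    """Unweighted means of the per-class precisions and recalls (%)."""
    return float(per_class_precision(m).mean()), float(per_class_recall(m).mean())


def f1_from_macros(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of macro precision and recall (%), two-decimal chain.

    Both inputs are rounded to two decimals before combining, matching the
    printed-report convention; P = R = 0 -> 0.
    """
    p = round(precision_pct, 2)
    r = round(recall_pct, 2)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def summarize(m: np.ndarray, level: str = "glomerular") -> dict:
    """All reported metrics for one confusion matrix, as a JSON-ready dict."""
    prec, rec = macro_precision_recall(m)
    return {
        "level": level,
        "confusion": np.asarray(m).tolist(),
        "accuracy": round(accuracy(m), 2),
        "per_class": {
            c: {"recall": round(r, 2), "precision": round(p, 2)}
            for c, r, p in zip(BFE_CLASSES, per_class_recall(m), per_class_precision(m))
        },
        "macro_precision": round(prec, 2),
        "macro_recall": round(rec, 2),
        "f1": round(f1_from_macros(prec, rec), 2),
    }
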