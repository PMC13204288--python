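"""Multi-class evaluation machinery.

Confusion-matrix metrics (per-class sensitivity / specificity / PPV / NPV /
balanced accuracy / F1 via one-vs-rest collapse), multiclass Cohen's kappa,
and one-vs-rest ROC analysis with interpolation of sensitivity onto a fixed
specificity grid so that curves from different resampling iterations can be
aggregated point-wise.  Macro-average curves are the unweighted mean of the
per-class interpolated sensitivities; micro-average curves pool all binary
labels and scores into one array first.

Division-by-zero cells (e.g. sensitivity of a class with no true members)
yield NaN markers, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve


class MetricsError(ValueError):
    pass


def default_specificity_grid(n_points: int = 101) -> np.ndarray:
    """Fixed shared grid of specificities (0.00 .. 1.00)."""
    return np.linspace(0.0, 1.0, n_points)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence
) -> pd.DataFrame:
    """Square count matrix; cell (i, j) counts true-i predicted-j."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise MetricsError("y_true and y_pred length mismatch")
    classes = list(class_order)
    idx = {c: k for k, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise MetricsError(f"labels outside class order: {sorted(unknown)[:3]}")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return pd.DataFrame(cm, index=classes, columns=classes)


def per_class_metrics(cm: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest per-class metrics from a square confusion matrix.

    balanced accuracy = (sensitivity + specificity) / 2.  Undefined ratios
    (0/0) are NaN.
    """
    m = cm.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise MetricsError("confusion matrix must be square")
    total = m.sum()
    tp = np.diag(m)
    fn = m.sum(axis=1) - tp
    fp = m.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _ratio(num, den):
        den = np.asarray(den, dtype=float)
        out = np.full(den.shape, np.nan)
        ok = den > 0
        out[ok] = np.asarray(num, dtype=float)[ok] / den[ok]
        return out

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    bal = (sens + spec) / 2.0
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    return pd.DataFrame(
        {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "balanced_accuracy": bal,
            "f1": f1,
        },
        index=cm.index,
    )


def accuracy(cm: pd.DataFrame) -> float:
    m = cm.to_numpy(dtype=float)
    tot = m.sum()
    if tot == 0:
        raise MetricsError("empty confusion matrix")
    return float(np.trace(m) / tot)


def cohens_kappa(cm: pd.DataFrame) -> float:
    """Chance-corrected agreement from row/column marginals.

    kappa = (p_o - p_e) / (1 - p_e); when p_e = 1 the value is 1 for perfect
    agreement and NaN otherwise.
    """
    m = cm.to_numpy(dtype=float)
    tot = m.sum()
    if tot == 0:
        raise MetricsError("empty confusion matrix")
    p_o = np.trace(m) / tot
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / tot**2
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class ROCCurve:
    """Sensitivity interpolated onto a fixed, shared specificity grid."""

    specificity: np.ndarray
    sensitivity: np.ndarray
    auc: float


def ovr_roc_interpolated(
    y_bin: Sequence[int], scores: Sequence[float], grid: np.ndarray | None = None
) -> ROCCurve:
    """Empirical one-vs-rest ROC interpolated onto the specificity grid.

    Tied scores are threshold-grouped (standard empirical ROC).  The curve
    is evaluated along the ROC polyline: a grid point hitting a vertical
    segment exactly takes the segment's top (so perfectly separating scores
    give sensitivity 1 on the whole grid and AUC 1), and points between two
    distinct specificities interpolate linearly along the connecting
    segment.  The AUC is the trapezoid of the interpolated curve over
    1 - specificity.
    """
    if grid is None:
        grid = default_specificity_grid()
    y = np.asarray(y_bin, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise MetricsError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    # evaluate the ROC polyline at each grid false-positive rate: a vertical
    # segment contributes its top when hit exactly; between distinct FPRs the
    # segment runs from the top of the left run to the bottom of the right run
    xs, first_idx = np.unique(fpr, return_index=True)
    last_idx = np.r_[first_idx[1:] - 1, len(fpr) - 1]
    tops = tpr[last_idx]
    bottoms = tpr[first_idx]
    fpr_grid = 1.0 - np.asarray(grid, float)
    sens_grid = np.empty_like(fpr_grid)
    pos = np.searchsorted(xs, fpr_grid)
    for i, (x, j) in enumerate(zip(fpr_grid, pos)):
        if j < len(xs) and xs[j] == x:
            sens_grid[i] = tops[j]
        else:
            lo, hi = j - 1, j
            t = (x - xs[lo]) / (xs[hi] - xs[lo])
            sens_grid[i] = tops[lo] + t * (bottoms[hi] - tops[lo])
    order = np.argsort(fpr_grid)
    auc = float(np.trapezoid(sens_grid[order], fpr_grid[order]))
    return ROCCurve(specificity=np.asarray(grid, float), sensitivity=sens_grid, auc=auc)


def macro_micro_curves(
    per_class_curves: Sequence[ROCCurve],
    pooled_truth: Sequence[int],
    pooled_scores: Sequence[float],
    grid: np.ndarray | None = None,
) -> tuple[ROCCurve, ROCCurve]:
    """Macro (unweighted mean of interpolated sensitivities) and micro
    (pooled one-vs-rest array) average curves on the shared grid."""
    if grid is None:
        grid = default_specificity_grid()
    if len(per_class_curves) < 2:
        raise MetricsError("need at least two per-class curves")
    for c in per_class_curves:
        if len(c.specificity) != len(grid) or not np.allclose(c.specificity, grid):
            raise MetricsError("per-class curves must share the grid")
    sens = np.mean([c.sensitivity for c in per_class_curves], axis=0)
    fpr_grid = 1.0 - np.asarray(grid)
    order = np.argsort(fpr_grid)
    macro = ROCCurve(
        specificity=np.asarray(grid, float),
        sensitivity=sens,
        auc=float(np.trapezoid(sens[order], fpr_grid[order])),
    )
    micro = ovr_roc_interpolated(pooled_truth, pooled_scores, grid)
    return macro, micro


def ovr_binary_arrays(
    y_true: Sequence, proba: np.ndarray, class_order: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-class (binary truth, score) arrays for micro averaging."""
    y = np.asarray(y_true)
    truths, scores = [], []
    for k, c in enumerate(class_order):
        truths.append((y == c).astype(int))
        scores.append(np.asarray(proba)[:, k])
    return np.concatenate(truths), np.concatenate(scores)


def evaluate_multiclass(
    y_true: Sequence,
    proba: np.ndarray,
    class_order: Sequence,
    grid: np.ndarray | None = None,
) -> dict:
    """One-stop evaluation: confusion, accuracy, kappa, per-class metrics,
    per-class interpolated ROC, macro/micro curves and AUCs."""
    if grid is None:
        grid = default_specificity_grid()
    proba = np.asarray(proba, dtype=float)
    classes = list(class_order)
    y_pred = [classes[k] for k in np.argmax(proba, axis=1)]
    cm = confusion_matrix(y_true, y_pred, classes)
    y = np.asarray(y_true)
    curves: dict[str, ROCCurve] = {}
    for k, c in enumerate(classes):
        y_bin = (y == c).astype(int)
        if 0 < y_bin.sum() < len(y_bin):
            curves[c] = ovr_roc_interpolated(y_bin, proba[:, k], grid)
    pooled_t, pooled_s = ovr_binary_arrays(y_true, proba, classes)
    macro, micro = macro_micro_curves(list(curves.values()), pooled_t, pooled_s, grid)
    return {
        "confusion": cm,
        "accuracy": accuracy(cm),
        "kappa": cohens_kappa(cm),
        "per_class": per_class_metrics(cm),
        "curves": curves,
        "macro_curve": macro,
        "micro_curve": micro,
        "per_class_auc": {c: curves[c].auc for c in curves},
        "macro_auc": macro.auc,
        "micro_auc": micro.auc,
    }
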