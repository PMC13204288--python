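"""Distillation of bootstrap runs into a robust feature signature.

The B per-iteration feature sets are aggregated into four per-feature
statistics — selection frequency, mean importance, median importance, and
PCA-weighted importance — plus a Combined Score (mean importance divided by
its standard deviation, a signal-to-noise ratio).  The signature is the set
of features passing both a Stability Filter (frequency > 80%) and a
Signal-to-Noise Filter (Combined Score > 1).

Importances are assembled into a B x F matrix with 0 for features a run did
not select (zero-fill convention; a selected-runs-only alternative is
available).  PCA weighting projects the B runs onto the first two principal
components of that matrix, measures each run's Euclidean distance d_i to
the component-space centroid, and weights runs by 1 / (1 + d_i / median(d))
(normalized to sum 1), down-weighting outlier iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .selection import BootstrapRunResult

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


def importance_matrix(
    runs: Sequence[BootstrapRunResult], zero_fill: bool = True
) -> pd.DataFrame:
    """B x F matrix of gain importances over the union of selected features.

    With ``zero_fill`` (default), a feature not selected in a run scores 0
    in that run; otherwise the cell is NaN and per-feature statistics are
    computed over selecting runs only.
    """
    if len(runs) == 0:
        raise SignatureError("at least one bootstrap run is required")
    feats: list[str] = []
    for r in runs:
        for f in r.selected_features:
            if f not in feats:
                feats.append(f)
    fill = 0.0 if zero_fill else np.nan
    M = np.full((len(runs), len(feats)), fill)
    col = {f: j for j, f in enumerate(feats)}
    for i, r in enumerate(runs):
        for f in r.selected_features:
            M[i, col[f]] = r.importances.get(f, 0.0)
    return pd.DataFrame(M, columns=feats)


def pca_weighted_importance(
    M: pd.DataFrame, n_components: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Per-run weights from PCA-space centrality, and weighted mean importances.

    Runs are projected onto the first ``n_components`` principal components
    of the importance matrix; d_i is the Euclidean distance to the centroid
    of the projected runs.  Weights w_i = 1 / (1 + d_i / median(d)) are
    normalized to sum 1 (uniform when all runs coincide).  A single run gets
    weight 1.
    """
    X = M.to_numpy(dtype=float)
    B = X.shape[0]
    if B == 1:
        return np.array([1.0]), pd.Series(X[0], index=M.columns)
    k = min(n_components, B - 1, X.shape[1])
    if k < 1 or np.allclose(X, X[0]):
        d = np.zeros(B)
    else:
        proj = PCA(n_components=k, svd_solver="full").fit_transform(X)
        d = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
    med = float(np.median(d))
    if med == 0.0:
        w = np.full(B, 1.0 / B)
    else:
        w = 1.0 / (1.0 + d / med)
        w = w / w.sum()
    weighted = pd.Series(w @ np.nan_to_num(X), index=M.columns)
    return w, weighted


def combined_score(mean_importance: float, std_importance: float) -> float:
    """Signal-to-noise ratio mean/std.

    std = 0 with positive mean -> +inf sentinel (passes the > 1 filter);
    std = 0 with zero mean -> 0.
    """
    if std_importance < 0:
        raise SignatureError("std_importance must be non-negative")
    if mean_importance < 0:
        raise SignatureError("mean_importance must be non-negative")
    if std_importance == 0.0:
        return float("inf") if mean_importance > 0 else 0.0
    return mean_importance / std_importance


def aggregate_importance(
    runs: Sequence[BootstrapRunResult], zero_fill: bool = True
) -> pd.DataFrame:
    """Per-feature aggregation table over the B bootstrap runs.

    Columns: frequency, mean_importance, median_importance, std_importance
    (population std over all B runs under the zero-fill convention),
    pca_weighted_importance, combined_score.
    """
    M = importance_matrix(runs, zero_fill=zero_fill)
    B = len(runs)
    selected_counts = pd.Series(0, index=M.columns, dtype=float)
    for r in runs:
        for f in set(r.selected_features):
            selected_counts[f] += 1
    freq = selected_counts / B
    mean = M.mean(axis=0, skipna=True)
    median = M.median(axis=0, skipna=True)
    std = M.std(axis=0, ddof=0, skipna=True)
    _, pca_imp = pca_weighted_importance(M.fillna(0.0))
    cs = pd.Series(
        [combined_score(float(m), float(s)) for m, s in zip(mean, std)], index=M.columns
    )
    return pd.DataFrame(
        {
            "frequency": freq,
            "mean_importance": mean,
            "median_importance": median,
            "std_importance": std,
            "pca_weighted_importance": pca_imp,
            "combined_score": cs,
        }
    )


@dataclass
class RobustSignature:
    features: list[str]
    freq_min: float
    score_min: float
    aggregate: pd.DataFrame

    def __len__(self) -> int:
        return len(self.features)


def apply_signature_filters(
    agg: pd.DataFrame,
    freq_min: float = 0.80,
    score_min: float = 1.0,
    order_by: str = "pca_weighted_importance",
) -> RobustSignature:
    """Stability Filter (frequency > freq_min) + Signal-to-Noise Filter
    (Combined Score > score_min); both strict.  Members are ordered by the
    configured importance metric, descending."""
    if len(agg) == 0:
        raise SignatureError("empty aggregation table")
    passing = agg[(agg["frequency"] > freq_min) & (agg["combined_score"] > score_min)]
    if len(passing) == 0:
        logger.warning(
            "no feature passed the stability (> %.2f) and signal-to-noise (> %.2f) "
            "filters; returning an empty signature", freq_min, score_min,
        )
    ordered = passing.sort_values(order_by, ascending=False, kind="stable")
    return RobustSignature(
        features=list(ordered.index),
        freq_min=freq_min,
        score_min=score_min,
        aggregate=agg,
    )
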