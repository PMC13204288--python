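"""Final Robust Model: repeated cross-validated evaluation and attribution.

The signature features feed a single gradient-boosted-tree classifier whose
performance is estimated by repeated stratified 5-fold cross-validation
(250 repetitions by default).  Within a repetition every subject is
predicted exactly once, out of fold; the pooled out-of-fold predictions
give one confusion matrix and one ROC analysis per repetition, and the
reported metrics are mean +/- SD over repetitions.  Exact tree Shapley
attributions quantify per-class global feature importance, and paired arm
comparisons (T1-only vs T2-only vs combined) use the two-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .metrics import default_specificity_grid, evaluate_multiclass
from .selection import DEFAULT_LEARNER_PARAMS, make_classifier


class FinalModelError(ValueError):
    pass


@dataclass(frozen=True)
class FinalModelConfig:
    k_folds: int = 5
    n_repetitions: int = 250
    learner_params: dict = field(default_factory=lambda: dict(DEFAULT_LEARNER_PARAMS))
    master_seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise FinalModelError("k_folds must be >= 2")
        if self.n_repetitions < 1:
            raise FinalModelError("n_repetitions must be >= 1")


@dataclass
class MetricsDistribution:
    """Per-repetition metric series plus pooled summaries."""

    accuracy: np.ndarray
    kappa: np.ndarray
    macro_auc: np.ndarray
    micro_auc: np.ndarray
    per_class_auc: pd.DataFrame          # repetitions x classes
    per_class_metrics_mean: pd.DataFrame  # classes x metric (mean over reps)
    per_class_metrics_std: pd.DataFrame
    pooled_confusion: pd.DataFrame
    class_order: list[str]

    @property
    def n_repetitions(self) -> int:
        return len(self.accuracy)

    def summary(self) -> pd.DataFrame:
        rows = {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
        }
        return pd.DataFrame(
            {
                "mean": {k: float(np.mean(v)) for k, v in rows.items()},
                "sd": {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in rows.items()},
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "summary": self.summary().to_dict(),
            "accuracy": self.accuracy.tolist(),
            "kappa": self.kappa.tolist(),
            "macro_auc": self.macro_auc.tolist(),
            "micro_auc": self.micro_auc.tolist(),
            "per_class_auc_mean": self.per_class_auc.mean().to_dict(),
            "per_class_metrics_mean": self.per_class_metrics_mean.to_dict(),
            "per_class_metrics_std": self.per_class_metrics_std.to_dict(),
            "pooled_confusion": self.pooled_confusion.to_dict(),
            "class_order": self.class_order,
        }


def repeated_cv_evaluate(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    config: FinalModelConfig,
    grid: np.ndarray | None = None,
) -> MetricsDistribution:
    """Repeated stratified k-fold evaluation of the final classifier.

    ``X`` must be complete (no missing cells) and restricted to the
    signature features.  Each repetition uses an independent stratified
    partition; out-of-fold probabilities are pooled into one confusion
    matrix and ROC analysis per repetition.
    """
    config.validate()
    if grid is None:
        grid = default_specificity_grid()
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise FinalModelError("X contains missing values")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < config.k_folds]
    if len(too_small):
        raise FinalModelError(
            f"class {too_small[0]!r} has fewer members than k_folds={config.k_folds}"
        )
    y_enc = np.searchsorted(classes, y)
    rng = np.random.default_rng(config.master_seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(config.n_repetitions, 2))

    acc, kap, mac, mic = [], [], [], []
    pc_auc_rows = []
    pc_metric_frames = []
    pooled_cm = None
    for rep in range(config.n_repetitions):
        s_fold, s_fit = (int(v) for v in rep_seeds[rep])
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=s_fold)
        proba = np.full((len(y), len(classes)), np.nan)
        for tr, te in skf.split(X, y_enc):
            clf = make_classifier(config.learner_params, s_fit, len(classes))
            clf.fit(X[tr], y_enc[tr])
            proba[te] = clf.predict_proba(X[te])
        assert not np.isnan(proba).any()
        ev = evaluate_multiclass(y, proba, list(classes), grid)
        acc.append(ev["accuracy"])
        kap.append(ev["kappa"])
        mac.append(ev["macro_auc"])
        mic.append(ev["micro_auc"])
        pc_auc_rows.append({str(c): a for c, a in ev["per_class_auc"].items()})
        pc_metric_frames.append(ev["per_class"])
        pooled_cm = ev["confusion"] if pooled_cm is None else pooled_cm + ev["confusion"]

    pc_stack = np.stack([f.to_numpy(dtype=float) for f in pc_metric_frames])
    template = pc_metric_frames[0]
    return MetricsDistribution(
        accuracy=np.asarray(acc),
        kappa=np.asarray(kap),
        macro_auc=np.asarray(mac),
        micro_auc=np.asarray(mic),
        per_class_auc=pd.DataFrame(pc_auc_rows),
        per_class_metrics_mean=pd.DataFrame(
            np.nanmean(pc_stack, axis=0), index=template.index, columns=template.columns
        ),
        per_class_metrics_std=pd.DataFrame(
            np.nanstd(pc_stack, axis=0, ddof=1) if len(pc_metric_frames) > 1
            else np.zeros_like(pc_stack[0]),
            index=template.index, columns=template.columns,
        ),
        pooled_confusion=pooled_cm,
        class_order=[str(c) for c in classes],
    )


def shapley_attributions(
    model, X: np.ndarray | pd.DataFrame, feature_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Global per-class feature importance as mean |Shapley attribution|.

    Uses exact tree Shapley values (additivity holds per sample and class:
    attributions + base value = model margin).  Returns features x classes.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    n_model_feats = booster.num_features()
    if X.shape[1] != n_model_feats:
        raise FinalModelError(
            f"X has {X.shape[1]} features but the model was fit on {n_model_feats}"
        )
    contribs = booster.predict(xgboost.DMatrix(X), pred_contribs=True)
    if contribs.ndim == 2:  # binary: single margin
        contribs = contribs[:, None, :]
    phi = contribs[:, :, :-1]  # drop bias column
    imp = np.abs(phi).mean(axis=0).T  # features x classes
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    cols = [f"class_{k}" for k in range(imp.shape[1])]
    return pd.DataFrame(imp, index=list(feature_names), columns=cols)


def shapley_additivity_residual(model, X: np.ndarray) -> float:
    """Max |sum(attributions) + base - margin| over samples and classes."""
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    dm = xgboost.DMatrix(np.asarray(X, dtype=float))
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    if contribs.ndim == 2:
        contribs = contribs[:, None, :]
        margins = margins.reshape(len(margins), 1)
    return float(np.abs(contribs.sum(axis=2) - margins).max())


def compare_model_metrics(
    metric_series_a: Sequence[float], metric_series_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank comparison of paired metric series.

    Pairs are matched by repetition (or bootstrap iteration) index;
    zero-difference pairs are dropped.  The statistic is W+ - W- (so
    swapping the series flips its sign); the p-value is exact for n <= 25
    with untied |differences| and a tie-corrected normal approximation
    otherwise.  All-zero differences give (0.0, 1.0).
    """
    a = np.asarray(metric_series_a, dtype=float)
    b = np.asarray(metric_series_b, dtype=float)
    if a.shape != b.shape:
        raise FinalModelError("paired series must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return statistic, float(res.pvalue)
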