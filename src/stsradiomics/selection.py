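"""Bootstrap-stable feature selection.

Each bootstrap iteration stratifies the cohort into a 70/30 train/test
split, runs a nested 5-fold cross-validation on the training partition to
choose the optimal feature-set size N_opt from a candidate grid (ranking
features by gradient-boosted-tree gain, truncating to N, then filtering
pairwise correlation > r_max), refits on the whole training partition, and
evaluates the resulting model on the untouched 30% with the one-vs-rest ROC
machinery.  Missing-sequence features are imputed per split with models fit
on the training partition only, so neither the ranking nor the imputer ever
sees a test row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .cohort import FeatureTable, SubjectRecord
from .impute import fit_imputer, impute
from .metrics import default_specificity_grid, evaluate_multiclass

logger = logging.getLogger(__name__)

# Moderate depth and shrinkage; strong column subsampling so that splits (and
# hence gain) are spread over redundant informative features rather than
# concentrating on one representative per block — the stability analysis
# depends on every consistently useful feature actually being used.
DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.3,
    "colsample_bytree": 0.3,
    "objective": "multi:softprob",
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
}

DEFAULT_N_GRID = (10, 20, 30, 50, 75, 100, 150, 200, 250, 300)


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionConfig:
    n_iterations: int = 250
    train_fraction: float = 0.70
    k_folds: int = 5
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    r_max: float = 0.90
    learner_params: dict = field(default_factory=lambda: dict(DEFAULT_LEARNER_PARAMS))
    master_seed: int = 0
    use_subtype_imputer: bool = True

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise SelectionError("n_iterations must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise SelectionError("train_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise SelectionError("k_folds must be >= 2")
        if len(self.n_grid) == 0 or list(self.n_grid) != sorted(self.n_grid):
            raise SelectionError("n_grid must be non-empty and ascending")
        if not 0.0 < self.r_max <= 1.0:
            raise SelectionError("r_max must lie in (0, 1]")


@dataclass
class BootstrapRunResult:
    iteration: int
    train_ids: list[str]
    test_ids: list[str]
    n_opt: int
    selected_features: list[str]
    importances: dict[str, float]
    accuracy: float
    kappa: float
    per_class_auc: dict[str, float]
    macro_auc: float
    micro_auc: float
    roc_sensitivities: dict[str, list[float]]  # per class, on the shared grid

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "n_opt": self.n_opt,
            "selected_features": self.selected_features,
            "importances": self.importances,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "roc_sensitivities": self.roc_sensitivities,
        }


def make_classifier(params: dict, seed: int, n_classes: int) -> XGBClassifier:
    p = dict(params)
    if n_classes <= 2:
        p.pop("objective", None)  # binary fallback; xgboost infers the objective
    return XGBClassifier(random_state=int(seed), **p)


def stratified_split(
    labels: Sequence, train_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Per-class 70/30-style split with largest-remainder rounding.

    Returns positional indices.  Every class must have at least 2 members so
    both partitions can be non-empty overall.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SelectionError("train_fraction must lie in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise SelectionError(f"class with < 2 members: {small[0]!r}")
    raw = counts * train_fraction
    n_train_per = np.floor(raw).astype(int)
    short = int(round(raw.sum())) - n_train_per.sum()
    order = np.argsort(-(raw - n_train_per), kind="stable")
    n_train_per[order[:short]] += 1
    train, test = [], []
    for c, n_tr in zip(classes, n_train_per):
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        train.extend(perm[:n_tr].tolist())
        test.extend(perm[n_tr:].tolist())
    return sorted(train), sorted(test)


def rank_features_by_gain(
    X: np.ndarray, y: Sequence, learner_params: dict, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rank columns by average gain of a gradient-boosted-tree fit.

    Returns (order, gains): ``order`` is column indices in descending gain,
    features never used by any tree get gain 0 and rank after all used
    features, ties broken by column order.  Deterministic given
    (data, params, seed).
    """
    y_arr = np.asarray(y)
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise SelectionError("need at least two classes to rank features")
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise SelectionError("missing values must be imputed before ranking")
    clf = make_classifier(learner_params, seed, len(classes))
    y_enc = np.searchsorted(classes, y_arr)
    clf.fit(X, y_enc)
    score = clf.get_booster().get_score(importance_type="gain")
    gains = np.zeros(X.shape[1])
    for k, v in score.items():
        gains[int(k[1:])] = v
    order = np.lexsort((np.arange(X.shape[1]), -gains))
    return order, gains


def decorrelate(
    ranking: Sequence[int], X: np.ndarray, r_max: float
) -> list[int]:
    """Greedy multicollinearity filter in rank order.

    A feature is dropped iff its absolute Pearson correlation with an
    already-kept feature exceeds ``r_max`` (strict).  Constant columns have
    undefined correlation and are kept.  Survivor order is preserved.
    """
    if len(ranking) == 0:
        raise SelectionError("ranking must be non-empty")
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    norms = np.sqrt((Z**2).sum(axis=0))
    kept: list[int] = []
    for f in ranking:
        if norms[f] == 0:
            kept.append(int(f))
            continue
        drop = False
        for k in kept:
            if norms[k] == 0:
                continue
            r = abs(float(Z[:, f] @ Z[:, k]) / (norms[f] * norms[k]))
            if r > r_max:
                drop = True
                break
        if not drop:
            kept.append(int(f))
    return kept


def _argmax_smallest(scores: Sequence[float]) -> int:
    """Index of the maximum; ties resolve to the earliest (smallest N)."""
    arr = np.asarray(scores, dtype=float)
    return int(np.argmax(arr))  # np.argmax returns the first maximum


def _macro_ovr_auc(y_true_enc: np.ndarray, proba: np.ndarray, n_classes: int) -> float:
    if n_classes == 2:
        return float(roc_auc_score(y_true_enc, proba[:, 1]))
    return float(
        roc_auc_score(
            y_true_enc, proba, multi_class="ovr", average="macro",
            labels=np.arange(n_classes),
        )
    )


def select_n_opt(
    X_train: np.ndarray,
    y_train: Sequence,
    config: SelectionConfig,
    seed: int,
) -> tuple[int, list[int], pd.DataFrame]:
    """Nested-CV choice of the feature-set size.

    For each outer fold the ranking is fit once on the fold's training part;
    for each candidate N the ranking is truncated to N, decorrelated, a model
    is fit on the fold-train restriction and scored by macro one-vs-rest AUC
    on the fold's validation part.  N_opt is the N with the best mean score
    (ties -> smallest N).  The final set is the decorrelated top-N_opt of a
    ranking refit on all of X_train.

    Returns (N_opt, selected column indices, per-N per-fold score table).
    """
    config.validate()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    y_enc = np.searchsorted(classes, y)
    n_grid = [n for n in config.n_grid if n <= X.shape[1]]
    if len(n_grid) < len(config.n_grid):
        logger.warning(
            "n_grid values above the feature count (%d) were truncated", X.shape[1]
        )
        if not n_grid:
            n_grid = [X.shape[1]]
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    scores = np.zeros((config.k_folds, len(n_grid)))
    for fold, (tr, va) in enumerate(skf.split(X, y_enc)):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        order, _ = rank_features_by_gain(X[tr], y[tr], config.learner_params, fold_seed)
        for j, n in enumerate(n_grid):
            sel = decorrelate(order[:n], X[tr], config.r_max)
            clf = make_classifier(config.learner_params, fold_seed, len(classes))
            clf.fit(X[np.ix_(tr, sel)], y_enc[tr])
            proba = clf.predict_proba(X[np.ix_(va, sel)])
            scores[fold, j] = _macro_ovr_auc(y_enc[va], proba, len(classes))
    mean_scores = scores.mean(axis=0)
    n_opt = n_grid[_argmax_smallest(mean_scores)]
    final_seed = int(rng.integers(0, 2**31 - 1))
    order, _ = rank_features_by_gain(X, y, config.learner_params, final_seed)
    selected = decorrelate(order[:n_opt], X, config.r_max)
    table = pd.DataFrame(scores, columns=n_grid)
    table.index.name = "outer_fold"
    return n_opt, selected, table


def run_bootstrap(
    table: FeatureTable,
    subjects: list[SubjectRecord],
    config: SelectionConfig,
    imputer_factory: Callable | None = None,
    grid: np.ndarray | None = None,
) -> list[BootstrapRunResult]:
    """Run the full B-iteration bootstrap selection experiment.

    Per-iteration seeds are derived deterministically from
    ``config.master_seed``.  Iteration failures are recorded and re-raised
    at the end with their iteration indices.
    """
    config.validate()
    if grid is None:
        grid = default_specificity_grid()
    if imputer_factory is None:
        imputer_factory = fit_imputer
    by_id = {s.subject_id: s for s in subjects}
    ids = table.subject_ids
    labels = np.asarray([by_id[i].subtype for i in ids])
    class_order = list(dict.fromkeys(labels))
    rng = np.random.default_rng(config.master_seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=(config.n_iterations, 3))
    has_missing = bool(table.values.isna().any().any())

    results: list[BootstrapRunResult] = []
    failures: list[tuple[int, Exception]] = []
    for b in range(config.n_iterations):
        s_split, s_sel, s_fit = (int(x) for x in iter_seeds[b])
        try:
            tr_idx, te_idx = stratified_split(labels, config.train_fraction, s_split)
            train_ids = [ids[i] for i in tr_idx]
            test_ids = [ids[i] for i in te_idx]
            if has_missing:
                model = imputer_factory(
                    table, subjects, train_ids, use_subtype=config.use_subtype_imputer
                )
                filled = impute(model, table, subjects)
            else:
                filled = table
            X = filled.values.to_numpy(dtype=float)
            fids = filled.feature_ids
            n_opt, sel, _ = select_n_opt(X[tr_idx], labels[tr_idx], config, s_sel)
            classes = np.unique(labels)
            y_enc = np.searchsorted(classes, labels)
            clf = make_classifier(config.learner_params, s_fit, len(classes))
            clf.fit(X[np.ix_(tr_idx, sel)], y_enc[tr_idx])
            proba = clf.predict_proba(X[np.ix_(te_idx, sel)])
            ev = evaluate_multiclass(labels[te_idx], proba, list(classes), grid)
            gains_score = clf.get_booster().get_score(importance_type="gain")
            importances = {
                fids[sel[int(k[1:])]]: float(v) for k, v in gains_score.items()
            }
            results.append(
                BootstrapRunResult(
                    iteration=b,
                    train_ids=train_ids,
                    test_ids=test_ids,
                    n_opt=n_opt,
                    selected_features=[fids[i] for i in sel],
                    importances=importances,
                    accuracy=ev["accuracy"],
                    kappa=ev["kappa"],
                    per_class_auc={str(c): a for c, a in ev["per_class_auc"].items()},
                    macro_auc=ev["macro_auc"],
                    micro_auc=ev["micro_auc"],
                    roc_sensitivities={
                        str(c): curve.sensitivity.tolist()
                        for c, curve in ev["curves"].items()
                    },
                )
            )
        except Exception as exc:  # recorded, re-raised collectively
            logger.error("bootstrap iteration %d failed: %s", b, exc)
            failures.append((b, exc))
    if failures:
        idx = [i for i, _ in failures]
        raise RuntimeError(
            f"{len(failures)} bootstrap iteration(s) failed: {idx}"
        ) from failures[0][1]
    return results
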