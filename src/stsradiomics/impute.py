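"""Mixed-model imputation of missing-sequence radiomic features.

Subjects missing an entire MRI sequence have every feature of that sequence
missing.  Each feature is modeled as a linear function of log tumor volume
with subtype fixed effects (reference-coded); when the same underlying
feature is replicated across imaging planes, the plane replicates of a
subject share a subject-level random intercept.  Models are fit on the
training partition only and missing cells are filled from the fixed-effect
linear predictor.

Because the covariates (log volume, subtype) are subject-level and block
missingness makes plane replicates balanced, the model has a closed-form
ANOVA-type solution: each feature's fixed effects come from least squares
on its own column (one batched solve per plane group), and the shared
subject random-intercept variance comes from the between/within
decomposition of the group residuals.  Groups degenerate to ordinary least
squares (random-intercept variance 0) when a subject contributes a single
observation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import FeatureTable, SubjectRecord

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class FeatureFit:
    intercept: float = np.nan
    volume_slope: float = np.nan
    subtype_offsets: dict[str, float] = field(default_factory=dict)
    random_intercept_variance: float = 0.0
    residual_variance: float = np.nan
    n_train_obs: int = 0
    fittable: bool = False


@dataclass
class ImputationModel:
    """Per-feature linear predictor records plus the class coding used."""

    fits: dict[str, FeatureFit]
    class_order: list[str]
    reference_class: str
    use_subtype: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_order": self.class_order,
                "reference_class": self.reference_class,
                "use_subtype": self.use_subtype,
                "fits": {k: asdict(v) for k, v in self.fits.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ImputationModel":
        d = json.loads(text)
        return cls(
            fits={k: FeatureFit(**v) for k, v in d["fits"].items()},
            class_order=d["class_order"],
            reference_class=d["reference_class"],
            use_subtype=d["use_subtype"],
        )


def _sibling_groups(meta: pd.DataFrame, group_planes: bool) -> list[list[str]]:
    """Columns replicated across planes (same sequence/family/base name/distance)."""
    if not group_planes:
        return [[fid] for fid in meta.index]
    key = meta.apply(
        lambda r: (
            r["sequence"],
            r["family"],
            r.name.split(f"_{r['plane']}_", 1)[-1] if f"_{r['plane']}_" in r.name else r.name,
        ),
        axis=1,
    )
    groups: dict[object, list[str]] = {}
    for fid, k in key.items():
        groups.setdefault(k, []).append(fid)
    return list(groups.values())


def _design_matrix(
    subjects: list[SubjectRecord], ids: list[str], class_order: list[str], use_subtype: bool
) -> tuple[np.ndarray, list[str]]:
    by_id = {s.subject_id: s for s in subjects}
    logv = np.array([np.log(by_id[i].tumor_volume) for i in ids])
    cols = [np.ones(len(ids)), logv]
    names = ["intercept", "log_volume"]
    if use_subtype:
        for c in class_order[1:]:
            cols.append(np.array([1.0 if by_id[i].subtype == c else 0.0 for i in ids]))
            names.append(c)
    return np.column_stack(cols), names


def fit_imputer(
    table: FeatureTable,
    subjects: list[SubjectRecord],
    train_ids: list[str],
    group_planes: bool = True,
    use_subtype: bool = True,
) -> ImputationModel:
    """Fit per-feature volume/subtype linear predictors on training rows only.

    Features with fewer than p + 2 non-missing training observations are
    flagged unfittable (an error is raised only if imputation is later
    requested for them).  With ``use_subtype=False`` a label-free,
    volume-only imputer is fit instead (no outcome information is used at
    prediction time).
    """
    missing = set(train_ids) - set(table.subject_ids)
    if missing:
        raise ImputationError(f"train ids absent from table: {sorted(missing)[:3]}")
    by_id = {s.subject_id: s for s in subjects}
    class_order = list(dict.fromkeys(s.subtype for s in subjects))
    # classes represented in training rows; only their offsets are estimable
    train_classes = list(dict.fromkeys(by_id[i].subtype for i in train_ids))
    if use_subtype and len(train_classes) == 1:
        # single-subtype cohort: no contrast estimable, collapse to volume-only
        effective_subtype = False
    else:
        effective_subtype = use_subtype

    V = table.values.loc[list(train_ids)]
    fits: dict[str, FeatureFit] = {}
    for group in _sibling_groups(table.feature_meta, group_planes):
        sub = V[group].to_numpy()  # n_train x k plane-replicate columns
        obs_rows = ~np.isnan(sub).all(axis=1)
        # block missingness: a subject has all or none of the group observed
        row_ids = [tid for tid, keep in zip(train_ids, obs_rows) if keep]
        if not row_ids:
            for fid in group:
                fits[fid] = FeatureFit()
            continue
        sub = sub[obs_rows]
        if np.isnan(sub).any():
            raise ImputationError(
                f"partially missing plane block in group containing {group[0]}"
            )
        classes_here = [c for c in class_order if c in {by_id[i].subtype for i in row_ids}]
        use_st = effective_subtype and len(classes_here) > 1
        X, names = _design_matrix(subjects, row_ids, classes_here, use_st)
        p = X.shape[1]
        n_subj, k = sub.shape
        if n_subj < p + 2:
            for fid in group:
                fits[fid] = FeatureFit(n_train_obs=n_subj)
            continue
        # column-specific fixed effects (one least-squares solve for the group)
        beta, *_ = np.linalg.lstsq(X, sub, rcond=None)  # p x k
        resid = sub - X @ beta
        # shared subject random intercept from the residual decomposition
        dof_between = max(n_subj - p, 1)
        if k > 1:
            rbar = resid.mean(axis=1)
            within = resid - rbar[:, None]
            sigma_e2 = float((within**2).sum()) / (n_subj * (k - 1))
            sigma_b2 = max(0.0, float(rbar @ rbar) / dof_between - sigma_e2 / k)
        else:
            sigma_e2 = float((resid**2).sum()) / dof_between
            sigma_b2 = 0.0
        for j, fid in enumerate(group):
            offsets = {c: 0.0 for c in classes_here}
            if use_st:
                for name, b in zip(names[2:], beta[2:, j]):
                    offsets[name] = float(b)
            fits[fid] = FeatureFit(
                intercept=float(beta[0, j]),
                volume_slope=float(beta[1, j]),
                subtype_offsets=offsets,
                random_intercept_variance=sigma_b2,
                residual_variance=sigma_e2,
                n_train_obs=n_subj,
                fittable=True,
            )
    if use_subtype:
        logger.warning(
            "imputer uses the subject's subtype label at prediction time; "
            "set use_subtype=False for a label-free (volume-only) imputer"
        )
    return ImputationModel(
        fits=fits,
        class_order=class_order,
        reference_class=train_classes[0],
        use_subtype=effective_subtype,
    )


def impute(
    model: ImputationModel, table: FeatureTable, subjects: list[SubjectRecord]
) -> FeatureTable:
    """Fill every missing cell from the fitted fixed-effect predictor.

    value = intercept + volume_slope * log(V) + subtype_offset.  Non-missing
    cells are untouched; the result has no missing cells.  Idempotent.
    """
    out = table.copy()
    by_id = {s.subject_id: s for s in subjects}
    vals = out.values
    logv = pd.Series(
        {sid: np.log(by_id[sid].tumor_volume) for sid in vals.index}, dtype=float
    )
    subtype = pd.Series({sid: by_id[sid].subtype for sid in vals.index})
    miss_cols = vals.columns[vals.isna().any(axis=0)]
    for fid in miss_cols:
        fit = model.fits.get(fid)
        if fit is None or not fit.fittable:
            raise ImputationError(f"feature {fid!r} is unfittable but needs imputation")
        rows = vals.index[vals[fid].isna()]
        if model.use_subtype:
            unseen = set(subtype.loc[rows]) - set(fit.subtype_offsets)
            if unseen:
                raise ImputationError(
                    f"subtype {sorted(unseen)[0]!r} unseen when fitting {fid!r}"
                )
            offsets = subtype.loc[rows].map(fit.subtype_offsets).to_numpy(float)
        else:
            offsets = 0.0
        vals.loc[rows, fid] = (
            fit.intercept + fit.volume_slope * logv.loc[rows].to_numpy() + offsets
        )
    return out
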