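"""End-to-end orchestration of the three-arm experiment.

For each arm (T1-only, T2-only, combined T1+T2) the pipeline runs the
bootstrap selection stage, aggregates per-iteration importances, applies
the stability and signal-to-noise filters to obtain the arm's robust
signature, and evaluates the Final Robust Model by repeated stratified
cross-validation on the signature features.  Arms are then compared
pairwise with the Wilcoxon signed-rank test on the per-iteration /
per-repetition accuracy and macro-AUC series.

A single master seed deterministically spawns one seed per (arm, stage) via
a counter scheme, so every stage is independently replayable.  The final
CV stage requires a complete matrix; the pipeline imputes the full table
once (imputer fit on all subjects) before that stage, while the bootstrap
stage keeps its strict per-split, train-only imputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, FeatureTable, SubjectRecord, generate_cohort
from .final import (
    FinalModelConfig,
    compare_model_metrics,
    repeated_cv_evaluate,
    shapley_attributions,
)
from .impute import fit_imputer, impute
from .io import load_feature_table, load_subjects, write_feature_table, write_subjects
from .selection import BootstrapRunResult, SelectionConfig, run_bootstrap
from .signature import aggregate_importance, apply_signature_filters

logger = logging.getLogger(__name__)

ARMS = ("T1", "T2", "T1+T2")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    arms: tuple[str, ...] = ARMS
    values_csv: str | None = None
    meta_csv: str | None = None
    subjects_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    freq_min: float = 0.80
    score_min: float = 1.0
    order_by: str = "pca_weighted_importance"
    final: FinalModelConfig = field(default_factory=FinalModelConfig)
    output_dir: str = "results"
    master_seed: int = 0

    def validate(self) -> None:
        if len(self.arms) == 0:
            raise PipelineError("at least one arm is required")
        bad = set(self.arms) - set(ARMS)
        if bad:
            raise PipelineError(f"unknown arms: {sorted(bad)}")
        has_files = self.values_csv and self.meta_csv and self.subjects_csv
        if not has_files and self.cohort_spec is None:
            raise PipelineError("either input CSV paths or a cohort spec is required")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = raw.pop("cohort_spec", None)
        sel = raw.pop("selection", None)
        fin = raw.pop("final", None)
        if spec is not None:
            for key in ("class_names", "class_counts"):
                if key in spec:
                    spec[key] = tuple(spec[key])
            spec = CohortSpec(**spec)
        if sel is not None:
            if "n_grid" in sel:
                sel["n_grid"] = tuple(sel["n_grid"])
            sel = SelectionConfig(**sel)
        if fin is not None:
            fin = FinalModelConfig(**fin)
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(
            cohort_spec=spec,
            selection=sel or SelectionConfig(),
            final=fin or FinalModelConfig(),
            **raw,
        )


def _stage_seed(master_seed: int, arm: str, stage: str) -> int:
    """Deterministic counter-style seed for one (arm, stage)."""
    h = hashlib.sha256(f"{master_seed}:{arm}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class ArmResult:
    arm: str
    runs: list[BootstrapRunResult]
    aggregate: pd.DataFrame
    signature_features: list[str]
    final_metrics: object | None  # MetricsDistribution, None if signature empty
    attributions: pd.DataFrame | None = None  # feature x class mean |Shapley|

    def bootstrap_series(self, metric: str) -> np.ndarray:
        return np.asarray([getattr(r, metric) for r in self.runs])


def _arm_table(table: FeatureTable, arm: str) -> FeatureTable:
    sequences = ("T1", "T2") if arm == "T1+T2" else (arm,)
    return table.subset_sequences(sequences)


def run_experiment(
    config: ExperimentConfig,
    table: FeatureTable | None = None,
    subjects: list[SubjectRecord] | None = None,
) -> dict:
    """Run every configured arm end to end and compare them pairwise.

    Returns a bundle: per-arm results, cross-arm Wilcoxon tables for the
    bootstrap and final stages, and a manifest (config hash, seeds,
    versions).  Fails with the arm name and stage on any arm error.
    """
    config.validate()
    if table is None or subjects is None:
        if config.values_csv:
            table = load_feature_table(config.values_csv, config.meta_csv)
            subjects = load_subjects(config.subjects_csv)
        else:
            subjects, table = generate_cohort(
                config.cohort_spec, _stage_seed(config.master_seed, "*", "cohort")
            )
    by_id = {s.subject_id: s for s in subjects}
    labels = np.asarray([by_id[i].subtype for i in table.subject_ids])

    arm_results: dict[str, ArmResult] = {}
    for arm in config.arms:
        sub_table = _arm_table(table, arm)
        stage = "bootstrap"
        try:
            sel_cfg = SelectionConfig(
                **{**asdict_shallow(config.selection),
                   "master_seed": _stage_seed(config.master_seed, arm, "bootstrap")}
            )
            runs = run_bootstrap(sub_table, subjects, sel_cfg)
            stage = "signature"
            agg = aggregate_importance(runs)
            sig = apply_signature_filters(
                agg, config.freq_min, config.score_min, config.order_by
            )
            stage = "final"
            final_metrics = None
            attributions = None
            if len(sig.features) > 0:
                if sub_table.values.isna().any().any():
                    model = fit_imputer(
                        sub_table, subjects, sub_table.subject_ids,
                        use_subtype=config.selection.use_subtype_imputer,
                    )
                    filled = impute(model, sub_table, subjects)
                else:
                    filled = sub_table
                fin_cfg = FinalModelConfig(
                    **{**asdict_shallow(config.final),
                       "master_seed": _stage_seed(config.master_seed, arm, "final")}
                )
                final_metrics = repeated_cv_evaluate(
                    filled.values[sig.features], labels, fin_cfg
                )
                # global attributions from one fit on the full cohort
                from .selection import make_classifier

                classes = np.unique(labels)
                clf = make_classifier(
                    fin_cfg.learner_params,
                    _stage_seed(config.master_seed, arm, "attribution"),
                    len(classes),
                )
                X_sig = filled.values[sig.features].to_numpy(dtype=float)
                clf.fit(X_sig, np.searchsorted(classes, labels))
                attributions = shapley_attributions(clf, X_sig, sig.features)
                attributions.columns = [str(c) for c in classes]
            else:
                logger.warning("arm %s: empty signature; final stage skipped", arm)
            arm_results[arm] = ArmResult(
                arm=arm, runs=runs, aggregate=agg,
                signature_features=sig.features, final_metrics=final_metrics,
                attributions=attributions,
            )
        except Exception as exc:
            raise PipelineError(f"arm {arm!r} failed at stage {stage!r}: {exc}") from exc

    comparisons = []
    if len(config.arms) >= 2:
        for a, b in combinations(config.arms, 2):
            for stage_name, getter in (
                ("bootstrap", lambda r, m: r.bootstrap_series(m)),
                ("final", lambda r, m: getattr(r.final_metrics, m)
                 if r.final_metrics is not None else None),
            ):
                for metric in ("accuracy", "macro_auc"):
                    sa = getter(arm_results[a], metric)
                    sb = getter(arm_results[b], metric)
                    if sa is None or sb is None:
                        continue
                    stat, p = compare_model_metrics(sa, sb)
                    comparisons.append(
                        {"stage": stage_name, "arm_a": a, "arm_b": b,
                         "metric": metric, "statistic": stat, "p_value": p}
                    )
    else:
        logger.warning("single arm configured; no comparison table produced")

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {
            arm: {st: _stage_seed(config.master_seed, arm, st)
                  for st in ("bootstrap", "final")}
            for arm in config.arms
        },
        "config_hash": hashlib.sha256(
            repr(sorted(asdict_shallow(config).items(), key=lambda kv: kv[0])).encode()
        ).hexdigest(),
        "n_subjects": len(subjects),
        "n_features": len(table.feature_ids),
    }
    return {
        "arms": arm_results,
        "comparisons": pd.DataFrame(comparisons),
        "manifest": manifest,
        "table": table,
        "subjects": subjects,
    }


def asdict_shallow(obj) -> dict:
    """dataclass -> dict without recursing into nested dataclasses."""
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}


def write_report(bundle: dict, out_dir) -> list[str]:
    """Persist the bundle: per-arm JSON-lines runs, aggregation CSV,
    signature JSON, final metrics JSON, comparison CSV, manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save_json(name: str, payload) -> None:
        p = out / name
        p.write_text(json.dumps(payload, indent=1, default=_json_default))
        written.append(str(p))

    for arm, res in bundle["arms"].items():
        tag = arm.replace("+", "")
        p = out / f"{tag}_bootstrap_runs.jsonl"
        with open(p, "w") as fh:
            for r in res.runs:
                fh.write(json.dumps(r.to_dict()) + "\n")
        written.append(str(p))
        agg_p = out / f"{tag}_aggregate_importance.csv"
        res.aggregate.to_csv(agg_p, index_label="feature_id")
        written.append(str(agg_p))
        _save_json(f"{tag}_signature.json", {"features": res.signature_features})
        if res.final_metrics is not None:
            _save_json(f"{tag}_final_metrics.json", res.final_metrics.to_json_dict())
            cm_p = out / f"{tag}_final_confusion.csv"
            res.final_metrics.pooled_confusion.to_csv(cm_p)
            written.append(str(cm_p))
        if res.attributions is not None:
            at_p = out / f"{tag}_shap_attributions.csv"
            res.attributions.to_csv(at_p, index_label="feature_id")
            written.append(str(at_p))
    comp = bundle["comparisons"]
    if len(comp):
        comp_p = out / "arm_comparisons.csv"
        comp.to_csv(comp_p, index=False)
        written.append(str(comp_p))
    _save_json("manifest.json", bundle["manifest"])
    write_feature_table(bundle["table"], out / "feature_values.csv", out / "feature_meta.csv")
    write_subjects(bundle["subjects"], out / "subjects.csv")
    written += [str(out / n) for n in ("feature_values.csv", "feature_meta.csv", "subjects.csv")]
    return written


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
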