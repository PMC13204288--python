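"""Mixed-model imputation: exact recovery on noiseless data, train-only
fitting (leakage guard), idempotence, and agreement with an independent
mixed-effects fitter on plane-replicated data."""

import numpy as np
import pandas as pd
import pytest

from stsradiomics.cohort import CohortSpec, FeatureTable, SubjectRecord, generate_cohort
from stsradiomics.impute import (
    FeatureFit,
    ImputationError,
    ImputationModel,
    fit_imputer,
    impute,
)
from stsradiomics.selection import stratified_split


def _mini_table(n_per_class=20, noise=0.0, seed=0, n_classes=3):
    """Three plane-replicated T1 features + one T2 feature with known law."""
    rng = np.random.default_rng(seed)
    classes = [f"C{k}" for k in range(n_classes)]
    offsets = {c: 0.5 * k for k, c in enumerate(classes)}
    subjects, rows = [], []
    for k, c in enumerate(classes):
        for i in range(n_per_class):
            sid = f"{c}_{i:02d}"
            vol = float(np.exp(rng.normal(3.5, 0.8)))
            subjects.append(SubjectRecord(sid, c, vol))
            base = 2.0 + 0.5 * np.log(vol) + offsets[c]
            rows.append(
                [base + rng.normal(0, noise) for _ in range(3)]
                + [1.0 - 0.25 * np.log(vol) + offsets[c] + rng.normal(0, noise)]
            )
    fids = ["T1_axial_glszm_000", "T1_coronal_glszm_000",
            "T1_sagittal_glszm_000", "T2_axial_firstorder_000"]
    meta = pd.DataFrame(
        {
            "sequence": ["T1", "T1", "T1", "T2"],
            "plane": ["axial", "coronal", "sagittal", "axial"],
            "family": ["GLSZM", "GLSZM", "GLSZM", "firstorder"],
            "glcm_distance_mm": [np.nan] * 4,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    values = pd.DataFrame(rows, index=[s.subject_id for s in subjects], columns=fids)
    return subjects, FeatureTable(values, meta), offsets


class TestFitting:
    def test_noiseless_coefficients_recovered_exactly(self):
        subjects, table, offsets = _mini_table(noise=0.0)
        model = fit_imputer(table, subjects, [s.subject_id for s in subjects])
        fit = model.fits["T1_axial_glszm_000"]
        assert fit.intercept == pytest.approx(2.0, abs=1e-6)
        assert fit.volume_slope == pytest.approx(0.5, abs=1e-6)
        assert fit.subtype_offsets["C1"] == pytest.approx(0.5, abs=1e-6)
        assert fit.subtype_offsets["C2"] == pytest.approx(1.0, abs=1e-6)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-9)

    def test_single_subtype_cohort_has_zero_offsets(self):
        subjects, table, _ = _mini_table(n_classes=1)
        model = fit_imputer(table, subjects, [s.subject_id for s in subjects])
        fit = model.fits["T2_axial_firstorder_000"]
        assert all(v == 0.0 for v in fit.subtype_offsets.values())
        assert fit.fittable

    def test_leakage_guard_test_rows_never_touch_fit(self):
        subjects, table, _ = _mini_table(noise=0.3, seed=4)
        ids = [s.subject_id for s in subjects]
        train = ids[::2]
        model_a = fit_imputer(table, subjects, train)
        mutated = table.copy()
        held_out = [i for i in ids if i not in train]
        mutated.values.loc[held_out] += 100.0
        model_b = fit_imputer(mutated, subjects, train)
        assert model_a.to_json() == model_b.to_json()

    def test_entirely_missing_feature_flagged_then_rejected_on_demand(self):
        subjects, table, _ = _mini_table()
        t = table.copy()
        t.values["T2_axial_firstorder_000"] = np.nan
        model = fit_imputer(t, subjects, [s.subject_id for s in subjects])
        assert not model.fits["T2_axial_firstorder_000"].fittable
        with pytest.raises(ImputationError, match="T2_axial_firstorder_000"):
            impute(model, t, subjects)

    def test_random_intercept_variance_detected_on_plane_replicates(self):
        # plant a per-subject shift shared by the three plane columns
        subjects, table, _ = _mini_table(noise=0.1, seed=9)
        rng = np.random.default_rng(1)
        shift = rng.normal(0, 2.0, size=len(subjects))
        t1_cols = [c for c in table.values.columns if c.startswith("T1")]
        t = table.copy()
        t.values[t1_cols] = t.values[t1_cols].add(shift, axis=0)
        model = fit_imputer(t, subjects, [s.subject_id for s in subjects])
        fit = model.fits[t1_cols[0]]
        assert fit.random_intercept_variance > 1.0  # true sigma_b^2 = 4

    def test_matches_statsmodels_mixedlm(self):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        subjects, table, _ = _mini_table(noise=0.5, seed=2)
        rng = np.random.default_rng(3)
        shift = rng.normal(0, 1.0, size=len(subjects))
        t1_cols = [c for c in table.values.columns if c.startswith("T1")]
        t = table.copy()
        t.values[t1_cols] = t.values[t1_cols].add(shift, axis=0)
        model = fit_imputer(t, subjects, [s.subject_id for s in subjects])
        fit = model.fits[t1_cols[0]]
        long = t.values[t1_cols].stack().reset_index()
        long.columns = ["sid", "plane", "y"]
        meta = {s.subject_id: s for s in subjects}
        long["logv"] = [np.log(meta[i].tumor_volume) for i in long["sid"]]
        long["subtype"] = [meta[i].subtype for i in long["sid"]]
        mm = statsmodels.mixedlm("y ~ logv + C(subtype)", long,
                                 groups=long["sid"]).fit(reml=True)
        # per-column fixed effects vs the pooled mixed fit: same law, so the
        # estimates must agree within sampling noise; variance components match
        assert fit.intercept == pytest.approx(mm.params["Intercept"], abs=0.5)
        assert fit.volume_slope == pytest.approx(mm.params["logv"], abs=0.15)
        assert fit.random_intercept_variance == pytest.approx(
            float(mm.cov_re.iloc[0, 0]), rel=0.35)
        assert fit.residual_variance == pytest.approx(float(mm.scale), rel=0.35)


class TestImputation:
    def test_model_json_round_trip(self):
        subjects, table, _ = _mini_table(noise=0.2, seed=6)
        model = fit_imputer(table, subjects, [s.subject_id for s in subjects])
        back = ImputationModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert back.class_order == model.class_order

    def test_no_missing_cells_is_identity(self):
        subjects, table, _ = _mini_table()
        model = fit_imputer(table, subjects, [s.subject_id for s in subjects])
        out = impute(model, table, subjects)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_known_coefficients_plug_in(self):
        # intercept 2, slope 0.5, offset +1, V = e^2 -> 2 + 1 + 1 = 4
        fit = FeatureFit(intercept=2.0, volume_slope=0.5,
                         subtype_offsets={"A": 0.0, "B": 1.0},
                         residual_variance=0.0, n_train_obs=10, fittable=True)
        model = ImputationModel(fits={"T1_axial_f_000": fit},
                                class_order=["A", "B"], reference_class="A")
        meta = pd.DataFrame(
            {"sequence": ["T1"], "plane": ["axial"], "family": ["firstorder"],
             "glcm_distance_mm": [np.nan]},
            index=pd.Index(["T1_axial_f_000"], name="feature_id"))
        values = pd.DataFrame({"T1_axial_f_000": [np.nan, np.nan]},
                              index=["s1", "s2"])
        table = FeatureTable(values, meta)
        subjects = [SubjectRecord("s1", "B", float(np.exp(2.0))),
                    SubjectRecord("s2", "B", float(np.exp(2.0)))]
        out = impute(model, table, subjects)
        assert out.values.loc["s1", "T1_axial_f_000"] == pytest.approx(4.0)
        # same subtype + volume -> identical imputed values
        assert (out.values.loc["s1", "T1_axial_f_000"]
                == out.values.loc["s2", "T1_axial_f_000"])

    def test_unseen_subtype_rejected(self):
        subjects, table, _ = _mini_table()
        train = [s.subject_id for s in subjects if s.subtype != "C2"]
        model = fit_imputer(table, subjects, train)
        t = table.copy()
        c2 = [s.subject_id for s in subjects if s.subtype == "C2"][0]
        t.values.loc[c2, "T2_axial_firstorder_000"] = np.nan
        with pytest.raises(ImputationError, match="C2"):
            impute(model, t, subjects)

    def test_noiseless_cohort_imputed_below_1e6(self):
        # end-to-end: volume-linked noiseless features, block missingness,
        # single class so the law is purely volume-driven
        spec = CohortSpec(class_names=("A",), class_counts=(80,),
                          n_features_total=12, n_informative_per_class=0,
                          volume_link_fraction=1.0, noise_sd=0.0,
                          missing_fraction=0.25, n_redundant_pairs=0)
        subjects, table = generate_cohort(spec, 17)
        complete_subjects, complete = generate_cohort(
            CohortSpec(**{**spec.__dict__, "missing_fraction": 0.0}), 17)
        train = [s.subject_id for s in subjects]
        model = fit_imputer(table, subjects, train)
        out = impute(model, table, subjects)
        err = (out.values - complete.values).abs().to_numpy().max()
        assert err < 1e-6

    def test_idempotent(self, small_cohort):
        _, subjects, table = small_cohort
        labels = [s.subtype for s in subjects]
        tr, _ = stratified_split(labels, 0.7, 3)
        train = [table.subject_ids[i] for i in tr]
        model = fit_imputer(table, subjects, train)
        once = impute(model, table, subjects)
        twice = impute(model, once, subjects)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert not once.values.isna().any().any()

    def test_slope_rmse_decreases_with_sample_size(self):
        rmses = []
        for n in (50, 200, 800):
            errs = []
            for seed in (0, 1, 2):
                spec = CohortSpec(class_names=("A",), class_counts=(n,),
                                  n_features_total=12, n_informative_per_class=0,
                                  volume_link_fraction=1.0, noise_sd=1.0,
                                  missing_fraction=0.0, n_redundant_pairs=0)
                subjects, table = generate_cohort(spec, seed)
                model = fit_imputer(table, subjects,
                                    [s.subject_id for s in subjects])
                for fid, (a, b) in table.provenance["volume_linked"].items():
                    errs.append(model.fits[fid].volume_slope - b)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]
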