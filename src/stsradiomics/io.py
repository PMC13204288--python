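"""Reading and writing the pipeline's on-disk formats.

Feature tables travel as a values CSV (rows = subjects, columns = features,
missing cells as empty fields) plus a sidecar metadata CSV
(feature_id, sequence, plane, family, glcm_distance_mm).  Subject metadata
is one CSV (subject_id, subtype, tumor_volume_ml, available_sequences with
``|``-separated tags).  Phantoms are NIfTI volume + binary-mask pairs.
Round trips are bit-identical, including the missing-cell encoding.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FeatureTable, SubjectRecord, SEQUENCES


class TableIOError(ValueError):
    pass


def write_feature_table(table: FeatureTable, values_path, meta_path) -> None:
    table.values.to_csv(values_path, index_label="subject_id", na_rep="")
    table.feature_meta.to_csv(meta_path, index_label="feature_id")


def load_feature_table(values_path, meta_path) -> FeatureTable:
    values_path, meta_path = Path(values_path), Path(meta_path)
    for p in (values_path, meta_path):
        if not p.exists() or p.stat().st_size == 0:
            raise TableIOError(f"{p}: missing or empty file")
    values = pd.read_csv(values_path, index_col="subject_id",
                         float_precision="round_trip")
    values.index.name = None
    meta = pd.read_csv(meta_path, index_col="feature_id")
    dup_subj = values.index[values.index.duplicated()]
    if len(dup_subj):
        lines = [int(np.flatnonzero(values.index == d)[1]) + 2 for d in dup_subj[:3]]
        raise TableIOError(f"duplicate subject ids at data lines {lines}")
    dup_feat = meta.index[meta.index.duplicated()]
    if len(dup_feat):
        lines = [int(np.flatnonzero(meta.index == d)[1]) + 2 for d in dup_feat[:3]]
        raise TableIOError(f"duplicate feature ids at metadata lines {lines}")
    required = {"sequence", "plane", "family", "glcm_distance_mm"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise TableIOError(f"metadata lacks columns: {sorted(missing_cols)}")
    bad = ~meta["sequence"].isin(SEQUENCES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TableIOError(
            f"unknown sequence tag {meta['sequence'][bad].iloc[0]!r} "
            f"at metadata line {line}"
        )
    if list(values.columns) != list(meta.index):
        raise TableIOError("values columns do not match metadata feature ids")
    return FeatureTable(values=values, feature_meta=meta)


def write_subjects(subjects: list[SubjectRecord], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "subtype": [s.subtype for s in subjects],
            "tumor_volume_ml": [s.tumor_volume for s in subjects],
            "available_sequences": ["|".join(s.available_sequences) for s in subjects],
        }
    ).to_csv(path, index=False)


def load_subjects(path) -> list[SubjectRecord]:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TableIOError(f"{path}: missing or empty file")
    df = pd.read_csv(path)
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            subtype=str(r.subtype),
            tumor_volume=float(r.tumor_volume_ml),
            available_sequences=tuple(str(r.available_sequences).split("|")),
        )
        for r in df.itertuples()
    ]


def write_phantom_nifti(volume: np.ndarray, mask: np.ndarray,
                        spacing_mm, volume_path, mask_path) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(volume_path))
    nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), affine), str(mask_path))


def load_nifti_pair(volume_path, mask_path) -> tuple[np.ndarray, np.ndarray, tuple]:
    import nibabel as nib

    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    return (
        np.asarray(vimg.dataobj, dtype=float),
        np.asarray(mimg.dataobj) > 0,
        spacing,
    )
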