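"""Synthetic cohort generation.

Emulates a six-subtype soft-tissue-tumor MRI radiomics cohort: per-subject
T1/T2 radiomic feature tables with planted class-discriminative feature
blocks, highly correlated redundant pairs, volume-linked features, and
sequence-level (block) missingness, plus small 3D phantom image/mask pairs
for exercising the feature extractor.

The default :class:`CohortSpec` reproduces the study structure this package
targets: 332 subjects split 67/55/60/33/70/47 over the subtypes
LMS / MFS / mLPS / ddLPS / UPS / MYX, with 1240 tagged radiomic feature
columns per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_CLASS_NAMES = ("LMS", "MFS", "mLPS", "ddLPS", "UPS", "MYX")
DEFAULT_CLASS_COUNTS = (67, 55, 60, 33, 70, 47)
SEQUENCES = ("T1", "T2")
PLANES = ("axial", "coronal", "sagittal")
FAMILIES = ("shape", "firstorder", "GLCM", "GLRLM", "GLSZM", "NGTDM")
GLCM_DISTANCES_MM = (1, 2, 3, 4, 5)

# Fraction of each sequence/plane block allotted to each family.  GLCM gets
# half the block because it is replicated over five spatial distances.
_FAMILY_WEIGHTS = {
    "shape": 0.025,
    "firstorder": 0.15,
    "GLCM": 0.50,
    "GLRLM": 0.125,
    "GLSZM": 0.125,
    "NGTDM": 0.075,
}


class CohortError(ValueError):
    """Invalid cohort specification or generation request."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the emulated cohort.

    ``effect_size`` is the standardized mean shift (in units of ``noise_sd``)
    applied to a class's informative features; ``volume_link_fraction`` is the
    fraction of columns given a linear dependence on log tumor volume;
    ``missing_fraction`` is the fraction of subjects that lose one entire
    MRI sequence (block missingness).
    """

    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    n_features_total: int = 1240
    n_informative_per_class: int = 10
    effect_size: float = 1.0
    n_redundant_pairs: int = 50
    volume_link_fraction: float = 0.10
    noise_sd: float = 1.0
    missing_fraction: float = 0.15

    def validate(self) -> None:
        if len(self.class_names) == 0:
            raise CohortError("at least one class is required")
        if len(self.class_names) != len(self.class_counts):
            raise CohortError("class_names and class_counts length mismatch")
        if len(set(self.class_names)) != len(self.class_names):
            raise CohortError("class names must be unique")
        if any(c <= 0 for c in self.class_counts):
            raise CohortError("every class count must be a positive integer")
        if self.n_features_total <= 0:
            raise CohortError("n_features_total must be positive")
        if self.n_informative_per_class < 0:
            raise CohortError("n_informative_per_class must be non-negative")
        if self.n_informative_per_class * len(self.class_names) > self.n_features_total:
            raise CohortError("informative features exceed n_features_total")
        if self.noise_sd < 0:
            raise CohortError("noise_sd must be non-negative")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise CohortError("missing_fraction must lie in [0, 1]")
        if not 0.0 <= self.volume_link_fraction <= 1.0:
            raise CohortError("volume_link_fraction must lie in [0, 1]")
        if self.n_redundant_pairs < 0:
            raise CohortError("n_redundant_pairs must be non-negative")


@dataclass
class SubjectRecord:
    subject_id: str
    subtype: str
    tumor_volume: float  # mL
    available_sequences: tuple[str, ...] = SEQUENCES

    def __post_init__(self) -> None:
        if self.tumor_volume <= 0:
            raise CohortError(f"{self.subject_id}: tumor_volume must be > 0")
        if len(self.available_sequences) == 0:
            raise CohortError(f"{self.subject_id}: no available sequences")


@dataclass
class FeatureTable:
    """Subjects x tagged radiomic features with explicit missingness (NaN).

    ``values`` is a DataFrame indexed by subject id with feature-id columns;
    ``feature_meta`` is indexed by feature id with columns
    ``sequence, plane, family, glcm_distance_mm``.  ``provenance`` records
    the planted structure (informative / redundant / volume-linked columns)
    when the table was synthesized; it is None for tables read from disk.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.feature_meta.index):
            raise CohortError("values columns and feature_meta index disagree")
        bad = set(self.feature_meta["sequence"]) - set(SEQUENCES)
        if bad:
            raise CohortError(f"unknown sequence tags: {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def features_for_sequence(self, sequence: str) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["sequence"] == sequence])

    def subset_sequences(self, sequences: Sequence[str]) -> "FeatureTable":
        keep = self.feature_meta.index[self.feature_meta["sequence"].isin(sequences)]
        return FeatureTable(
            values=self.values[list(keep)].copy(),
            feature_meta=self.feature_meta.loc[keep].copy(),
            provenance=self.provenance,
        )

    def copy(self) -> "FeatureTable":
        prov = dict(self.provenance) if self.provenance is not None else None
        return FeatureTable(self.values.copy(), self.feature_meta.copy(), prov)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def default_feature_layout(n_features_total: int = 1240) -> pd.DataFrame:
    """Tagged feature id layout for a synthetic table.

    Columns are apportioned as evenly as possible over the six
    sequence x plane blocks, and within a block over families by the
    documented weights, with GLCM columns cycled over the five distances.
    """
    if n_features_total <= 0:
        raise CohortError("n_features_total must be positive")
    blocks = [(s, p) for s in SEQUENCES for p in PLANES]
    per_block = _largest_remainder(n_features_total, np.ones(len(blocks)))
    fam_names = list(_FAMILY_WEIGHTS)
    fam_w = np.array([_FAMILY_WEIGHTS[f] for f in fam_names])
    rows = []
    for (seq, plane), n_block in zip(blocks, per_block):
        fam_counts = _largest_remainder(int(n_block), fam_w)
        for fam, n_fam in zip(fam_names, fam_counts):
            for k in range(int(n_fam)):
                if fam == "GLCM":
                    dist = GLCM_DISTANCES_MM[k % len(GLCM_DISTANCES_MM)]
                    fid = f"{seq}_{plane}_glcm_d{dist}_{k // len(GLCM_DISTANCES_MM):03d}"
                else:
                    dist = np.nan
                    fid = f"{seq}_{plane}_{fam.lower()}_{k:03d}"
                rows.append((fid, seq, plane, fam, dist))
    meta = pd.DataFrame(
        rows, columns=["feature_id", "sequence", "plane", "family", "glcm_distance_mm"]
    ).set_index("feature_id")
    assert len(meta) == n_features_total
    return meta


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[SubjectRecord], FeatureTable]:
    """Generate a synthetic cohort with planted class structure.

    Subject tumor volumes are log-normal (median ~55 mL, sdlog 0.9).
    Informative columns receive a per-class Gaussian mean shift of
    ``effect_size * noise_sd`` on disjoint column blocks; redundant pairs are
    near-duplicates (target r >= 0.95) planted among non-informative columns;
    volume-linked columns follow ``a + b*log(volume) + noise``.  Block
    missingness is applied via :func:`inject_missingness`.  Deterministic
    given ``(spec, seed)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(sum(spec.class_counts))

    subjects: list[SubjectRecord] = []
    labels: list[str] = []
    for cname, count in zip(spec.class_names, spec.class_counts):
        labels.extend([cname] * count)
    volumes = np.exp(rng.normal(np.log(55.0), 0.9, size=n))
    for i, (lab, vol) in enumerate(zip(labels, volumes)):
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                subtype=lab,
                tumor_volume=float(vol),
                available_sequences=SEQUENCES,
            )
        )

    meta = default_feature_layout(spec.n_features_total)
    F = spec.n_features_total
    values = rng.normal(0.0, spec.noise_sd, size=(n, F))

    # disjoint informative blocks, one per class
    m = spec.n_informative_per_class
    n_cls = len(spec.class_names)
    informative = rng.choice(F, size=m * n_cls, replace=False) if m else np.array([], int)
    informative_by_class: dict[str, list[int]] = {}
    y = np.asarray(labels)
    # shift in units of the noise scale; absolute in the noiseless limit
    shift = spec.effect_size * (spec.noise_sd if spec.noise_sd > 0 else 1.0)
    for k, cname in enumerate(spec.class_names):
        cols = np.sort(informative[k * m : (k + 1) * m])
        informative_by_class[cname] = [int(c) for c in cols]
        if m:
            values[np.ix_(y == cname, cols)] += shift

    remaining = np.setdiff1d(np.arange(F), informative)

    # volume-linked columns: value = a + b*log(V) + noise
    n_vol = int(round(spec.volume_link_fraction * F))
    n_vol = min(n_vol, len(remaining))
    vol_cols = rng.choice(remaining, size=n_vol, replace=False) if n_vol else np.array([], int)
    logv = np.log(volumes)
    vol_params = {}
    for c in vol_cols:
        a = float(rng.normal(0.0, 0.5))
        b = float(rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0]) * max(spec.noise_sd, 1e-12))
        values[:, c] += a + b * logv
        vol_params[int(c)] = (a, b)
    remaining = np.setdiff1d(remaining, vol_cols)

    # redundant near-duplicate pairs among non-informative columns
    n_pairs = min(spec.n_redundant_pairs, len(remaining) // 2)
    pair_cols = (
        rng.choice(remaining, size=2 * n_pairs, replace=False)
        if n_pairs
        else np.array([], int)
    )
    redundant_pairs: list[tuple[int, int]] = []
    for j in range(n_pairs):
        src, dst = int(pair_cols[2 * j]), int(pair_cols[2 * j + 1])
        # eps_sd = 0.25 * col_sd gives r ~ 1/sqrt(1 + 0.0625) ~ 0.970
        col_sd = float(np.std(values[:, src])) or 1.0
        values[:, dst] = values[:, src] + rng.normal(0.0, 0.25 * col_sd, size=n)
        redundant_pairs.append((src, dst))

    fids = list(meta.index)
    table = FeatureTable(
        values=pd.DataFrame(values, index=[s.subject_id for s in subjects], columns=fids),
        feature_meta=meta,
        provenance={
            "informative_by_class": {
                c: [fids[i] for i in cols] for c, cols in informative_by_class.items()
            },
            "redundant_pairs": [(fids[a], fids[b]) for a, b in redundant_pairs],
            "volume_linked": {fids[c]: ab for c, ab in vol_params.items()},
        },
    )

    if spec.missing_fraction > 0:
        miss_seed = int(rng.integers(0, 2**31 - 1))
        table, subjects = inject_missingness(
            table, subjects, spec.missing_fraction, miss_seed
        )
    return subjects, table


def inject_missingness(
    table: FeatureTable,
    subjects: list[SubjectRecord],
    missing_fraction: float,
    seed: int,
) -> tuple[FeatureTable, list[SubjectRecord]]:
    """Blank one whole sequence block for round(fraction * n) random subjects.

    The affected sequence is chosen uniformly between T1 and T2 per subject;
    all other cells are untouched.  Subjects must still have both sequences
    available to be eligible.
    """
    if not 0.0 <= missing_fraction <= 1.0:
        raise CohortError("missing_fraction must lie in [0, 1]")
    n = len(subjects)
    n_affect = int(round(missing_fraction * n))
    out = table.copy()
    out_subjects = [replace(s) for s in subjects]
    if n_affect == 0:
        return out, out_subjects
    eligible = [i for i, s in enumerate(out_subjects) if len(s.available_sequences) == 2]
    if len(eligible) < n_affect:
        raise CohortError(
            f"cannot blank a sequence for {n_affect} subjects; "
            f"only {len(eligible)} still have both sequences"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_affect, replace=False)
    seq_cols = {s: table.features_for_sequence(s) for s in SEQUENCES}
    for i in chosen:
        subj = out_subjects[i]
        drop = SEQUENCES[int(rng.integers(0, 2))]
        out.values.loc[subj.subject_id, seq_cols[drop]] = np.nan
        subj.available_sequences = tuple(s for s in subj.available_sequences if s != drop)
    return out, out_subjects


# ---------------------------------------------------------------------------
# 3D phantoms for the feature extractor


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: str = "sphere"
    intensity_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise CohortError("grid_shape must be three integers >= 1")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise CohortError("voxel_spacing_mm must be three positive reals")
        if self.geometry not in {"sphere", "box", "checkerboard", "two_level_split"}:
            raise CohortError(f"unknown geometry {self.geometry!r}")


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic intensity volume + binary mask for extractor tests.

    Geometries: ``sphere`` (radius_mm, centered), ``box`` (box_shape voxels,
    centered), ``checkerboard`` (full-grid mask, intensities ``low``/``high``
    alternating with voxel ``period``), ``two_level_split`` (full-grid mask,
    first half ``low``, second half ``high`` along axis 0).  Optional
    ``noise_sd`` adds Gaussian intensity noise inside the mask.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    p = dict(spec.intensity_params)
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    mask = np.zeros(shape, dtype=bool)

    if spec.geometry == "sphere":
        r = float(p.get("radius_mm", min(shape) * min(spec.voxel_spacing_mm) / 3))
        center = [(s - 1) / 2 for s in shape]
        d2 = sum(
            ((g - c) * sp) ** 2
            for g, c, sp in zip((zz, yy, xx), center, spec.voxel_spacing_mm)
        )
        mask = d2 <= r**2
        intensity = np.full(shape, float(p.get("intensity", 100.0)))
    elif spec.geometry == "box":
        box = p.get("box_shape", tuple(max(1, s // 2) for s in shape))
        starts = [(s - b) // 2 for s, b in zip(shape, box)]
        mask[tuple(slice(st, st + b) for st, b in zip(starts, box))] = True
        intensity = np.full(shape, float(p.get("intensity", 100.0)))
    elif spec.geometry == "checkerboard":
        mask[:] = True
        period = int(p.get("period", 2))
        parity = ((zz // period) + (yy // period) + (xx // period)).astype(int) % 2
        intensity = np.where(parity == 0, float(p.get("low", 0.0)), float(p.get("high", 100.0)))
    else:  # two_level_split
        mask[:] = True
        half = shape[0] // 2
        intensity = np.full(shape, float(p.get("low", 0.0)))
        intensity[half:] = float(p.get("high", 100.0))

    if not mask.any():
        raise CohortError("degenerate phantom: empty mask")
    noise_sd = float(p.get("noise_sd", 0.0))
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=shape)
    return intensity.astype(float), mask
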