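"""3D radiomic feature extraction.

Implements the extraction settings used throughout the package: relative
intensity rescaling to mean +/- k standard deviations (k = 3) followed by
32-level gray binning, then shape, first-order, and the four texture-matrix
families — GLCM (at spatial distances of 1-5 mm), GLRLM, GLSZM, NGTDM.

Conventions (documented, common radiomics practice):

- texture matrices accumulate over the 13 unique 3D directions; family
  features are computed per direction matrix and averaged (GLSZM and NGTDM
  are direction-free);
- zones and neighborhoods use 26-connectivity;
- all entropies are in bits (log base 2);
- GLCM mm->voxel conversion: per-axis step = max(1, round(d_mm / spacing_axis))
  times the direction sign.

Intended for modest ROI sizes (masks up to a few tens of thousands of
voxels); run-length and neighborhood accumulation walk voxels in Python.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

FAMILY_NAMES = ("shape", "firstorder", "GLCM", "GLRLM", "GLSZM", "NGTDM")

# 13 unique 3D directions (one per +/- pair of the 26-neighborhood)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class ExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class ExtractionConfig:
    n_bins: int = 32
    rescale_k: float = 3.0
    glcm_distances_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    families_enabled: tuple[str, ...] = FAMILY_NAMES

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ExtractionError("n_bins must be >= 2")
        if self.rescale_k <= 0:
            raise ExtractionError("rescale_k must be positive")
        if any(d <= 0 for d in self.glcm_distances_mm):
            raise ExtractionError("GLCM distances must be positive")
        bad = set(self.families_enabled) - set(FAMILY_NAMES)
        if bad:
            raise ExtractionError(f"unknown families: {sorted(bad)}")


@dataclass
class DiscretizedVolume:
    """Integer gray levels 1..n_bins on mask voxels; 0 outside the mask."""

    levels: np.ndarray
    n_bins: int
    voxel_spacing_mm: tuple[float, float, float]
    mask: np.ndarray


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ExtractionError("empty mask")
    return mask


def rescale_discretize(
    volume: np.ndarray,
    mask: np.ndarray,
    config: ExtractionConfig,
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedVolume:
    """Relative intensity rescaling (mean +/- k*SD) + equal-width binning.

    The range [mu - k*sigma, mu + k*sigma] over mask voxels is divided into
    ``n_bins`` equal-width left-closed bins; values outside clamp to the
    first / last bin.  A constant region (sigma = 0) maps every voxel to
    bin 1 (degenerate rule; any constant assignment is equivalent for the
    texture matrices).
    """
    config.validate()
    mask = _check_mask(mask)
    vol = np.asarray(volume, dtype=float)
    vals = vol[mask]
    if not np.isfinite(vals).all():
        raise ExtractionError("volume is not finite on the mask")
    mu, sigma = float(vals.mean()), float(vals.std())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if sigma == 0.0:
        levels[mask] = 1
    else:
        lo = mu - config.rescale_k * sigma
        width = 2.0 * config.rescale_k * sigma / config.n_bins
        binned = np.floor((vals - lo) / width).astype(np.int64) + 1
        levels[mask] = np.clip(binned, 1, config.n_bins)
    return DiscretizedVolume(levels, config.n_bins, tuple(voxel_spacing_mm), mask)


# ---------------------------------------------------------------------------
# shape


def shape_features(
    mask: np.ndarray, voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> pd.Series:
    """Morphology: volume (mL), surface area (mm^2), compactness, sphericity,
    maximum 3D diameter (mm).

    Volume is voxel count x voxel volume.  Surface area comes from a
    marching-cubes mesh of the 0.5 isosurface; sphericity
    (pi^(1/3) (6 V)^(2/3) / A) and compactness (= sphericity^3) use the mesh
    volume so both lie in (0, 1] by the isoperimetric inequality.
    """
    mask = _check_mask(mask)
    spacing = tuple(float(s) for s in voxel_spacing_mm)
    voxvol = float(np.prod(spacing))
    n_vox = int(mask.sum())
    volume_mm3 = n_vox * voxvol

    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    # mesh volume via divergence theorem (sum of signed tetrahedra)
    tri = verts[faces]
    mesh_vol = abs(float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0)
    sphericity = float(np.pi ** (1 / 3) * (6.0 * mesh_vol) ** (2 / 3) / area)
    compactness = sphericity**3

    coords = np.argwhere(mask) * np.asarray(spacing)
    if len(coords) == 1:
        max_diam = 0.0
    else:
        pts = coords
        if len(pts) > 400:
            try:
                from scipy.spatial import ConvexHull

                pts = coords[ConvexHull(coords, qhull_options="QJ").vertices]
            except Exception:
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        max_diam = float(np.sqrt(d2.max()))

    return pd.Series(
        {
            "volume_mL": volume_mm3 / 1000.0,
            "surface_area_mm2": area,
            "compactness": compactness,
            "sphericity": sphericity,
            "max_3d_diameter_mm": max_diam,
        }
    )


# ---------------------------------------------------------------------------
# first order


def firstorder_features(
    volume: np.ndarray, mask: np.ndarray, config: ExtractionConfig = ExtractionConfig()
) -> pd.Series:
    """Intensity-distribution statistics over mask voxels.

    Moments are population moments (ddof = 0); skewness and kurtosis are the
    standardized third and fourth moments (kurtosis is non-excess; both are
    defined as 0 for a constant region).  Entropy is computed on the
    discretized histogram, in bits.
    """
    mask = _check_mask(mask)
    vals = np.asarray(volume, dtype=float)[mask]
    mu = float(vals.mean())
    var = float(vals.var())
    if var > 0:
        z = (vals - mu) / np.sqrt(var)
        skew, kurt = float(np.mean(z**3)), float(np.mean(z**4))
    else:
        skew = kurt = 0.0
    disc = rescale_discretize(volume, mask, config)
    counts = np.bincount(disc.levels[mask], minlength=config.n_bins + 1)[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    pcts = np.percentile(vals, [10, 25, 50, 75, 90])
    return pd.Series(
        {
            "mean": mu,
            "variance": var,
            "skewness": skew,
            "kurtosis": kurt,
            "entropy": entropy,
            "min": float(vals.min()),
            "max": float(vals.max()),
            "p10": float(pcts[0]),
            "p25": float(pcts[1]),
            "p50": float(pcts[2]),
            "p75": float(pcts[3]),
            "p90": float(pcts[4]),
        }
    )


# ---------------------------------------------------------------------------
# GLCM


def _glcm_offset(direction: tuple[int, int, int], distance_mm: float,
                 spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    return tuple(
        int(d) * max(1, int(round(distance_mm / s))) for d, s in zip(direction, spacing)
    )


def glcm_matrix(disc: DiscretizedVolume, offset: tuple[int, int, int]) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix at one voxel offset.

    Returns None when no in-mask voxel pair exists at the offset.
    """
    lv, mask = disc.levels, disc.mask
    shape = lv.shape
    src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(offset, shape)]
    dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(offset, shape)]
    a, b = lv[tuple(src)], lv[tuple(dst)]
    both = mask[tuple(src)] & mask[tuple(dst)]
    if not both.any():
        return None
    i, j = a[both] - 1, b[both] - 1
    n = disc.n_bins
    mat = np.zeros((n, n))
    np.add.at(mat, (i, j), 1.0)
    mat += mat.T.copy()
    return mat / mat.sum()


def _glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    autocorr = float((ii * jj * p).sum())
    joint_var = float((((ii - mu_x) ** 2) * p).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    nz = p[p > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum())
    if var_x > 0:
        correlation = (autocorr - mu_x * mu_x) / var_x  # symmetric: mu_x = mu_y
    else:
        correlation = 1.0  # single gray level: perfectly correlated by convention
    energy = float((p**2).sum())
    return {
        "joint_variance": joint_var,
        "autocorrelation": autocorr,
        "contrast": contrast,
        "joint_entropy": joint_entropy,
        "correlation": float(correlation),
        "energy": energy,
    }


def glcm_features(disc: DiscretizedVolume, distance_mm: float) -> pd.Series:
    """Direction-averaged GLCM features at one spatial distance (mm)."""
    if distance_mm <= 0:
        raise ExtractionError("distance_mm must be positive")
    per_dir = []
    for direction in DIRECTIONS_13:
        mat = glcm_matrix(disc, _glcm_offset(direction, distance_mm, disc.voxel_spacing_mm))
        if mat is not None:
            per_dir.append(_glcm_features_from_matrix(mat))
    names = ["joint_variance", "autocorrelation", "contrast", "joint_entropy",
             "correlation", "energy"]
    if not per_dir:
        return pd.Series({k: np.nan for k in names})
    return pd.Series({k: float(np.mean([d[k] for d in per_dir])) for k in names})


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(disc: DiscretizedVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix R[gray-1, length-1] along one direction."""
    lv, mask = disc.levels, disc.mask
    shape = lv.shape
    max_len = int(np.ceil(np.sqrt(sum((s * abs(d)) ** 2 for s, d in zip(shape, direction))))) + 1
    R = np.zeros((disc.n_bins, max_len))
    dz, dy, dx = direction
    for z, y, x in np.argwhere(mask):
        pz, py, px = z - dz, y - dy, x - dx
        if (
            0 <= pz < shape[0] and 0 <= py < shape[1] and 0 <= px < shape[2]
            and mask[pz, py, px] and lv[pz, py, px] == lv[z, y, x]
        ):
            continue  # not a run start
        g = lv[z, y, x]
        length = 1
        nz, ny, nx = z + dz, y + dy, x + dx
        while (
            0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
            and mask[nz, ny, nx] and lv[nz, ny, nx] == g
        ):
            length += 1
            nz, ny, nx = nz + dz, ny + dy, nx + dx
        R[g - 1, length - 1] += 1
    return R


def _glrlm_features_from_matrix(R: np.ndarray, n_vox: int) -> dict[str, float]:
    Nr = R.sum()
    p = R / Nr
    g = np.arange(1, R.shape[0] + 1)[:, None].astype(float)
    l = np.arange(1, R.shape[1] + 1)[None, :].astype(float)
    nz = p[p > 0]
    return {
        "short_run_emphasis": float((p / l**2).sum()),
        "long_run_emphasis": float((p * l**2).sum()),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / Nr),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / Nr),
        "run_percentage": float(Nr / n_vox),
        "run_entropy": float(-(nz * np.log2(nz)).sum()),
        "low_gray_run_emphasis": float((p / g**2).sum()),
        "high_gray_run_emphasis": float((p * g**2).sum()),
    }


def glrlm_features(disc: DiscretizedVolume) -> pd.Series:
    """Run-length features averaged over the 13 directions."""
    n_vox = int(disc.mask.sum())
    per_dir = [
        _glrlm_features_from_matrix(glrlm_matrix(disc, d), n_vox) for d in DIRECTIONS_13
    ]
    return pd.Series({k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]})


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Size-zone matrix S[gray-1, size-1]; zones are 26-connected components
    of constant gray level."""
    lv, mask = disc.levels, disc.mask
    n_vox = int(mask.sum())
    S = np.zeros((disc.n_bins, n_vox))
    for g in np.unique(lv[mask]):
        labeled, n_zones = ndimage.label((lv == g) & mask, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            S[g - 1, s - 1] += 1
    return S


def _glszm_features_from_matrix(S: np.ndarray, n_vox: int) -> dict[str, float]:
    Nz = S.sum()
    p = S / Nz
    g = np.arange(1, S.shape[0] + 1)[:, None].astype(float)
    s = np.arange(1, S.shape[1] + 1)[None, :].astype(float)
    nz = p[p > 0]
    mu_g = float((g * p).sum())
    mu_s = float((s * p).sum())
    return {
        "small_zone_emphasis": float((p / s**2).sum()),
        "large_zone_emphasis": float((p * s**2).sum()),
        "gray_level_nonuniformity": float((S.sum(axis=1) ** 2).sum() / Nz),
        "zone_size_nonuniformity": float((S.sum(axis=0) ** 2).sum() / Nz),
        "zone_percentage": float(Nz / n_vox),
        "zone_size_entropy": float(-(nz * np.log2(nz)).sum()),
        "gray_level_variance": float((((g - mu_g) ** 2) * p).sum()),
        "zone_size_variance": float((((s - mu_s) ** 2) * p).sum()),
    }


def glszm_features(disc: DiscretizedVolume) -> pd.Series:
    return pd.Series(_glszm_features_from_matrix(glszm_matrix(disc), int(disc.mask.sum())))


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-gray-level (n_i, s_i): voxel counts and accumulated absolute
    difference from the 26-neighborhood mean.  Voxels with no in-mask
    neighbor are excluded."""
    lv, mask = disc.levels, disc.mask
    shape = lv.shape
    n_i = np.zeros(disc.n_bins)
    s_i = np.zeros(disc.n_bins)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z, y, x in np.argwhere(mask):
        tot, cnt = 0.0, 0
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2] and mask[nz, ny, nx]:
                tot += lv[nz, ny, nx]
                cnt += 1
        if cnt == 0:
            continue
        g = lv[z, y, x]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - tot / cnt)
    return n_i, s_i


def ngtdm_features(disc: DiscretizedVolume) -> pd.Series:
    """Coarseness, contrast, busyness, complexity, strength (Amadasun-Ma
    formulation, 26-neighborhood).  NaN when no voxel has a neighbor."""
    n_i, s_i = ngtdm_table(disc)
    N = n_i.sum()
    names = ["coarseness", "contrast", "busyness", "complexity", "strength"]
    if N == 0:
        return pd.Series({k: np.nan for k in names})
    p_i = n_i / N
    i = np.arange(1, disc.n_bins + 1).astype(float)
    present = p_i > 0
    Ng = int(present.sum())
    dot = float((p_i * s_i).sum())
    coarseness = 1.0 / dot if dot > 0 else 1e6

    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
    si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
    if Ng > 1:
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (Ng * (Ng - 1)) * float(s_i.sum()) / N
    else:
        contrast = 0.0
    denom_busy = float(np.abs(ii * pi - jj * pj).sum())
    busyness = dot / denom_busy if denom_busy > 0 else 0.0
    complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / N
    s_sum = float(s_i.sum())
    strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    return pd.Series(
        {
            "coarseness": coarseness,
            "contrast": contrast,
            "busyness": busyness,
            "complexity": complexity,
            "strength": strength,
        }
    )


# ---------------------------------------------------------------------------
# full extraction


def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    config: ExtractionConfig = ExtractionConfig(),
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sequence: str = "T1",
    plane: str = "axial",
) -> tuple[pd.Series, pd.DataFrame]:
    """Extract every enabled family from one volume + mask.

    Returns ``(values, meta)`` where values is an ordered Series of
    ``feature_id -> value`` and meta tags each id with sequence, plane,
    family, and GLCM distance.  Family-level failures become NaN entries.
    Deterministic and idempotent for fixed input.
    """
    config.validate()
    mask = _check_mask(mask)
    prefix = f"{sequence}_{plane}"
    out: dict[str, float] = {}
    meta_rows: list[tuple[str, str, str, str, float]] = []

    def _add(series: pd.Series, family: str, group: str, dist: float = np.nan) -> None:
        for name, val in series.items():
            fid = f"{prefix}_{group}_{name}"
            out[fid] = float(val)
            meta_rows.append((fid, sequence, plane, family, dist))

    disc = None
    if set(config.families_enabled) & {"GLCM", "GLRLM", "GLSZM", "NGTDM", "firstorder"}:
        disc = rescale_discretize(volume, mask, config, voxel_spacing_mm)

    if "shape" in config.families_enabled:
        _add(shape_features(mask, voxel_spacing_mm), "shape", "shape")
    if "firstorder" in config.families_enabled:
        _add(firstorder_features(volume, mask, config), "firstorder", "firstorder")
    if "GLCM" in config.families_enabled:
        for d in config.glcm_distances_mm:
            _add(glcm_features(disc, d), "GLCM", f"glcm_d{d:g}", float(d))
    if "GLRLM" in config.families_enabled:
        _add(glrlm_features(disc), "GLRLM", "glrlm")
    if "GLSZM" in config.families_enabled:
        _add(glszm_features(disc), "GLSZM", "glszm")
    if "NGTDM" in config.families_enabled:
        _add(ngtdm_features(disc), "NGTDM", "ngtdm")

    meta = pd.DataFrame(
        meta_rows,
        columns=["feature_id", "sequence", "plane", "family", "glcm_distance_mm"],
    ).set_index("feature_id")
    return pd.Series(out), meta
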