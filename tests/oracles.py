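"""Independent brute-force oracles for texture matrices and metrics.

Everything here is written as plain nested loops / flood fills, independent
of the vectorized implementations under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def in_grid(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def glcm_matrix_bruteforce(levels, mask, offset, n_bins):
    """Symmetric normalized co-occurrence matrix by exhaustive pair listing."""
    shape = levels.shape
    mat = np.zeros((n_bins, n_bins))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                q = (z + offset[0], y + offset[1], x + offset[2])
                if in_grid(q, shape) and mask[q]:
                    i, j = levels[z, y, x] - 1, levels[q] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    tot = mat.sum()
    return mat / tot if tot else None


def glcm_features_bruteforce(p):
    n = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    feats = dict.fromkeys(
        ["joint_variance", "autocorrelation", "contrast", "joint_entropy", "energy"], 0.0
    )
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            feats["joint_variance"] += (i + 1 - mu) ** 2 * v
            feats["autocorrelation"] += (i + 1) * (j + 1) * v
            feats["contrast"] += (i - j) ** 2 * v
            feats["energy"] += v * v
            if v > 0:
                feats["joint_entropy"] -= v * np.log2(v)
    var = sum((i + 1 - mu) ** 2 * p[i, :].sum() for i in range(n))
    feats["correlation"] = (
        (feats["autocorrelation"] - mu * mu) / var if var > 0 else 1.0
    )
    return feats


def glrlm_matrix_bruteforce(levels, mask, direction, n_bins, max_len):
    """Run-length matrix by walking whole grid lines from their entry voxels."""
    shape = levels.shape
    R = np.zeros((n_bins, max_len))
    d = np.asarray(direction)
    starts = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                prev = (z - d[0], y - d[1], x - d[2])
                if not in_grid(prev, shape):
                    starts.append((z, y, x))
    for start in starts:
        pos = np.asarray(start)
        run_level, run_len = None, 0
        while in_grid(tuple(pos), shape):
            t = tuple(pos)
            if mask[t]:
                g = levels[t]
                if g == run_level:
                    run_len += 1
                else:
                    if run_level is not None:
                        R[run_level - 1, run_len - 1] += 1
                    run_level, run_len = g, 1
            else:
                if run_level is not None:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = None, 0
            pos = pos + d
        if run_level is not None:
            R[run_level - 1, run_len - 1] += 1
    return R


def glszm_zones_bruteforce(levels, mask):
    """(gray level, zone size) list via 26-connected BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    neighbors = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                size = 0
                q = deque([(z, y, x)])
                seen[z, y, x] = True
                while q:
                    cz, cy, cx = q.popleft()
                    size += 1
                    for dz, dy, dx in neighbors:
                        t = (cz + dz, cy + dy, cx + dx)
                        if (
                            in_grid(t, shape) and mask[t] and not seen[t]
                            and levels[t] == g
                        ):
                            seen[t] = True
                            q.append(t)
                zones.append((g, size))
    return zones


def ngtdm_bruteforce(levels, mask, n_bins):
    """(n_i, s_i) by direct per-voxel neighborhood-mean computation."""
    shape = levels.shape
    n_i = np.zeros(n_bins)
    s_i = np.zeros(n_bins)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                vals = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            t = (z + dz, y + dy, x + dx)
                            if in_grid(t, shape) and mask[t]:
                                vals.append(levels[t])
                if not vals:
                    continue
                g = levels[z, y, x]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(vals) / len(vals))
    return n_i, s_i


# --- confusion-matrix hand oracles -----------------------------------------


def per_class_metrics_bruteforce(cm):
    """Per-class OvR metrics from an integer matrix, by direct counting."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    total = cm.sum()
    out = []
    for c in range(K):
        tp = cm[c, c]
        fn = sum(cm[c, j] for j in range(K)) - tp
        fp = sum(cm[i, c] for i in range(K)) - tp
        tn = total - tp - fn - fp

        def r(num, den):
            return num / den if den > 0 else float("nan")

        sens, spec = r(tp, tp + fn), r(tn, tn + fp)
        out.append(
            {
                "sensitivity": sens,
                "specificity": spec,
                "ppv": r(tp, tp + fp),
                "npv": r(tn, tn + fn),
                "balanced_accuracy": (sens + spec) / 2,
                "f1": r(2 * tp, 2 * tp + fp + fn),
            }
        )
    return out


def kappa_bruteforce(cm):
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    po = sum(cm[i, i] for i in range(cm.shape[0])) / n
    pe = sum(cm[i, :].sum() * cm[:, i].sum() for i in range(cm.shape[0])) / n**2
    if pe >= 1 - 1e-15:
        return 1.0 if po >= 1 - 1e-15 else float("nan")
    return (po - pe) / (1 - pe)
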