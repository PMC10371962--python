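"""Texture matrices and their features: GLCM, GLRLM, GLZLM, NGLDM.

All matrix families aggregate the 13 unique 3D directions at voxel distance
1 into a single matrix before feature computation (LIFEx-style "merged"
aggregation) and use 26-connectivity for neighborhoods and zones.  Voxels
outside the VOI never contribute to any matrix.

Degenerate single-level lesions get deterministic, documented fallbacks
instead of NaN: GLCM correlation := 1, NGLDM coarseness capped at 1e6,
contrast/busyness := 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

COARSENESS_CAP = 1e6

# the 13 unique 3D direction offsets: one representative per +/- pair
# (first nonzero component positive)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and (dx == 1 or dy == 1 or (dy == 0 and dz == 1))
)
assert len(DIRECTIONS_13) == 13

_CONN26 = np.ones((3, 3, 3), dtype=int)


def _pairs_along(levels: np.ndarray, mask: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Gray-level pairs (a, b) for voxels v in VOI with v+d in VOI."""
    sl_a, sl_b = [], []
    for axis, off in enumerate(d):
        n = levels.shape[axis]
        if abs(off) >= n:
            return np.empty(0, int), np.empty(0, int)
        if off >= 0:
            sl_a.append(slice(0, n - off))
            sl_b.append(slice(off, n))
        else:
            sl_a.append(slice(-off, n))
            sl_b.append(slice(0, n + off))
    ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return levels[tuple(sl_a)][ok], levels[tuple(sl_b)][ok]


def glcm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Symmetric, direction-aggregated, probability-normalized co-occurrence
    matrix (indices 0..n_levels-1 correspond to gray levels 1..n_levels).
    Returns the zero matrix when the VOI has no within-VOI voxel pairs."""
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for d in directions:
        a, b = _pairs_along(levels, mask, d)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T  # symmetric: count both orderings
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(d, directions=DIRECTIONS_13) -> dict[str, float]:
    """Seven co-occurrence features from the merged GLCM."""
    p = glcm_matrix(d.levels, d.mask, d.bin_count, directions)
    if p.sum() == 0:
        # isolated voxel(s): no pairs — documented constant-lesion fill
        return {
            "Homogeneity": 1.0, "Energy": 1.0, "Contrast": 0.0,
            "Correlation": 1.0, "Entropy": 0.0, "Entropy_log2": 0.0,
            "Dissimilarity": 0.0,
        }
    i = np.arange(1, d.bin_count + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    sigma = float(np.sqrt(((i - mu) ** 2 * pi).sum()))
    if sigma > 0:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / sigma**2)
    else:
        correlation = 1.0  # single-level lesion
    return {
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Energy": float((p**2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "Entropy": entropy,
        "Entropy_log2": entropy / np.log(2.0),
        "Dissimilarity": float((p * np.abs(ii - jj)).sum()),
    }


def ngldm_features(d) -> dict[str, float]:
    """Coarseness, Contrast and Busyness from neighborhood gray-tone
    differences (26-connected, within-VOI neighbors only)."""
    mask = d.mask
    levels = d.levels.astype(float)
    neigh_sum = ndimage.correlate(np.where(mask, levels, 0.0), _CONN26, mode="constant") - np.where(mask, levels, 0.0)
    neigh_cnt = ndimage.correlate(mask.astype(float), _CONN26.astype(float), mode="constant") - mask
    valid = mask & (neigh_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return {"Coarseness": COARSENESS_CAP, "Contrast": 0.0, "Busyness": 0.0}
    diffs = np.abs(levels[valid] - neigh_sum[valid] / neigh_cnt[valid])
    lv = d.levels[valid]

    level_ids = np.arange(1, d.bin_count + 1)
    n_i = np.bincount(lv, minlength=d.bin_count + 1)[1:].astype(float)
    s_i = np.bincount(lv, weights=diffs, minlength=d.bin_count + 1)[1:]
    p_i = n_i / n_valid

    denom_coarse = float((p_i * s_i).sum())
    coarseness = min(1.0 / denom_coarse, COARSENESS_CAP) if denom_coarse > 0 else COARSENESS_CAP

    occupied = p_i > 0
    ng = int(occupied.sum())
    if ng > 1:
        pi_o = p_i[occupied]
        gi = level_ids[occupied].astype(float)
        pij = np.outer(pi_o, pi_o)
        dij2 = (gi[:, None] - gi[None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ng * (ng - 1)) * (s_i.sum() / n_valid))
        ip = gi * pi_o
        busy_denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
        busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness}


def glrlm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Run-length count matrix aggregated over directions.

    Entry [i-1, r-1] counts VOI-interrupted runs of gray level i and length r.
    Runs are maximal same-level streaks along each direction, broken whenever
    a voxel leaves the VOI.
    """
    shape = levels.shape
    max_run = int(max(shape))
    counts = np.zeros((n_levels, max_run), dtype=float)
    idx = np.argwhere(mask)
    levset = levels
    for d in directions:
        d = np.asarray(d)
        # run starts: predecessor outside VOI or different level
        for v in idx:
            prev = v - d
            if (
                np.all(prev >= 0)
                and np.all(prev < shape)
                and mask[tuple(prev)]
                and levset[tuple(prev)] == levset[tuple(v)]
            ):
                continue  # not a run start
            length = 1
            nxt = v + d
            while (
                np.all(nxt >= 0)
                and np.all(nxt < shape)
                and mask[tuple(nxt)]
                and levset[tuple(nxt)] == levset[tuple(v)]
            ):
                length += 1
                nxt = nxt + d
            counts[levset[tuple(v)] - 1, length - 1] += 1.0
    return counts


def _run_zone_stats(counts: np.ndarray, prefix: dict[str, str]) -> dict[str, float]:
    """Shared weighted-sum formulas of the run-length / zone-size families."""
    total = counts.sum()
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    c = counts / total
    return {
        prefix["short"]: float((c / j**2).sum()),
        prefix["long"]: float((c * j**2).sum()),
        prefix["low"]: float((c / i**2).sum()),
        prefix["high"]: float((c * i**2).sum()),
        prefix["short_low"]: float((c / (i**2 * j**2)).sum()),
        prefix["short_high"]: float((c * i**2 / j**2).sum()),
        prefix["long_low"]: float((c * j**2 / i**2).sum()),
        prefix["long_high"]: float((c * i**2 * j**2).sum()),
        "GLNU": float((counts.sum(axis=1) ** 2).sum() / total),
        prefix["nu2"]: float((counts.sum(axis=0) ** 2).sum() / total),
    }


def glrlm_features(d, directions=DIRECTIONS_13) -> dict[str, float]:
    """Eleven run-length features (SRE ... RP) from the merged GLRLM.

    RP (run percentage) is runs / (voxels * directions), so it lies in (0, 1]
    for the merged matrix and equals runs/voxels in the single-direction case.
    """
    counts = glrlm_matrix(d.levels, d.mask, d.bin_count, directions)
    n_vox = int(d.mask.sum())
    stats = _run_zone_stats(
        counts,
        {
            "short": "SRE", "long": "LRE", "low": "LGRE", "high": "HGRE",
            "short_low": "SRLGE", "short_high": "SRHGE",
            "long_low": "LRLGE", "long_high": "LRHGE", "nu2": "RLNU",
        },
    )
    stats["RP"] = float(counts.sum() / (n_vox * len(directions)))
    order = ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU", "RLNU", "RP"]
    return {k: stats[k] for k in order}


def glzlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix: zones are 26-connected components of equal
    gray level inside the VOI; entry [i-1, s-1] counts zones of level i and
    size s voxels."""
    n_vox = int(mask.sum())
    counts = np.zeros((n_levels, max(n_vox, 1)), dtype=float)
    present = np.unique(levels[mask])
    for lev in present:
        lab, n_comp = ndimage.label((levels == lev) & mask, structure=_CONN26)
        if n_comp:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                counts[lev - 1, s - 1] += 1.0
    return counts


def glzlm_features(d) -> dict[str, float]:
    """Eleven size-zone features (SZE ... ZP); ZP = zones / voxels."""
    counts = glzlm_matrix(d.levels, d.mask, d.bin_count)
    n_vox = int(d.mask.sum())
    stats = _run_zone_stats(
        counts,
        {
            "short": "SZE", "long": "LZE", "low": "LGZE", "high": "HGZE",
            "short_low": "SZLGE", "short_high": "SZHGE",
            "long_low": "LZLGE", "long_high": "LZHGE", "nu2": "ZLNU",
        },
    )
    stats["ZP"] = float(counts.sum() / n_vox)
    order = ["SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU", "ZLNU", "ZP"]
    return {k: stats[k] for k in order}
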